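"""Synaptic-pathway flagging and module-concentration randomization tests.

A pathway counts as synaptic when "synap", "neuro" or "neura" appears
(case-insensitively) in its name or in its ancestor/child term text.
Four randomization families ask whether synaptic pathways concentrate
in particular co-expression modules:

1. per module: the count of synaptic pathways in that module, null by
   shuffling the pathway-to-module assignment (module sizes held fixed);
2. overall: the total synaptic count in the trait-significant modules,
   same null;
3. mean per significant module, null by shuffling the
   significant/non-significant designation across modules;
4. geography ratio: mean synaptic count in geography-associated modules
   over the mean in the others, null by shuffling that designation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .de import bh_fdr, storey_qvalue
from .ratios import RandTestResult

__all__ = [
    "SYNAPTIC_SUBSTRINGS",
    "flag_synaptic",
    "per_module_concentration_test",
    "overall_concentration_test",
    "mean_per_significant_test",
    "geo_ratio_test",
]

SYNAPTIC_SUBSTRINGS = ("synap", "neuro", "neura")


def flag_synaptic(table: pd.DataFrame) -> pd.DataFrame:
    """Add an is_synaptic column from substring search of the text fields."""
    def hit(row) -> bool:
        text = f"{row.get('name_text', '')} {row.get('ancestor_child_text', '')}".lower()
        return any(s in text for s in SYNAPTIC_SUBSTRINGS)

    out = table.copy()
    out["is_synaptic"] = [hit(row) for _, row in table.iterrows()]
    return out


def _require_flags(table: pd.DataFrame) -> pd.DataFrame:
    if "is_synaptic" not in table.columns:
        table = flag_synaptic(table)
    return table


def _synaptic_counts(modules: np.ndarray, synaptic: np.ndarray,
                     module_names: list) -> np.ndarray:
    return np.array([synaptic[modules == m].sum() for m in module_names], dtype=float)


def per_module_concentration_test(table: pd.DataFrame, n_reps: int = 10000,
                                  seed: int = 0, use_storey: bool = True) -> pd.DataFrame:
    """Synaptic-pathway concentration test for every module.

    Statistic: number of synaptic pathways in the module.  Null: shuffle
    the pathway-to-module map, holding module sizes fixed (exactly the
    hypergeometric null).  P-values are one-sided proportions >= the
    observed count; q-values are computed over the modules.
    """
    if len(table) < 1:
        raise ValueError("empty pathway table")
    table = _require_flags(table)
    modules = table["module"].to_numpy()
    synaptic = table["is_synaptic"].to_numpy(dtype=bool)
    names = sorted(pd.unique(modules).tolist())
    observed = _synaptic_counts(modules, synaptic, names)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(names))
    shuffled = modules.copy()
    for _ in range(n_reps):
        rng.shuffle(shuffled)
        null = _synaptic_counts(shuffled, synaptic, names)
        exceed += null >= observed
    p = exceed / n_reps
    out = pd.DataFrame({
        "module": names,
        "n_pathways": [int((modules == m).sum()) for m in names],
        "n_synaptic": observed.astype(int),
        "p": p,
    }).set_index("module")
    if use_storey and len(out) >= 2:
        try:
            out["q"] = storey_qvalue(out["p"].to_numpy())
        except ValueError:
            out["q"] = bh_fdr(out["p"].to_numpy())
    else:
        out["q"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["q"] < 0.05
    return out


def overall_concentration_test(table: pd.DataFrame, significant_modules,
                               n_reps: int = 10000, seed: int = 0) -> RandTestResult:
    """Total synaptic pathways in the significant modules vs the shuffle null."""
    if len(table) < 1:
        raise ValueError("empty pathway table")
    significant_modules = set(significant_modules)
    if not significant_modules:
        raise ValueError("significant module set is empty")
    table = _require_flags(table)
    modules = table["module"].to_numpy()
    synaptic = table["is_synaptic"].to_numpy(dtype=bool)
    in_sig = np.isin(modules, list(significant_modules))
    observed = float(synaptic[in_sig].sum())
    rng = np.random.default_rng(seed)
    null = np.empty(n_reps)
    shuffled = modules.copy()
    for r in range(n_reps):
        rng.shuffle(shuffled)
        null[r] = synaptic[np.isin(shuffled, list(significant_modules))].sum()
    p = float((null >= observed).mean())
    return RandTestResult(observed, null, p, n_reps, seed, "overall_concentration")


def _per_module_synaptic(table: pd.DataFrame):
    table = _require_flags(table)
    counts = table.groupby("module")["is_synaptic"].sum().astype(float)
    return counts


def mean_per_significant_test(table: pd.DataFrame, significant_modules,
                              n_reps: int = 10000, seed: int = 0) -> RandTestResult:
    """Mean synaptic count per significant module, null over designations.

    The null shuffles which modules are labeled significant (the number
    of significant modules and the per-module synaptic counts are held
    fixed).
    """
    counts = _per_module_synaptic(table)
    modules = counts.index.to_numpy()
    sig_mask = np.isin(modules, list(significant_modules))
    n_sig = int(sig_mask.sum())
    if n_sig == 0 or n_sig == len(modules):
        raise ValueError("need at least one significant and one non-significant module")
    vals = counts.to_numpy()
    observed = float(vals[sig_mask].mean())
    rng = np.random.default_rng(seed)
    null = np.empty(n_reps)
    for r in range(n_reps):
        pick = rng.choice(len(modules), size=n_sig, replace=False)
        null[r] = vals[pick].mean()
    p = float((null >= observed).mean())
    return RandTestResult(observed, null, p, n_reps, seed, "mean_per_significant")


def geo_ratio_test(table: pd.DataFrame, geo_modules, n_reps: int = 10000,
                   seed: int = 0) -> RandTestResult:
    """Ratio of mean synaptic counts, geography modules over the rest.

    Statistic: meanNSynapticGeo / meanNSynapticNonGeo; the null shuffles
    the geography-association designation across modules.
    """
    counts = _per_module_synaptic(table)
    modules = counts.index.to_numpy()
    geo_mask = np.isin(modules, list(geo_modules))
    n_geo = int(geo_mask.sum())
    if n_geo == 0 or n_geo == len(modules):
        raise ValueError("need at least one module in each designation group")
    vals = counts.to_numpy()
    denom = vals[~geo_mask].mean()
    if denom == 0:
        raise ZeroDivisionError("non-geography modules have no synaptic pathways")
    observed = float(vals[geo_mask].mean() / denom)
    rng = np.random.default_rng(seed)
    null = np.empty(n_reps)
    for r in range(n_reps):
        pick = np.zeros(len(modules), dtype=bool)
        pick[rng.choice(len(modules), size=n_geo, replace=False)] = True
        d = vals[~pick].mean()
        null[r] = vals[pick].mean() / d if d > 0 else np.inf
    p = float((null >= observed).mean())
    return RandTestResult(observed, null, p, n_reps, seed, "geo_ratio")
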