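"""Count filtering, TMM normalization and (log) counts-per-million.

The normalization pipeline mirrors the standard bulk RNA-seq workflow:
genes with mean CPM below a threshold are discarded, between-sample
scaling factors are computed with the trimmed mean of M-values (TMM)
method of Robinson & Oshlack, and log2 CPM values are computed with a
library-size-scaled prior count so that zeros stay finite.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "SampleTable",
    "NormalizedExpression",
    "read_counts",
    "read_samples",
    "filter_low_expression",
    "tmm_factors",
    "log_cpm",
    "normalize",
]

GEOGRAPHIES = ("allopatric", "sympatric")
SEXES = ("female", "male")


@dataclasses.dataclass
class CountMatrix:
    """Raw integer read counts, genes x samples.

    ``counts`` is a pandas DataFrame indexed by gene id with one column
    per sample id.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            raise ValueError("duplicate gene ids in count matrix")
        if c.columns.has_duplicates:
            raise ValueError("duplicate sample ids in count matrix")
        if (c.to_numpy() < 0).any():
            raise ValueError("negative entries in count matrix")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def values(self) -> np.ndarray:
        return self.counts.to_numpy(dtype=float)

    @property
    def lib_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0).to_numpy(dtype=float)


@dataclasses.dataclass
class NormalizedExpression:
    """TMM factors, effective library sizes and (log2) CPM matrices."""

    tmm_factor: pd.Series
    effective_lib_size: pd.Series
    cpm: pd.DataFrame
    log2_cpm: pd.DataFrame
    kept_gene_ids: list[str]
    prior_count: float


@dataclasses.dataclass
class SampleTable:
    """Sample metadata: geography (allopatric/sympatric) and sex.

    ``table`` is indexed by sample id with columns ``geography`` and
    ``sex``; a derived ``group`` label combines the two.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if t.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        bad_geo = set(t["geography"]) - set(GEOGRAPHIES)
        bad_sex = set(t["sex"]) - set(SEXES)
        if bad_geo or bad_sex:
            raise ValueError(f"unknown factor levels: {bad_geo | bad_sex}")
        if "group" not in t.columns:
            t = t.copy()
            t["group"] = t["geography"] + "_" + t["sex"]
            self.table = t

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def geography(self) -> pd.Series:
        return self.table["geography"]

    def sex(self) -> pd.Series:
        return self.table["sex"]

    def group(self) -> pd.Series:
        return self.table["group"]

    def check_matches(self, counts: CountMatrix) -> None:
        if set(self.sample_ids) != set(counts.sample_ids):
            raise ValueError("sample table does not match count matrix columns")


def read_samples(path) -> SampleTable:
    """Read a samples TSV with columns sample_id, geography, sex."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SampleTable(df)


def read_counts(path) -> CountMatrix:
    """Read a counts TSV whose first column holds gene ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(df)


def raw_cpm(counts: CountMatrix) -> pd.DataFrame:
    """Unnormalized counts per million (raw library sizes, no prior)."""
    lib = counts.lib_sizes
    if (lib <= 0).any():
        raise ValueError("library size zero; cannot compute CPM")
    return counts.counts / lib * 1e6


def filter_low_expression(counts: CountMatrix, min_mean_cpm: float = 1.0) -> CountMatrix:
    """Drop genes whose mean unnormalized CPM across samples is below threshold.

    Filtering happens before normalization, so plain library sizes are
    used.  The boundary is kept inclusive: mean CPM exactly equal to the
    threshold survives (the filter discards strictly-below genes).
    """
    mean_cpm = raw_cpm(counts).mean(axis=1)
    keep = mean_cpm >= min_mean_cpm
    if not keep.any():
        raise ValueError(
            f"all {len(keep)} genes removed at min_mean_cpm={min_mean_cpm}; "
            "lower the threshold"
        )
    return CountMatrix(counts.counts.loc[keep])


def _tmm_pair(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
              logratio_trim: float = 0.3, sum_trim: float = 0.05) -> float:
    """TMM factor of one sample against the reference.

    Doubly trimmed (30% on M, 5% on A) weighted mean of M-values, with
    inverse asymptotic-variance weights; genes zero in either sample are
    excluded.
    """
    pos = (obs > 0) & (ref > 0)
    obs, ref = obs[pos], ref[pos]
    if obs.size == 0:
        return 1.0
    p_obs = obs / n_obs
    p_ref = ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # delta-method variance of M
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    fin = np.isfinite(m) & np.isfinite(a)
    m, a, v = m[fin], a[fin], v[fin]
    n = m.size
    if n == 0:
        return 1.0
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rm = _rank(m)
    ra = _rank(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        f = 0.0
    return float(2.0 ** f)


def _rank(x: np.ndarray) -> np.ndarray:
    """Average ranks, 1-based (matching R's rank)."""
    from scipy.stats import rankdata

    return rankdata(x)


def tmm_factors(counts: CountMatrix) -> pd.Series:
    """Per-sample TMM normalization factors, rescaled to geometric mean 1.

    The reference sample is the one whose 75th-percentile count fraction
    is closest to the mean of those fractions across samples.
    """
    y = counts.values
    if y.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = counts.lib_sizes
    if (lib <= 0).any():
        bad = [s for s, l in zip(counts.sample_ids, lib) if l <= 0]
        raise ValueError(f"sample(s) with all-zero counts: {bad}")
    q75 = np.array([np.quantile(y[:, j] / lib[j], 0.75) for j in range(y.shape[1])])
    ref = int(np.argmin(np.abs(q75 - q75.mean())))
    f = np.array([
        _tmm_pair(y[:, j], y[:, ref], lib[j], lib[ref]) for j in range(y.shape[1])
    ])
    f = f / np.exp(np.mean(np.log(f)))
    return pd.Series(f, index=counts.sample_ids, name="tmm_factor")


def log_cpm(counts: CountMatrix, factors: pd.Series | None = None,
            prior_count: float = 2.0) -> NormalizedExpression:
    """CPM and log2 CPM with a library-size-scaled prior count.

    The prior for sample *s* is ``prior_count * L_s / mean(L)`` where
    ``L_s`` is the effective (TMM-scaled) library size; log2 CPM is then
    ``log2((y + prior_s) / (L_s + 2 * prior_s) * 1e6)``.  Scaling the
    prior by relative library size makes log ratios of equal relative
    abundance exactly zero.
    """
    if prior_count < 0:
        raise ValueError("prior_count must be >= 0")
    if factors is None:
        factors = tmm_factors(counts)
    factors = factors.reindex(counts.sample_ids)
    if factors.isna().any():
        raise ValueError("factors not aligned to samples")
    lib = counts.lib_sizes
    eff = lib * factors.to_numpy()
    y = counts.values
    cpm = y / eff * 1e6
    prior = prior_count * eff / eff.mean()
    with np.errstate(divide="ignore"):
        lcpm = np.log2((y + prior) / (eff + 2.0 * prior) * 1e6)
    if prior_count == 0 and not np.isfinite(lcpm).all():
        # permitted limit case, but only for strictly positive counts
        raise ValueError("prior_count=0 with zero counts gives -inf log CPM")
    idx, cols = counts.counts.index, counts.counts.columns
    return NormalizedExpression(
        tmm_factor=factors,
        effective_lib_size=pd.Series(eff, index=cols, name="effective_lib_size"),
        cpm=pd.DataFrame(cpm, index=idx, columns=cols),
        log2_cpm=pd.DataFrame(lcpm, index=idx, columns=cols),
        kept_gene_ids=list(idx),
        prior_count=prior_count,
    )


def normalize(counts: CountMatrix, min_mean_cpm: float = 1.0,
              prior_count: float = 2.0) -> tuple[CountMatrix, NormalizedExpression]:
    """Filter low-expression genes, then TMM-normalize and compute log2 CPM."""
    kept = filter_low_expression(counts, min_mean_cpm)
    factors = tmm_factors(kept)
    return kept, log_cpm(kept, factors, prior_count)
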