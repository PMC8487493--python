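"""Transcriptome-wide DE-count ratio randomization tests.

Each test compares the number of differentially expressed genes in two
categories (for example geography-DE versus sex-DE).  The statistic is
the ratio of the category counts; the null shuffles each gene's pair of
0/1 indicators horizontally (swap with probability 1/2, independently
per gene) and recomputes the ratio.  P-values are the proportion of
null replicates greater than or equal to the observed statistic.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

__all__ = [
    "DEIndicatorTable",
    "RandTestResult",
    "ratio_statistic",
    "ratio_randomization_test",
    "build_comparison_tables",
]


@dataclasses.dataclass
class DEIndicatorTable:
    """Per-gene 0/1 DE indicators for two categories A and B."""

    a: np.ndarray
    b: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=np.int8)
        self.b = np.asarray(self.b, dtype=np.int8)
        if self.a.shape != self.b.shape or self.a.ndim != 1:
            raise ValueError("categories must be equal-length 1-D vectors")
        for v in (self.a, self.b):
            if not np.isin(v, (0, 1)).all():
                raise ValueError("indicators must be 0/1")

    def swapped(self) -> "DEIndicatorTable":
        return DEIndicatorTable(self.b.copy(), self.a.copy(), self.name)


@dataclasses.dataclass
class RandTestResult:
    """Observed statistic, null samples and empirical p for one test."""

    observed_statistic: float
    null_samples: np.ndarray
    p: float
    n_reps: int
    seed: int
    name: str = ""


def ratio_statistic(table: DEIndicatorTable) -> float:
    """Ratio of DE counts, sum(A) / sum(B)."""
    nb = int(table.b.sum())
    if nb == 0:
        raise ZeroDivisionError(
            "category B has no significant genes; the ratio is undefined "
            "(swap categories or use a count-difference statistic)")
    return float(table.a.sum()) / nb


def ratio_randomization_test(table: DEIndicatorTable, n_reps: int = 10000,
                             seed: int = 0, add_one: bool = False) -> RandTestResult:
    """One-sided randomization test of A > B on the indicator table.

    Each null replicate swaps each gene's (A, B) pair with probability
    1/2 and recomputes the ratio; replicates whose denominator is zero
    count as infinite (they always reach the observed value).  With
    ``add_one`` the (r+1)/(N+1) p-value estimator is used instead of the
    plain proportion.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if table.a.sum() + table.b.sum() == 0:
        raise ValueError("degenerate table: no significant genes in either category")
    observed = ratio_statistic(table)
    rng = np.random.default_rng(seed)
    a, b = table.a.astype(np.int64), table.b.astype(np.int64)
    diff = a - b  # swap changes the A sum by -diff per swapped gene
    sum_a, sum_b = a.sum(), b.sum()
    total = sum_a + sum_b
    swaps = rng.random((n_reps, a.size)) < 0.5
    null_a = sum_a - swaps @ diff
    null_b = total - null_a
    with np.errstate(divide="ignore"):
        null = np.where(null_b > 0, null_a / np.maximum(null_b, 1), np.inf)
    ge = int((null >= observed).sum())
    p = (ge + 1) / (n_reps + 1) if add_one else ge / n_reps
    return RandTestResult(observed, null, float(p), n_reps, seed, table.name)


def _union(*flag_vectors) -> np.ndarray:
    out = np.zeros_like(np.asarray(flag_vectors[0], dtype=bool))
    for v in flag_vectors:
        out |= np.asarray(v, dtype=bool)
    return out.astype(np.int8)


def build_comparison_tables(de_results: dict) -> dict[str, DEIndicatorTable]:
    """The three study indicator tables from per-comparison DE results.

    - ``geo_vs_sex``: A = DE in either within-sex geography comparison,
      B = DE in either within-geography sex comparison (unique-gene
      unions).
    - ``female_vs_male_geo``: A = geography-DE in females, B = in males.
    - ``sym_vs_allo_sex``: A = sex-DE in sympatry, B = in allopatry.
    """
    needed = ["geo_female", "geo_male", "sex_allo", "sex_sym"]
    missing = [c for c in needed if c not in de_results]
    if missing:
        raise ValueError(f"missing comparison(s): {missing}")
    genes = de_results["geo_female"].table.index
    flags = {}
    for c in needed:
        t = de_results[c].table
        if not t.index.equals(genes):
            raise ValueError("comparisons tested different gene sets")
        flags[c] = t["significant"].to_numpy()
    return {
        "geo_vs_sex": DEIndicatorTable(
            _union(flags["geo_female"], flags["geo_male"]),
            _union(flags["sex_allo"], flags["sex_sym"]),
            name="geo_vs_sex"),
        "female_vs_male_geo": DEIndicatorTable(
            flags["geo_female"].astype(np.int8),
            flags["geo_male"].astype(np.int8),
            name="female_vs_male_geo"),
        "sym_vs_allo_sex": DEIndicatorTable(
            flags["sex_sym"].astype(np.int8),
            flags["sex_allo"].astype(np.int8),
            name="sym_vs_allo_sex"),
    }
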