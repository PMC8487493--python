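"""Expression-divergence trees among the four groups.

Per-gene expression is standardized, averaged within each geography x
sex group, converted to a pairwise distance matrix and summarized as a
neighbor-joining tree; tip branch lengths measure each group's
contribution to expression divergence.  Randomization tests compare
mean tip-length differences between group pairs, within and between
the candidate and non-candidate gene sets, by shuffling the candidate
labels among genes.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .de import bh_fdr

__all__ = [
    "GROUPS",
    "DivergenceTree",
    "standardize_genes",
    "neighbor_joining",
    "gene_divergence_tree",
    "group_mean_matrix",
    "tip_lengths_per_gene",
    "divergence_tests",
    "log2_tip_ratios",
]

#: tip order used throughout: sympatric/allopatric males, then females
GROUPS = ("SM", "AM", "SF", "AF")

GROUP_OF = {
    ("sympatric", "male"): "SM",
    ("allopatric", "male"): "AM",
    ("sympatric", "female"): "SF",
    ("allopatric", "female"): "AF",
}

#: default group pairs for the branch-length difference tests
DEFAULT_PAIRS = (("SF", "AF"), ("SM", "AM"), ("SF", "SM"), ("AF", "AM"))


def standardize_genes(expr: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-scores (mean 0, sd 1); zero-variance rows are dropped.

    Uses the population (ddof 0) standard deviation.
    """
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 samples to standardize")
    x = expr.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    keep = sd[:, 0] > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        import warnings

        warnings.warn(f"dropped {n_dropped} constant gene(s) before standardization")
    z = (x[keep] - mean[keep]) / sd[keep]
    return pd.DataFrame(z, index=expr.index[keep], columns=expr.columns)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class DivergenceTree:
    """Unrooted NJ tree over the four groups with tip branch lengths."""

    tip_labels: tuple[str, ...]
    tip_lengths: np.ndarray
    internal_length: float
    joined_pair: tuple[str, str]
    clipped: bool

    def tip_length(self, label: str) -> float:
        return float(self.tip_lengths[self.tip_labels.index(label)])


def neighbor_joining(dist: np.ndarray, labels=None):
    """Saitou-Nei neighbor joining on a full distance matrix.

    Returns (edges, node_labels): internal nodes are numbered past the
    tips; edges are (node_a, node_b, length) with lengths as computed
    (possibly negative).  Intended for small matrices; per-gene
    four-taxon trees use the vectorized closed form instead.
    """
    d = np.asarray(dist, dtype=float).copy()
    n = d.shape[0]
    if labels is None:
        labels = [str(i) for i in range(n)]
    nodes = list(range(n))
    labels = list(labels) + [f"node{i}" for i in range(n, 2 * n - 2)]
    next_node = n
    edges = []
    active = list(range(n))
    dm = {(i, j): d[i, j] for i in range(n) for j in range(n)}
    while len(active) > 2:
        m = len(active)
        r = {i: sum(dm[i, j] for j in active if j != i) for i in active}
        best, bq = None, np.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * dm[i, j] - r[i] - r[j]
                if q < bq - 1e-15:
                    bq, best = q, (i, j)
        i, j = best
        li = 0.5 * dm[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dm[i, j] - li
        u = next_node
        next_node += 1
        edges.append((i, u, li))
        edges.append((j, u, lj))
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (dm[i, k] + dm[j, k] - dm[i, j])
            dm[u, k] = dm[k, u] = duk
        active = [k for k in active if k not in (i, j)] + [u]
    a, b = active
    edges.append((a, b, dm[a, b]))
    return edges, labels


def _nj4_tip_lengths(d: np.ndarray):
    """Vectorized four-taxon NJ tip branch lengths.

    ``d`` has shape (G, 4, 4).  Returns (tips (G,4), internal (G,),
    joined pair index (G,)).  Tip order follows the input matrix.
    """
    G = d.shape[0]
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    r = d.sum(axis=2)  # (G, 4)
    q = np.stack([2.0 * d[:, i, j] - r[:, i] - r[:, j] for i, j in pairs], axis=1)
    # deterministic tie-break: first minimal pair in the fixed pair order
    choice = np.argmin(np.round(q, 12), axis=1)
    tips = np.zeros((G, 4))
    internal = np.zeros(G)
    idx = np.arange(G)
    for c, (i, j) in enumerate(pairs):
        mask = choice == c
        if not mask.any():
            continue
        k, l = [t for t in range(4) if t not in (i, j)]
        dij = d[mask, i, j]
        li = 0.5 * dij + (r[mask, i] - r[mask, j]) / 4.0
        lj = dij - li
        duk = 0.5 * (d[mask, i, k] + d[mask, j, k] - dij)
        dul = 0.5 * (d[mask, i, l] + d[mask, j, l] - dij)
        dkl = d[mask, k, l]
        lk = 0.5 * (duk + dkl - dul)
        ll = 0.5 * (dul + dkl - duk)
        lu = 0.5 * (duk + dul - dkl)
        m = idx[mask]
        tips[m, i] = li
        tips[m, j] = lj
        tips[m, k] = lk
        tips[m, l] = ll
        internal[mask] = lu
    return tips, internal, choice


def gene_divergence_tree(group_means, group_labels=GROUPS) -> DivergenceTree:
    """NJ tree from four per-group values (or vectors) of one gene set.

    For a single gene each group mean is a scalar and the distance is
    the absolute difference; for a set of genes the group profiles are
    vectors and the distance is Euclidean.  Negative NJ branch lengths
    are clipped to zero and flagged.
    """
    gm = np.asarray(group_means, dtype=float)
    if gm.ndim == 1:
        gm = gm[:, None]
    if gm.shape[0] != 4:
        raise ValueError("need exactly four groups")
    diff = gm[:, None, :] - gm[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=2))
    tips, internal, choice = _nj4_tip_lengths(d[None])
    tips, internal = tips[0], float(internal[0])
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    i, j = pairs[int(choice[0])]
    clipped = bool((tips < -1e-12).any() or internal < -1e-12)
    tips = np.clip(tips, 0.0, None)
    return DivergenceTree(
        tip_labels=tuple(group_labels),
        tip_lengths=tips,
        internal_length=max(internal, 0.0),
        joined_pair=(group_labels[i], group_labels[j]),
        clipped=clipped,
    )


def group_mean_matrix(standardized: pd.DataFrame, samples) -> pd.DataFrame:
    """Per-group mean of standardized expression: genes x four groups."""
    meta = samples.table.loc[standardized.columns]
    cols = {}
    for (geo, sex), label in GROUP_OF.items():
        sel = (meta["geography"] == geo) & (meta["sex"] == sex)
        if not sel.any():
            raise ValueError(f"group {label} has no samples")
        cols[label] = standardized.loc[:, sel.to_numpy()].mean(axis=1)
    return pd.DataFrame(cols)[list(GROUPS)]


def tip_lengths_per_gene(group_means: pd.DataFrame) -> pd.DataFrame:
    """Four-taxon NJ tip branch lengths for every gene (vectorized).

    Distances per gene are absolute differences of the four group means;
    negative branch lengths are clipped to zero.
    """
    gm = group_means.to_numpy(dtype=float)
    d = np.abs(gm[:, :, None] - gm[:, None, :])
    tips, _, _ = _nj4_tip_lengths(d)
    tips = np.clip(tips, 0.0, None)
    return pd.DataFrame(tips, index=group_means.index, columns=group_means.columns)


def divergence_tests(tip_lengths: pd.DataFrame, candidate_flags,
                     group_pairs=DEFAULT_PAIRS, n_reps: int = 10000,
                     seed: int = 0) -> pd.DataFrame:
    """Twelve randomization tests on mean tip-branch-length differences.

    For each of the four group pairs: the mean difference within the
    candidate set, within the non-candidate set (8 tests), and the
    candidate-minus-non-candidate difference of those means (4 tests).
    The null shuffles candidate/non-candidate labels among genes
    (10,000 replicates); p is the one-sided proportion of null values
    greater than or equal to the observed statistic; FDR (BH) is
    computed over all 12 tests.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    flags = np.asarray(pd.Series(candidate_flags).reindex(tip_lengths.index)
                       if not isinstance(candidate_flags, np.ndarray)
                       else candidate_flags, dtype=bool)
    if flags.sum() < 2 or (~flags).sum() < 2:
        raise ValueError("need at least 2 genes in each set")
    tl = tip_lengths.to_numpy(dtype=float)
    cols = {g: i for i, g in enumerate(tip_lengths.columns)}
    diffs = np.stack([tl[:, cols[a]] - tl[:, cols[b]] for a, b in group_pairs],
                     axis=1)  # genes x pairs

    def stats(mask):
        c = diffs[mask].mean(axis=0)
        nc = diffs[~mask].mean(axis=0)
        return c, nc, c - nc

    obs_c, obs_nc, obs_d = stats(flags)
    rng = np.random.default_rng(seed)
    null_c = np.empty((n_reps, len(group_pairs)))
    null_nc = np.empty_like(null_c)
    null_d = np.empty_like(null_c)
    perm = flags.copy()
    for r in range(n_reps):
        rng.shuffle(perm)
        c, nc, dd = stats(perm)
        null_c[r], null_nc[r], null_d[r] = c, nc, dd

    rows = []
    for pi, (a, b) in enumerate(group_pairs):
        pair = f"{a}-{b}"
        rows.append((f"candidate:{pair}", pair, "candidate", obs_c[pi],
                     float((null_c[:, pi] >= obs_c[pi]).mean())))
        rows.append((f"noncandidate:{pair}", pair, "non-candidate", obs_nc[pi],
                     float((null_nc[:, pi] >= obs_nc[pi]).mean())))
    for pi, (a, b) in enumerate(group_pairs):
        pair = f"{a}-{b}"
        rows.append((f"cand_minus_noncand:{pair}", pair, "difference", obs_d[pi],
                     float((null_d[:, pi] >= obs_d[pi]).mean())))
    out = pd.DataFrame(rows, columns=["test", "pair", "set", "statistic", "p"])
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    return out.set_index("test")


def log2_tip_ratios(tree: DivergenceTree, pairs=DEFAULT_PAIRS) -> dict[str, float]:
    """Reporting statistic: log2 ratio of tip lengths for group pairs.

    Zero denominators yield NaN rather than an error (zero-length
    branches are common for single genes).
    """
    out = {}
    for a, b in pairs:
        num, den = tree.tip_length(a), tree.tip_length(b)
        out[f"{a}/{b}"] = float(np.log2(num / den)) if num > 0 and den > 0 else float("nan")
    return out
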