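"""Weighted gene co-expression network analysis.

Implements the WGCNA-style workflow: variance filtering, soft-threshold
selection against a scale-free topology criterion, signed/unsigned
adjacency, topological overlap (TOM), average-linkage clustering with a
static cut plus recursive splitting (a documented approximation of the
dynamic tree cut), module eigengenes, eigengene-based module merging,
module-trait correlation with Storey q-values, connectivity statistics
and network export.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import t as t_dist

from .de import bh_fdr, storey_qvalue

__all__ = [
    "NetworkConfig",
    "ModulePartition",
    "select_top_variance",
    "adjacency_matrix",
    "pick_soft_threshold",
    "tom_similarity",
    "detect_modules",
    "module_eigengenes",
    "merge_modules",
    "module_trait_correlation",
    "connectivity_stats",
    "export_network",
    "build_network",
]

# WGCNA's conventional module color names, assigned in size order
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
]
GREY = "grey"


@dataclasses.dataclass
class NetworkConfig:
    top_variance_fraction: float = 0.10
    beta: int | str = "auto"
    beta_grid: tuple = tuple(range(1, 21))
    scale_free_r2_threshold: float = 0.9
    network_sign: str = "unsigned"
    min_module_size: int = 40
    cut_height: float = 0.99
    deep_split: int = 3
    merge_dissimilarity: float = 0.3
    edge_filter_r: float = 0.05
    report_thresholds: tuple = (0.1, 0.3)
    # rank genes for the variance filter on log2 CPM (default) or raw
    # CPM; raw-CPM variance is dominated by the mean-variance relation
    # and mostly ranks abundance
    variance_on: str = "log2_cpm"

    def __post_init__(self) -> None:
        if not 0 < self.top_variance_fraction <= 1:
            raise ValueError("top_variance_fraction must be in (0, 1]")
        if not 0 < self.cut_height <= 1:
            raise ValueError("cut_height must be in (0, 1]")
        if self.network_sign not in ("unsigned", "signed"):
            raise ValueError("network_sign must be 'unsigned' or 'signed'")


def select_top_variance(expr: pd.DataFrame, fraction: float = 0.10) -> pd.DataFrame:
    """Keep the ceil(fraction * G) genes with highest variance across samples.

    Ranking uses the per-gene variance of the supplied expression matrix
    (the study filtered on CPM variance); ties break by gene id for
    determinism.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    var = expr.var(axis=1, ddof=1)
    order = sorted(expr.index, key=lambda g: (-var[g], g))
    n_keep = int(np.ceil(fraction * len(order)))
    return expr.loc[order[:n_keep]]


def correlation_matrix(expr: pd.DataFrame) -> np.ndarray:
    """Gene-gene Pearson correlations (rows = genes)."""
    r = np.corrcoef(expr.to_numpy(dtype=float))
    return np.clip(np.nan_to_num(r, nan=0.0), -1.0, 1.0)


def adjacency_matrix(corr: np.ndarray, beta: int, sign: str = "unsigned") -> np.ndarray:
    """Soft-threshold adjacency: |r|^beta (unsigned) or ((1+r)/2)^beta (signed)."""
    if sign == "unsigned":
        a = np.abs(corr) ** beta
    else:
        a = ((1.0 + corr) / 2.0) ** beta
    np.fill_diagonal(a, 0.0)
    return a


def _scale_free_fit(k: np.ndarray, n_bins: int = 10):
    """R^2 and slope of log10 p(k) on log10 k over equal-width k bins."""
    k = k[k > 0]
    if k.size < 3 or np.allclose(k, k[0]):
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max() * (1 + 1e-12), n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        m = which == b
        if m.sum() == 0:
            continue
        xs.append(np.log10(k[m].mean()))
        ys.append(np.log10(m.mean()))
    if len(xs) < 3:
        return 0.0, 0.0
    x, y = np.array(xs), np.array(ys)
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = ((y - yhat) ** 2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(r2), float(slope)


def pick_soft_threshold(expr: pd.DataFrame, config: NetworkConfig | None = None):
    """Pick the smallest beta whose scale-free fit index reaches threshold.

    The fit index is R^2 of the log-log degree-frequency regression,
    with a negative-slope requirement (positive slopes score 0).
    Falls back to the argmax beta with a warning when no beta reaches
    the threshold.  Returns (beta, fit_table).
    """
    config = config or NetworkConfig()
    if len(config.beta_grid) == 0:
        raise ValueError("beta grid is empty")
    if expr.shape[0] < 3:
        raise ValueError("need at least 3 genes")
    corr = correlation_matrix(expr)
    rows = []
    for beta in config.beta_grid:
        a = adjacency_matrix(corr, beta, config.network_sign)
        k = a.sum(axis=1)
        r2, slope = _scale_free_fit(k)
        fit = r2 if slope < 0 else 0.0
        rows.append((beta, fit, r2, slope, k.mean(), np.median(k), k.max()))
    table = pd.DataFrame(rows, columns=["beta", "fit", "r2", "slope",
                                        "mean_k", "median_k", "max_k"])
    good = table[table["fit"] >= config.scale_free_r2_threshold]
    if len(good):
        beta = int(good["beta"].iloc[0])
    else:
        # fall back to the best-fitting beta that keeps the network
        # connected (mean k >= 2); an unconstrained argmax runs off to
        # the largest beta on data that is not scale-free
        usable = table[table["mean_k"] >= 2.0]
        if not len(usable):
            usable = table
        beta = int(usable.loc[usable["fit"].idxmax(), "beta"])
        warnings.warn(
            f"no beta reached scale-free fit {config.scale_free_r2_threshold}; "
            f"using best-fitting connected beta={beta} "
            f"(fit={usable['fit'].max():.3f})")
    return beta, table


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap similarity.

    omega_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) for
    i != j, omega_ii = 1.  Requires a symmetric adjacency with zero
    diagonal and entries in [0, 1].
    """
    a = np.asarray(adjacency, dtype=float)
    if (a < 0).any() or (a > 1).any():
        raise ValueError("adjacency entries must lie in [0, 1]")
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if not np.allclose(np.diag(a), 0.0):
        raise ValueError("adjacency diagonal must be zero")
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        omega = (shared + a) / denom
    omega = np.nan_to_num(omega, nan=0.0)
    np.fill_diagonal(omega, 1.0)
    return np.clip(omega, 0.0, 1.0)


@dataclasses.dataclass
class ModulePartition:
    """Gene-to-module labels; 'grey' marks unassigned genes."""

    labels: pd.Series
    merge_history: list = dataclasses.field(default_factory=list)

    @property
    def module_names(self) -> list[str]:
        return [m for m in self.labels.unique() if m != GREY]

    def sizes(self) -> pd.Series:
        return self.labels.value_counts()

    def members(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])

    def n_modules(self) -> int:
        return len(self.module_names)


def _significant_branches(link: np.ndarray, n: int, cut_height: float,
                          min_size: int, major_size: int) -> list[list[int]]:
    """Module branches from bottom-up agglomeration of the dendrogram.

    Merges are replayed in height order below ``cut_height``.  A merge
    of two clusters that are each at least ``major_size`` strong is a
    "major" merge: each side that does not already contain a recorded
    module and has at least ``min_size`` members is recorded as one.
    Minor merges (one side small) simply extend a growing cluster, which
    makes the procedure robust to the singleton chaining that average
    linkage produces.  Clusters still unrecorded when the cut height is
    reached are recorded if large enough.
    """
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    has_module: dict[int, bool] = {i: False for i in range(n)}
    modules: list[list[int]] = []
    for row, (ci, cj, h, _) in enumerate(link):
        ci, cj = int(ci), int(cj)
        parent = n + row
        if h > cut_height:
            break
        mi, mj = members.pop(ci), members.pop(cj)
        fi, fj = has_module.pop(ci), has_module.pop(cj)
        major = len(mi) >= major_size and len(mj) >= major_size
        if major:
            for side, side_flag in ((mi, fi), (mj, fj)):
                if not side_flag and len(side) >= min_size:
                    modules.append(side)
            flag = True
        else:
            flag = fi or fj
        members[parent] = mi + mj
        has_module[parent] = flag
    # clusters surviving to the cut height without a major merge
    for cid, mm in members.items():
        if not has_module[cid] and len(mm) >= min_size:
            modules.append(mm)
    return modules


def detect_modules(tom: np.ndarray, gene_ids, config: NetworkConfig | None = None,
                   return_linkage: bool = False):
    """Average-linkage clustering of TOM dissimilarity with tree cutting.

    The dendrogram is truncated at ``cut_height`` and modules are the
    "significant branches" found by replaying merges bottom-up: a
    cluster is frozen as a module the first time it merges with another
    sizable cluster (see :func:`_significant_branches`); singleton
    chain absorptions simply extend a growing cluster.  ``deep_split``
    controls how small that merge partner may be — higher values split
    more aggressively.  This is a documented approximation of the
    dynamic tree cut; over-split modules are typically reunited by the
    eigengene merging stage.  Genes outside any module are grey;
    modules receive conventional color names in decreasing size order.
    """
    config = config or NetworkConfig()
    gene_ids = list(gene_ids)
    n = len(gene_ids)
    if n != tom.shape[0]:
        raise ValueError("gene_ids do not match TOM dimension")
    if n < config.min_module_size:
        warnings.warn("fewer genes than min_module_size; everything is grey")
        part = ModulePartition(pd.Series(GREY, index=gene_ids))
        return (part, None) if return_linkage else part
    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    link = hierarchy.linkage(squareform(diss, checks=False), method="average")
    # deep_split 3 (default) lets any min_module_size cluster count as a
    # major merge partner; smaller values demand a larger partner and so
    # split less
    major_size = int(round(config.min_module_size *
                           (1.0 + 0.5 * max(0, 3 - config.deep_split))))
    branches = _significant_branches(link, n, config.cut_height,
                                     config.min_module_size, major_size)
    labels = pd.Series(GREY, index=gene_ids, dtype=object)
    branches.sort(key=lambda mm: (-len(mm), min(mm)))
    for j, mm in enumerate(branches):
        color = MODULE_COLORS[j] if j < len(MODULE_COLORS) else f"module{j + 1}"
        labels.iloc[mm] = color
    part = ModulePartition(labels)
    return (part, link) if return_linkage else part


def module_eigengenes(expr: pd.DataFrame, partition: ModulePartition) -> pd.DataFrame:
    """First principal component of each module across samples.

    Member genes are standardized before the SVD; the eigengene is the
    unit-norm sample-space singular vector, oriented so its correlation
    with the module-average expression is nonnegative.  Returns samples
    x modules.
    """
    cols = {}
    for module in partition.module_names:
        genes = partition.members(module)
        x = expr.loc[genes].to_numpy(dtype=float)
        mean = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        z = (x - mean) / sd
        if z.shape[0] == 1:
            v = z[0] / np.linalg.norm(z[0])
        else:
            _, _, vt = np.linalg.svd(z, full_matrices=False)
            v = vt[0]
        avg = z.mean(axis=0)
        if np.dot(v, avg) < 0:
            v = -v
        cols[module] = v
    return pd.DataFrame(cols, index=expr.columns)


def merge_modules(expr: pd.DataFrame, partition: ModulePartition,
                  threshold: float = 0.3) -> tuple[ModulePartition, pd.DataFrame]:
    """Merge modules whose eigengene dissimilarity is below threshold.

    Average-linkage grouping of the eigengene dissimilarity (1 - cor) is
    cut at the threshold; groups merge into their largest member's name;
    eigengenes are recomputed and the procedure repeats until stable.
    Returns the merged partition (with history) and its eigengenes.
    """
    labels = partition.labels.copy()
    history = list(partition.merge_history)
    for _ in range(50):
        part = ModulePartition(labels, history)
        egs = module_eigengenes(expr, part)
        mods = list(egs.columns)
        if len(mods) < 2:
            return part, egs
        corr = np.corrcoef(egs.to_numpy().T)
        diss = 1.0 - np.clip(np.nan_to_num(corr, nan=0.0), -1.0, 1.0)
        np.fill_diagonal(diss, 0.0)
        link = hierarchy.linkage(squareform(diss, checks=False), method="average")
        groups = hierarchy.fcluster(link, t=threshold, criterion="distance")
        if len(set(groups)) == len(mods):
            return part, egs
        sizes = part.sizes()
        for gid in sorted(set(groups)):
            members = [m for m, g in zip(mods, groups) if g == gid]
            if len(members) < 2:
                continue
            target = max(members, key=lambda m: (sizes[m], m))
            for m in members:
                if m != target:
                    labels[labels == m] = target
                    history.append((m, target))
    warnings.warn("module merging did not stabilize after 50 rounds")
    part = ModulePartition(labels, history)
    return part, module_eigengenes(expr, part)


def module_trait_correlation(eigengenes: pd.DataFrame, samples,
                             use_storey: bool = True) -> pd.DataFrame:
    """Pearson correlation of eigengenes with binary-coded traits.

    Geography is coded allopatric=0/sympatric=1 and sex male=0/female=1;
    p-values come from the t-distribution with n-2 df and are corrected
    over all module x trait tests (Storey q by default, BH fallback).
    """
    meta = samples.table.loc[eigengenes.index]
    traits = {
        "geography": (meta["geography"] == "sympatric").astype(float).to_numpy(),
        "sex": (meta["sex"] == "female").astype(float).to_numpy(),
    }
    n = len(meta)
    rows = []
    for module in eigengenes.columns:
        e = eigengenes[module].to_numpy()
        for trait, code in traits.items():
            if np.std(e) == 0 or np.std(code) == 0:
                rows.append((module, trait, np.nan, np.nan))
                continue
            r = float(np.corrcoef(e, code)[0, 1])
            r = np.clip(r, -1.0, 1.0)
            if abs(r) >= 1.0:
                p = 0.0
            else:
                tstat = r * np.sqrt((n - 2) / (1.0 - r * r))
                p = 2.0 * t_dist.sf(abs(tstat), n - 2)
            rows.append((module, trait, r, p))
    out = pd.DataFrame(rows, columns=["module", "trait", "r", "p"])
    pvals = out["p"].to_numpy()
    if use_storey:
        try:
            out["q"] = storey_qvalue(pvals)
        except ValueError:
            out["q"] = bh_fdr(pvals)
    else:
        out["q"] = bh_fdr(pvals)
    out["significant"] = out["q"] < 0.05
    return out.set_index(["module", "trait"])


@dataclasses.dataclass
class ConnectivityStats:
    per_gene: pd.DataFrame       # degree, clustering, neighborhood_connectivity
    per_module: pd.DataFrame     # averages + hub genes
    threshold_counts: dict       # report threshold -> genes with >= 1 edge
    network_avg: dict


def connectivity_stats(corr: np.ndarray, gene_ids, partition: ModulePartition,
                       config: NetworkConfig | None = None,
                       annotations: pd.DataFrame | None = None) -> ConnectivityStats:
    """Degree, clustering coefficient and neighborhood connectivity.

    The graph has an edge wherever |r| >= edge_filter_r.  C is the
    fraction of realized links among a node's neighbors; NC is the mean
    degree over neighbors.  Hubs are the genes with maximal
    within-module connectivity (sum of within-module |r| edges); the
    secondary hub is the next-highest gene carrying annotation text.
    """
    config = config or NetworkConfig()
    gene_ids = list(gene_ids)
    r = np.abs(np.asarray(corr, dtype=float))
    np.fill_diagonal(r, 0.0)
    adj = (r >= config.edge_filter_r)
    a = adj.astype(float)
    deg = a.sum(axis=1)
    triangles = np.einsum("ij,jk,ki->i", a, a, a) / 2.0
    possible = deg * (deg - 1) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        cc = np.where(possible > 0, triangles / possible, 0.0)
        nc = np.where(deg > 0, (a @ deg) / np.maximum(deg, 1.0), 0.0)
    per_gene = pd.DataFrame({
        "module": partition.labels.reindex(gene_ids).to_numpy(),
        "degree": deg,
        "clustering": cc,
        "neighborhood_connectivity": nc,
    }, index=gene_ids)

    has_annotation = None
    if annotations is not None:
        ann = annotations["annotation"].reindex(gene_ids).fillna("")
        has_annotation = ann.str.len() > 0

    mod_rows = []
    for module in partition.module_names:
        members = partition.members(module)
        mi = [gene_ids.index(g) for g in members]
        sub_r = r[np.ix_(mi, mi)].copy()
        sub_r[sub_r < config.edge_filter_r] = 0.0
        within_k = sub_r.sum(axis=1)
        order = np.argsort(-within_k, kind="mergesort")
        hub = members[order[0]]
        secondary = ""
        for oi in order[1:]:
            g = members[oi]
            if has_annotation is None or has_annotation[g]:
                secondary = g
                break
        pg = per_gene.loc[members]
        mod_rows.append((module, len(members), pg["degree"].mean(),
                         pg["clustering"].mean(),
                         pg["neighborhood_connectivity"].mean(), hub, secondary))
    per_module = pd.DataFrame(mod_rows, columns=[
        "module", "n_genes", "avg_degree", "avg_clustering",
        "avg_neighborhood_connectivity", "hub", "secondary_hub",
    ]).set_index("module")
    threshold_counts = {
        thr: int(((r >= thr).sum(axis=1) > 0).sum())
        for thr in config.report_thresholds
    }
    network_avg = {
        "avg_degree": float(deg.mean()),
        "avg_clustering": float(cc.mean()),
        "avg_neighborhood_connectivity": float(nc.mean()),
    }
    return ConnectivityStats(per_gene, per_module, threshold_counts, network_avg)


def export_network(corr: np.ndarray, gene_ids, partition: ModulePartition,
                   config: NetworkConfig | None = None, de_flags=None,
                   outdir=None):
    """Edge/node tables and a GraphML graph filtered at |r| >= edge_filter_r."""
    import networkx as nx

    config = config or NetworkConfig()
    gene_ids = list(gene_ids)
    r = np.asarray(corr, dtype=float)
    g = nx.Graph()
    labels = partition.labels.reindex(gene_ids)
    for gene in gene_ids:
        attrs = {"module": str(labels[gene])}
        if de_flags is not None:
            attrs["de"] = bool(pd.Series(de_flags).reindex([gene]).fillna(False).iloc[0])
        g.add_node(gene, **attrs)
    iu = np.triu_indices(len(gene_ids), k=1)
    mask = np.abs(r[iu]) >= config.edge_filter_r
    for i, j, w in zip(iu[0][mask], iu[1][mask], r[iu][mask]):
        g.add_edge(gene_ids[i], gene_ids[j], r=float(w))
    if outdir is not None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        nodes = pd.DataFrame(
            [(n, d.get("module", GREY), d.get("de", False)) for n, d in g.nodes(data=True)],
            columns=["gene_id", "module", "de"])
        edges = pd.DataFrame(
            [(u, v, d["r"]) for u, v, d in g.edges(data=True)],
            columns=["gene1", "gene2", "r"])
        nodes.to_csv(out / "nodes.tsv", sep="\t", index=False)
        edges.to_csv(out / "edges.tsv", sep="\t", index=False)
        nx.write_graphml(g, out / "network.graphml")
    return g


@dataclasses.dataclass
class NetworkResult:
    config: NetworkConfig
    beta: int
    fit_table: pd.DataFrame
    gene_ids: list
    correlations: np.ndarray
    partition: ModulePartition
    n_modules_before_merge: int
    eigengenes: pd.DataFrame
    module_trait: pd.DataFrame
    connectivity: ConnectivityStats


def build_network(log2_cpm: pd.DataFrame, cpm: pd.DataFrame, samples,
                  config: NetworkConfig | None = None,
                  annotations: pd.DataFrame | None = None) -> NetworkResult:
    """Run the full network pipeline on normalized expression.

    The variance filter ranks genes on log2 CPM by default (raw CPM
    variance mostly ranks abundance); the correlation network itself is
    computed on log2 CPM.
    """
    config = config or NetworkConfig()
    rank_on = cpm if config.variance_on == "cpm" else log2_cpm
    top = select_top_variance(rank_on, config.top_variance_fraction)
    expr = log2_cpm.loc[top.index]
    if config.beta == "auto":
        beta, fit_table = pick_soft_threshold(expr, config)
    else:
        beta, fit_table = int(config.beta), pd.DataFrame()
    corr = correlation_matrix(expr)
    adj = adjacency_matrix(corr, beta, config.network_sign)
    tom = tom_similarity(adj)
    partition = detect_modules(tom, expr.index, config)
    n_before = partition.n_modules()
    partition, eigengenes = merge_modules(expr, partition, config.merge_dissimilarity)
    if eigengenes.shape[1] >= 1:
        module_trait = module_trait_correlation(eigengenes, samples)
    else:
        module_trait = pd.DataFrame(
            columns=["r", "p", "q", "significant"],
            index=pd.MultiIndex.from_arrays([[], []], names=["module", "trait"]))
    conn = connectivity_stats(corr, list(expr.index), partition, config, annotations)
    return NetworkResult(config, beta, fit_table, list(expr.index), corr,
                         partition, n_before, eigengenes, module_trait, conn)
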