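"""End-to-end orchestration of the divergence analysis.

Runs the stage order of the study design on synthetic or user-supplied
data: filter -> TMM -> dispersions -> six LRT comparisons -> candidate
matching and calibration -> divergence trees -> DE-count ratio tests ->
co-expression network -> pathway concentration tests, plus the
ordination (classical MDS) and bootstrap-supported hierarchical
clustering reports, and a machine-readable JSON summary.
"""

from __future__ import annotations

import dataclasses
import json
import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from . import candidates as cand_mod
from . import divergence as div_mod
from . import pathways as pw_mod
from . import ratios as ratio_mod
from .de import CANDIDATE_COMPARISONS, run_comparisons
from .network import NetworkConfig, NetworkResult, build_network
from .preprocess import CountMatrix, SampleTable, normalize
from .simulate import SimulationConfig, SyntheticDataset, simulate_all

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "mds_coordinates",
    "cluster_with_support",
    "run_all",
]


def mds_coordinates(log2_cpm: pd.DataFrame, gene_ids=None,
                    top_n: int | None = None) -> pd.DataFrame:
    """Classical (Torgerson) MDS of pairwise expression distances.

    The distance between two samples is the root-mean-square log2
    difference over the selected genes; with ``top_n`` the per-pair
    largest |difference| genes are used (the plotMDS convention),
    otherwise the supplied ``gene_ids`` (or all genes).  Returns
    samples x 2 coordinates scaled by the square root of each
    eigenvalue; negative leading eigenvalues are clipped with a warning.
    """
    expr = log2_cpm if gene_ids is None else log2_cpm.loc[list(gene_ids)]
    x = expr.to_numpy(dtype=float)
    n = x.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples for MDS")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff2 = (x[:, i] - x[:, j]) ** 2
            if top_n is not None and top_n < diff2.size:
                diff2 = np.sort(diff2)[-top_n:]
            d[i, j] = d[j, i] = np.sqrt(diff2.mean())
    j_mat = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j_mat @ (d ** 2) @ j_mat
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if (vals[:2] < -1e-10).any():
        warnings.warn("negative leading MDS eigenvalues clipped to zero")
    vals = np.clip(vals, 0.0, None)
    coords = vecs[:, :2] * np.sqrt(vals[:2])[None, :]
    return pd.DataFrame(coords, index=expr.columns, columns=["dim1", "dim2"])


def _sample_linkage(x: np.ndarray):
    """Average-linkage tree on 1 - Pearson correlation between samples."""
    r = np.corrcoef(x.T)
    diss = 1.0 - np.clip(np.nan_to_num(r, nan=0.0), -1.0, 1.0)
    np.fill_diagonal(diss, 0.0)
    diss = (diss + diss.T) / 2.0
    return hierarchy.linkage(squareform(diss, checks=False), method="average")


def _cluster_sets(link, n: int) -> list[frozenset]:
    tree = hierarchy.to_tree(link)
    sets = []

    def walk(node):
        if node.is_leaf():
            return frozenset([node.id])
        s = walk(node.left) | walk(node.right)
        sets.append(s)
        return s

    walk(tree)
    return sets


def cluster_with_support(expr: pd.DataFrame, n_boot: int = 100,
                         seed: int = 0):
    """Sample dendrogram with plain gene-bootstrap cluster support.

    Samples are clustered on 1 - Pearson correlation (average linkage);
    genes are resampled with replacement ``n_boot`` times and support is
    the percentage of bootstrap dendrograms containing each original
    cluster (this is ordinary bootstrap support, not the multiscale
    approximately-unbiased variant).  Returns (linkage, support table).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    x = expr.to_numpy(dtype=float)
    link = _sample_linkage(x)
    originals = _cluster_sets(link, x.shape[1])
    counts = {s: 0 for s in originals}
    rng = np.random.default_rng(seed)
    for _ in range(n_boot):
        idx = rng.integers(0, x.shape[0], size=x.shape[0])
        bl = _sample_linkage(x[idx])
        bsets = set(_cluster_sets(bl, x.shape[1]))
        for s in originals:
            if s in bsets:
                counts[s] += 1
    labels = list(expr.columns)
    rows = [(";".join(sorted(labels[i] for i in s)), len(s),
             100.0 * counts[s] / n_boot) for s in originals]
    support = pd.DataFrame(rows, columns=["members", "size", "support_pct"])
    return link, support


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PipelineConfig:
    simulation: SimulationConfig = dataclasses.field(default_factory=SimulationConfig)
    # desk-scale network defaults: modules of ~35 genes need a lower
    # size floor than the study's 40, and the wider variance fraction
    # keeps planted modules plus DE genes inside the network gene set
    # beta fixed at the study's value: auto-selection is unstable on
    # desk-scale block-structured data that is not scale-free
    network: NetworkConfig = dataclasses.field(
        default_factory=lambda: NetworkConfig(min_module_size=25,
                                              top_variance_fraction=0.35,
                                              beta=6))
    alpha: float = 0.05
    n_reps: int = 10000
    n_boot: int = 100
    min_mean_cpm: float = 1.0
    prior_count: float = 2.0
    seed: int = 0
    comparisons: tuple = ("geo_all", "sex_all", "geo_female", "geo_male",
                          "sex_allo", "sex_sym")
    run_clustering: bool = True


@dataclasses.dataclass
class PipelineResult:
    dataset: SyntheticDataset | None
    de_results: dict
    candidate_set: cand_mod.CandidateSet
    calibration: tuple
    divergence_tests: pd.DataFrame
    ratio_results: dict
    network: NetworkResult
    pathway_table: pd.DataFrame
    pathway_tests: dict
    mds: pd.DataFrame | None
    cluster_support: pd.DataFrame | None
    summary: dict


def map_planted_modules(truth: pd.DataFrame, partition) -> dict[str, str]:
    """Match planted module labels to detected modules by plurality overlap."""
    mapping = {}
    labels = partition.labels
    for planted in sorted(set(truth["true_module"]) - {""}):
        genes = truth.index[truth["true_module"] == planted]
        hits = labels.reindex(genes).dropna()
        hits = hits[hits != "grey"]
        if len(hits):
            mapping[planted] = hits.value_counts().idxmax()
    return mapping


def run_all(config: PipelineConfig | None = None,
            dataset: SyntheticDataset | None = None) -> PipelineResult:
    """Execute every analysis stage and assemble the summary.

    With no ``dataset``, one is simulated from ``config.simulation``
    (seeded by ``config.seed``).
    """
    config = config or PipelineConfig()
    if dataset is None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        dataset = simulate_all(sim)
    counts, samples = dataset.counts, dataset.samples

    filtered, norm = normalize(counts, config.min_mean_cpm, config.prior_count)
    de_results = run_comparisons(filtered, samples, list(config.comparisons),
                                 alpha=config.alpha, norm=norm)

    # candidate synaptic genes
    candidate_set = cand_mod.match_candidates(
        dataset.annotations, expressed_gene_ids=filtered.gene_ids)
    cand_ids = [g for g in candidate_set.gene_ids]
    sig_union = np.zeros(len(filtered.gene_ids), dtype=bool)
    for c in CANDIDATE_COMPARISONS:
        if c in de_results:
            sig_union |= de_results[c].table["significant"].to_numpy()
    sig_series = pd.Series(sig_union, index=filtered.gene_ids)
    n_obs = int(sig_series.reindex(cand_ids).fillna(False).sum())
    if len(cand_ids):
        calibration = cand_mod.random_set_calibration(
            sig_series, len(cand_ids), n_obs,
            n_reps=config.n_reps, seed=config.seed)
    else:
        calibration = (float("nan"), float("nan"))

    # expression-divergence trees
    std = div_mod.standardize_genes(norm.log2_cpm)
    gm = div_mod.group_mean_matrix(std, samples)
    tips = div_mod.tip_lengths_per_gene(gm)
    cand_flags = pd.Series(False, index=tips.index)
    cand_flags[cand_flags.index.isin(cand_ids)] = True
    if cand_flags.sum() >= 2 and (~cand_flags).sum() >= 2:
        div_tests = div_mod.divergence_tests(
            tips, cand_flags, n_reps=config.n_reps, seed=config.seed)
    else:
        div_tests = pd.DataFrame(columns=["pair", "set", "statistic", "p", "fdr"])

    # transcriptome-wide ratio tests
    tables = ratio_mod.build_comparison_tables(de_results)
    ratio_results = {}
    for name, tbl in tables.items():
        try:
            ratio_results[name] = ratio_mod.ratio_randomization_test(
                tbl, n_reps=config.n_reps, seed=config.seed)
        except (ZeroDivisionError, ValueError) as exc:
            warnings.warn(f"ratio test {name} skipped: {exc}")

    # co-expression network
    net = build_network(norm.log2_cpm, norm.cpm, samples, config.network,
                        annotations=dataset.annotations)

    # pathway concentration tests on the planted table, mapped to
    # detected modules
    pw_table = pw_mod.flag_synaptic(dataset.pathways)
    mapping = map_planted_modules(dataset.truth, net.partition)
    pw_table = pw_table[pw_table["module"].isin(mapping)].copy()
    pw_table["module"] = pw_table["module"].map(mapping)
    mt = net.module_trait
    sig_any = sorted({m for (m, tr) in mt.index[mt["significant"]]})
    sig_geo = sorted({m for (m, tr) in mt.index[mt["significant"]]
                      if tr == "geography"})
    pathway_tests: dict = {}
    if len(pw_table):
        pathway_tests["per_module"] = pw_mod.per_module_concentration_test(
            pw_table, n_reps=config.n_reps, seed=config.seed)
        present = set(pw_table["module"])
        if present & set(sig_any) and present - set(sig_any):
            pathway_tests["overall"] = pw_mod.overall_concentration_test(
                pw_table, sig_any, n_reps=config.n_reps, seed=config.seed)
            pathway_tests["mean_per_significant"] = pw_mod.mean_per_significant_test(
                pw_table, sig_any, n_reps=config.n_reps, seed=config.seed)
        if present & set(sig_geo) and present - set(sig_geo):
            try:
                pathway_tests["geo_ratio"] = pw_mod.geo_ratio_test(
                    pw_table, sig_geo, n_reps=config.n_reps, seed=config.seed)
            except ZeroDivisionError as exc:
                warnings.warn(f"geo ratio test skipped: {exc}")

    # ordination and clustering reports
    de_union = sorted({g for r in de_results.values() for g in r.significant_genes})
    mds = cluster_support = None
    if len(de_union) >= 2:
        mds = mds_coordinates(norm.log2_cpm, gene_ids=de_union)
        if config.run_clustering:
            _, cluster_support = cluster_with_support(
                norm.log2_cpm.loc[de_union], n_boot=config.n_boot,
                seed=config.seed)

    de_counts = {name: r.n_significant for name, r in de_results.items()}
    for name, r in de_results.items():  # internal consistency
        assert de_counts[name] == int(r.table["significant"].sum())
    summary = {
        "seed": config.seed,
        "alpha": config.alpha,
        "n_reps": config.n_reps,
        "n_genes_input": len(counts.gene_ids),
        "n_genes_kept": len(filtered.gene_ids),
        "de_counts": de_counts,
        "n_candidates": len(cand_ids),
        "n_candidates_significant": n_obs,
        "calibration_mean_sig": calibration[0],
        "calibration_p": calibration[1],
        "ratio_tests": {
            name: {"observed": res.observed_statistic, "p": res.p}
            for name, res in ratio_results.items()
        },
        "divergence_min_fdr": (float(div_tests["fdr"].min())
                               if len(div_tests) else None),
        "network": {
            "beta": net.beta,
            "n_genes": len(net.gene_ids),
            "n_modules": net.partition.n_modules(),
            "n_modules_before_merge": net.n_modules_before_merge,
            "significant_modules_geography": sig_geo,
            "significant_modules_any": sig_any,
        },
        "module_trait": [
            {"module": m, "trait": tr, "r": None if np.isnan(row["r"]) else
             round(float(row["r"]), 6), "q": None if np.isnan(row["q"]) else
             round(float(row["q"]), 6)}
            for (m, tr), row in mt.iterrows()
        ],
        "pathway_tests": {
            name: ({"observed": res.observed_statistic, "p": res.p}
                   if isinstance(res, ratio_mod.RandTestResult)
                   else res[["n_pathways", "n_synaptic", "p", "q"]]
                   .reset_index().to_dict(orient="records"))
            for name, res in pathway_tests.items()
        },
    }
    return PipelineResult(dataset, de_results, candidate_set, calibration,
                          div_tests, ratio_results, net, pw_table,
                          pathway_tests, mds, cluster_support, summary)


def write_summary(result: PipelineResult, path) -> None:
    with open(path, "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True, default=float)
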