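"""Negative-binomial differential expression testing.

Implements the classic count-based DE workflow: Cox-Reid adjusted
profile likelihood (APL) dispersion estimation with empirical-Bayes
shrinkage toward an abundance trend, NB generalized linear models with a
group-mean parametrization and log effective-library-size offsets,
likelihood-ratio contrasts against a chi-square null, and
Benjamini-Hochberg / Storey multiple-testing corrections.

The six comparisons of the study design (geography and sex contrasts,
pooled and within-subset) are exposed through :func:`run_comparisons`.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from .preprocess import CountMatrix, NormalizedExpression, SampleTable, log_cpm, tmm_factors

__all__ = [
    "DispersionEstimates",
    "NBGLMFit",
    "DEResult",
    "COMPARISONS",
    "estimate_dispersions",
    "fit_nb_glm",
    "lrt_contrast",
    "bh_fdr",
    "storey_qvalue",
    "run_comparisons",
]

# Log2-dispersion grid spanning BCV ~0.004 to 4; spacing 0.25 in log2
# keeps the parabolic refinement accurate to well under the sampling
# noise of any realistic estimate.
_PHI_GRID = 2.0 ** np.linspace(-16.0, 4.0, 81)


# ---------------------------------------------------------------------------
# NB likelihood machinery (vectorized over genes)
# ---------------------------------------------------------------------------

def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi) -> np.ndarray:
    """Elementwise NB log-likelihood; Poisson limit for tiny dispersion.

    ``y`` and ``mu`` broadcast; ``phi`` is scalar or broadcastable.
    Entries with ``mu == 0`` contribute 0 when ``y == 0`` and -inf
    otherwise.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    out = np.zeros(np.broadcast_shapes(y.shape, mu.shape, phi.shape))
    pois = np.broadcast_to(phi < 1e-12, out.shape)
    mu_b = np.broadcast_to(mu, out.shape)
    y_b = np.broadcast_to(y, out.shape)
    phi_b = np.broadcast_to(phi, out.shape)
    zero = mu_b <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        # Poisson branch
        lp = y_b * np.log(mu_b) - mu_b - gammaln(y_b + 1.0)
        # NB branch
        r = 1.0 / np.where(phi_b > 0, phi_b, 1.0)
        ln = (
            gammaln(y_b + r) - gammaln(r) - gammaln(y_b + 1.0)
            + r * np.log(r / (r + mu_b))
            + y_b * np.log(mu_b / (r + mu_b))
        )
    out = np.where(pois, lp, ln)
    out = np.where(zero & (y_b == 0), 0.0, out)
    out = np.where(zero & (y_b > 0), -np.inf, out)
    return out


def _fit_group(y: np.ndarray, offsets: np.ndarray, phi) -> tuple[np.ndarray, bool]:
    """MLE of a single group-mean coefficient per gene.

    ``y`` is genes x samples (the samples of one group), ``offsets`` the
    log effective library sizes of those samples.  Returns per-gene beta
    (log scale; -inf for all-zero genes) and a convergence flag.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    e = np.exp(offsets)  # (n,)
    tot = y.sum(axis=1)
    with np.errstate(divide="ignore"):
        beta = np.log(tot / e.sum())  # -inf for all-zero genes
    active = tot > 0
    phi = np.asarray(phi, dtype=float)
    phi_a = phi[active, None] if phi.ndim else phi  # per-gene column or scalar
    converged = True
    b = beta[active].copy()
    ya = y[active]
    for _ in range(100):
        mu = np.exp(b)[:, None] * e[None, :]
        denom = 1.0 + phi_a * mu
        score = ((ya - mu) / denom).sum(axis=1)
        info = (mu / denom).sum(axis=1)
        step = np.clip(score / np.maximum(info, 1e-12), -5.0, 5.0)
        b += step
        if np.max(np.abs(step), initial=0.0) < 1e-10:
            break
    else:
        converged = False
    beta[active] = b
    return beta, converged


def _group_ll_and_info(y, offsets, groups_idx, phi):
    """Fit all group means; return (beta GxK, ll G, fisher-info GxK)."""
    y = np.asarray(y, dtype=float)
    G = y.shape[0]
    K = len(groups_idx)
    phi = np.asarray(phi, dtype=float)
    beta = np.full((G, K), -np.inf)
    ll = np.zeros(G)
    info = np.zeros((G, K))
    for k, idx in enumerate(groups_idx):
        yk = y[:, idx]
        ok = offsets[idx]
        bk, _ = _fit_group(yk, ok, phi)
        beta[:, k] = bk
        with np.errstate(over="ignore"):
            mu = np.exp(bk)[:, None] * np.exp(ok)[None, :]
        phi_col = phi[:, None] if phi.ndim else phi
        ll += _nb_loglik(yk, mu, phi_col).sum(axis=1)
        info[:, k] = (mu / (1.0 + phi_col * mu)).sum(axis=1)
    return beta, ll, info


def _apl(y, offsets, groups_idx, phi) -> np.ndarray:
    """Cox-Reid adjusted profile log-likelihood per gene at dispersion phi."""
    _, ll, info = _group_ll_and_info(y, offsets, groups_idx, phi)
    with np.errstate(divide="ignore"):
        adj = 0.5 * np.where(info > 0, np.log(info), 0.0).sum(axis=1)
    return ll - adj


def _argmax_parabolic(values: np.ndarray, log_grid: np.ndarray) -> np.ndarray:
    """Grid argmax with parabolic refinement, rows = curves.

    ``values`` is (curves x grid); returns the refined maximizing phi per
    curve (in natural units, grid is log2 phi).
    """
    v = np.atleast_2d(values)
    i = np.argmax(v, axis=1)
    i = np.clip(i, 1, v.shape[1] - 2)
    x0, x1, x2 = log_grid[i - 1], log_grid[i], log_grid[i + 1]
    y0 = v[np.arange(len(i)), i - 1]
    y1 = v[np.arange(len(i)), i]
    y2 = v[np.arange(len(i)), i + 1]
    denom = (y0 - 2.0 * y1 + y2)
    with np.errstate(divide="ignore", invalid="ignore"):
        shift = 0.5 * (y0 - y2) / denom
    shift = np.where(np.isfinite(shift), np.clip(shift, -1.0, 1.0), 0.0)
    # at interior maxima denom < 0; otherwise stay on the grid point
    shift = np.where(denom < 0, shift, 0.0)
    x = x1 + shift * (x1 - x0)
    # boundary maxima stay on the boundary
    raw = np.argmax(v, axis=1)
    x = np.where(raw == 0, log_grid[0], x)
    x = np.where(raw == v.shape[1] - 1, log_grid[-1], x)
    return 2.0 ** x


@dataclasses.dataclass
class DispersionEstimates:
    """Common, trended and tagwise NB dispersions (phi = BCV^2)."""

    common: float
    trended: pd.Series
    tagwise: pd.Series
    avg_log2_cpm: pd.Series
    all_zero: pd.Series

    @property
    def bcv(self) -> pd.Series:
        return np.sqrt(self.tagwise)


def _interp_weights(x: np.ndarray, centers: np.ndarray):
    """Linear interpolation weights of x onto sorted bin centers."""
    hi = np.searchsorted(centers, x)
    hi = np.clip(hi, 1, len(centers) - 1)
    lo = hi - 1
    span = centers[hi] - centers[lo]
    w = np.where(span > 0, (x - centers[lo]) / np.where(span > 0, span, 1.0), 0.0)
    w = np.clip(w, 0.0, 1.0)
    return lo, hi, w


def estimate_dispersions(counts: CountMatrix, norm: NormalizedExpression,
                         groups: pd.Series, prior_df: float = 10.0,
                         n_bins: int = 10, robust: bool = False) -> DispersionEstimates:
    """Estimate common, trended and tagwise dispersions by Cox-Reid APL.

    The common value maximizes the summed APL; the trend maximizes a
    locally shared APL (per-gene average within abundance deciles,
    linearly interpolated between bin centers); tagwise values maximize
    ``APL_g + G0 * sharedAPL_g`` with ``G0 = prior_df / df_residual``
    (empirical-Bayes shrinkage toward the trend; ``prior_df = inf``
    returns the trend exactly).  ``robust=True`` winsorizes the per-gene
    APL curves within bins before averaging, damping outlier genes.
    """
    groups = groups.reindex(counts.sample_ids)
    labels = sorted(groups.unique())
    groups_idx = [np.where(groups.to_numpy() == g)[0] for g in labels]
    if any(len(ix) == 0 for ix in groups_idx):
        raise ValueError("empty group in design")
    n, K = len(groups), len(labels)
    df_resid = n - K
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom for dispersion estimation")
    y = counts.values
    offsets = np.log(norm.effective_lib_size.reindex(counts.sample_ids).to_numpy())
    log_grid = np.log2(_PHI_GRID)
    apl = np.stack([_apl(y, offsets, groups_idx, phi) for phi in _PHI_GRID], axis=1)

    all_zero = y.sum(axis=1) == 0
    ok = ~all_zero
    common = float(_argmax_parabolic(apl[ok].sum(axis=0)[None, :], log_grid)[0])

    # abundance bins on average log2 CPM
    alc = norm.log2_cpm.mean(axis=1).to_numpy()
    n_ok = int(ok.sum())
    nb = max(1, min(n_bins, n_ok // 20 if n_ok >= 40 else 1))
    qs = np.quantile(alc[ok], np.linspace(0, 1, nb + 1))
    bin_of = np.clip(np.searchsorted(qs[1:-1], alc, side="right"), 0, nb - 1)
    bin_apl = np.zeros((nb, apl.shape[1]))
    centers = np.zeros(nb)
    for b in range(nb):
        mask = ok & (bin_of == b)
        if not mask.any():
            bin_apl[b] = apl[ok].mean(axis=0)
            centers[b] = alc[ok].mean()
            continue
        curves = apl[mask]
        if robust and curves.shape[0] >= 10:
            lo_q = np.quantile(curves, 0.05, axis=0)
            hi_q = np.quantile(curves, 0.95, axis=0)
            curves = np.clip(curves, lo_q, hi_q)
        bin_apl[b] = curves.mean(axis=0)
        centers[b] = alc[mask].mean()
    order = np.argsort(centers)
    centers, bin_apl = centers[order], bin_apl[order]

    if nb == 1:
        shared = np.broadcast_to(bin_apl[0], apl.shape).copy()
    else:
        lo, hi, w = _interp_weights(alc, centers)
        shared = (1.0 - w)[:, None] * bin_apl[lo] + w[:, None] * bin_apl[hi]

    trended = _argmax_parabolic(shared, log_grid)
    if np.isinf(prior_df):
        tagwise = trended.copy()
    else:
        g0 = prior_df / df_resid
        tagwise = _argmax_parabolic(apl + g0 * shared, log_grid)
    # all-zero genes carry no information: assign the trend value
    tagwise[all_zero] = trended[all_zero]
    idx = counts.counts.index
    return DispersionEstimates(
        common=common,
        trended=pd.Series(trended, index=idx, name="trended"),
        tagwise=pd.Series(tagwise, index=idx, name="tagwise"),
        avg_log2_cpm=pd.Series(alc, index=idx, name="avg_log2_cpm"),
        all_zero=pd.Series(all_zero, index=idx, name="all_zero"),
    )


# ---------------------------------------------------------------------------
# Per-gene GLM fits and LRT
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class NBGLMFit:
    """Fitted NB GLM with a group-mean design (per gene or gene block)."""

    group_labels: list
    coefficients: np.ndarray  # genes x groups, natural-log scale
    fitted: np.ndarray        # genes x samples
    loglik: np.ndarray        # per gene
    n_params: int
    converged: bool


def fit_nb_glm(counts_g, groups, offsets, dispersion) -> NBGLMFit:
    """Fit NB GLMs with one coefficient per group (log link, offsets).

    ``counts_g`` may be a single gene (1-D) or genes x samples;
    ``groups`` is a length-n label sequence; ``offsets`` the log
    effective library sizes; ``dispersion`` scalar or per-gene.
    """
    y = np.atleast_2d(np.asarray(counts_g, dtype=float))
    offsets = np.asarray(offsets, dtype=float)
    if not np.isfinite(offsets).all():
        raise ValueError("offsets must be finite")
    phi = np.asarray(dispersion, dtype=float)
    if (phi < 0).any():
        raise ValueError("dispersion must be >= 0")
    groups = np.asarray(groups)
    labels = sorted(pd.unique(groups).tolist())
    groups_idx = [np.where(groups == g)[0] for g in labels]
    beta, ll, _ = _group_ll_and_info(y, offsets, groups_idx, phi)
    with np.errstate(over="ignore"):
        fitted = np.zeros_like(y)
        for k, idx in enumerate(groups_idx):
            fitted[:, idx] = np.exp(beta[:, k])[:, None] * np.exp(offsets[idx])[None, :]
    fitted = np.nan_to_num(fitted, nan=0.0)
    return NBGLMFit(labels, beta, fitted, ll, n_params=len(labels), converged=True)


def lrt_contrast(fit_full: NBGLMFit, fit_null: NBGLMFit):
    """Likelihood-ratio test of nested group-mean GLMs.

    Returns per-gene (statistic, p).  The statistic is clipped at zero;
    the null distribution is chi-square with df equal to the coefficient
    difference.
    """
    df = fit_full.n_params - fit_null.n_params
    if df < 0:
        raise ValueError("null model must be nested in the full model")
    if df == 0:
        stat = np.zeros_like(fit_full.loglik)
        return stat, np.ones_like(stat)
    stat = 2.0 * (fit_full.loglik - fit_null.loglik)
    stat = np.where(np.isfinite(stat), stat, 0.0)
    stat = np.clip(stat, 0.0, None)
    p = chi2.sf(stat, df)
    return stat, p


# ---------------------------------------------------------------------------
# Multiple testing
# ---------------------------------------------------------------------------

def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN passed through)."""
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if (pv < 0).any() or (pv > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[ok] = res
    return out


def storey_qvalue(p_values, lambdas=None) -> np.ndarray:
    """Storey q-values with a smoother pi0 estimate.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is computed over a
    lambda grid and smoothed with a cubic fit evaluated at the largest
    lambda.  Estimates outside (0, 1] fall back to pi0 = 1 (plain BH)
    with a warning.
    """
    p = np.asarray(p_values, dtype=float)
    ok = ~np.isnan(p)
    pv = p[ok]
    if pv.size < 2:
        raise ValueError("need at least 2 p-values for pi0 estimation")
    if (pv < 0).any() or (pv > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if lambdas is None:
        lambdas = np.arange(0.05, 0.95, 0.05)
    lambdas = np.asarray(lambdas, dtype=float)
    m = pv.size
    if m < 20:
        # the pi0 smoother is unstable on tiny families; be conservative
        out = np.full(p.shape, np.nan)
        out[ok] = bh_fdr(pv)
        return out
    pi0_l = np.array([(pv > lam).sum() / (m * (1.0 - lam)) for lam in lambdas])
    if len(lambdas) >= 4:
        coef = np.polyfit(lambdas, pi0_l, 3)
        pi0 = float(np.polyval(coef, lambdas.max()))
    else:
        pi0 = float(pi0_l[-1])
    pi0 = min(pi0, 1.0)
    if pi0 <= 0:
        warnings.warn("pi0 estimate <= 0; falling back to pi0 = 1 (BH)")
        pi0 = 1.0
    out = np.full(p.shape, np.nan)
    out[ok] = np.minimum(pi0 * bh_fdr(pv), 1.0)
    return out


# ---------------------------------------------------------------------------
# The six study comparisons
# ---------------------------------------------------------------------------

# comparison name -> (design, (group_a, group_b)); logFC = log2(a) - log2(b).
# Positive logFC means overexpression in sympatry (geography contrasts) or
# in females (sex contrasts).
COMPARISONS = {
    "geo_all": ("geography", ("sympatric", "allopatric")),
    "sex_all": ("sex", ("female", "male")),
    "geo_female": ("group", ("sympatric_female", "allopatric_female")),
    "geo_male": ("group", ("sympatric_male", "allopatric_male")),
    "sex_allo": ("group", ("allopatric_female", "allopatric_male")),
    "sex_sym": ("group", ("sympatric_female", "sympatric_male")),
}

_NUMERIC_ALIASES = {1: "geo_all", 2: "sex_all", 3: "geo_female",
                    4: "geo_male", 5: "sex_allo", 6: "sex_sym"}

#: The three comparisons used for the candidate synaptic gene set
CANDIDATE_COMPARISONS = ("geo_all", "geo_female", "geo_male")


@dataclasses.dataclass
class DEResult:
    """Per-gene DE table for one comparison."""

    comparison: str
    table: pd.DataFrame  # logFC, avg_log2_cpm, lrt_stat, p, fdr, significant
    alpha: float

    @property
    def significant_genes(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())


def run_comparisons(counts: CountMatrix, samples: SampleTable,
                    which=None, alpha: float = 0.05,
                    norm: NormalizedExpression | None = None,
                    dispersions: DispersionEstimates | None = None,
                    subset_gene_ids=None, prior_df: float = 10.0) -> dict[str, DEResult]:
    """Run NB-GLM LRT differential expression for the requested comparisons.

    Dispersions are estimated once on the four-group design and the
    tagwise values reused across contrasts.  FDR (BH) is applied within
    each comparison separately; when ``subset_gene_ids`` is given (the
    candidate-set mode) the correction family is that subset only.
    """
    samples.check_matches(counts)
    if which is None:
        which = list(COMPARISONS)
    which = [_NUMERIC_ALIASES.get(w, w) for w in which]
    unknown = [w for w in which if w not in COMPARISONS]
    if unknown:
        raise ValueError(f"unknown comparison(s): {unknown}")
    meta = samples.table.loc[counts.sample_ids]
    if norm is None:
        norm = log_cpm(counts, tmm_factors(counts))
    if dispersions is None:
        dispersions = estimate_dispersions(counts, norm, meta["group"], prior_df=prior_df)
    phi = dispersions.tagwise.to_numpy()
    offsets = np.log(norm.effective_lib_size.reindex(counts.sample_ids).to_numpy())
    y = counts.values
    alc = dispersions.avg_log2_cpm

    results: dict[str, DEResult] = {}
    for name in which:
        factor, (ga, gb) = COMPARISONS[name]
        lab = meta[factor].to_numpy()
        sel = np.isin(lab, [ga, gb])
        if (lab == ga).sum() == 0 or (lab == gb).sum() == 0:
            raise ValueError(f"comparison {name}: empty group")
        ysub, osub, lsub = y[:, sel], offsets[sel], lab[sel]
        full = fit_nb_glm(ysub, lsub, osub, phi)
        null = fit_nb_glm(ysub, np.zeros(sel.sum(), dtype=int), osub, phi)
        stat, p = lrt_contrast(full, null)
        ia, ib = full.group_labels.index(ga), full.group_labels.index(gb)
        with np.errstate(invalid="ignore"):
            lfc = (full.coefficients[:, ia] - full.coefficients[:, ib]) / np.log(2.0)
        table = pd.DataFrame({
            "logFC": lfc,
            "avg_log2_cpm": alc.to_numpy(),
            "lrt_stat": stat,
            "p": p,
        }, index=counts.counts.index)
        if subset_gene_ids is not None:
            table = table.loc[[g for g in subset_gene_ids if g in table.index]]
        table["fdr"] = bh_fdr(table["p"].to_numpy())
        table["significant"] = table["fdr"] < alpha
        results[name] = DEResult(name, table, alpha)
    return results
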