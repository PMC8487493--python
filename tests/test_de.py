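"""NB dispersion estimation, GLM fits, LRT and multiple-testing correction."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

import neurodiverge as nd
from neurodiverge.de import CANDIDATE_COMPARISONS, estimate_dispersions


def _simulate_nb(G, groups, mu, phi, seed, lfc=None):
    """NB counts with per-group log2 offsets (None lfc -> null)."""
    rng = np.random.default_rng(seed)
    n = len(groups)
    m = np.full((G, n), float(mu))
    if lfc is not None:
        m[:, np.asarray(groups) == 1] *= 2.0 ** lfc[:, None]
    if phi > 0:
        lam = rng.gamma(1.0 / phi, phi * m)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(m)
    df = pd.DataFrame(counts, index=[f"g{i}" for i in range(G)],
                      columns=[f"s{j}" for j in range(n)])
    return nd.CountMatrix(df)


def _norm_and_groups(cm, groups):
    factors = pd.Series(1.0, index=cm.sample_ids)
    norm = nd.log_cpm(cm, factors, 2.0)
    return norm, pd.Series(groups, index=cm.sample_ids)


class TestDispersions:
    def test_poisson_limit(self):
        groups = [0] * 8 + [1] * 8
        cm = _simulate_nb(2000, groups, mu=200, phi=0.0, seed=1)
        norm, g = _norm_and_groups(cm, groups)
        d = estimate_dispersions(cm, norm, g)
        assert d.common < 0.01

    def test_recovers_bcv_04(self):
        groups = [0] * 8 + [1] * 8
        cm = _simulate_nb(2000, groups, mu=200, phi=0.16, seed=2)
        norm, g = _norm_and_groups(cm, groups)
        d = estimate_dispersions(cm, norm, g)
        assert d.common == pytest.approx(0.16, abs=0.03)
        assert np.median(d.tagwise) == pytest.approx(0.16, abs=0.05)

    def test_infinite_prior_df_gives_trend(self):
        groups = [0] * 4 + [1] * 4
        cm = _simulate_nb(300, groups, mu=100, phi=0.1, seed=3)
        norm, g = _norm_and_groups(cm, groups)
        d = estimate_dispersions(cm, norm, g, prior_df=np.inf)
        assert np.allclose(d.tagwise.to_numpy(), d.trended.to_numpy())

    def test_bcv_is_sqrt_dispersion(self):
        groups = [0] * 4 + [1] * 4
        cm = _simulate_nb(100, groups, mu=50, phi=0.2, seed=4)
        norm, g = _norm_and_groups(cm, groups)
        d = estimate_dispersions(cm, norm, g)
        assert np.allclose(d.bcv.to_numpy() ** 2, d.tagwise.to_numpy())


class TestNBGLM:
    def test_single_group_equal_offsets_mean(self):
        y = np.array([[3, 5, 7, 9]])
        fit = nd.fit_nb_glm(y, ["a"] * 4, np.zeros(4), 0.2)
        assert fit.fitted[0, 0] == pytest.approx(6.0, rel=1e-6)

    def test_poisson_closed_form_coefficients(self):
        y = np.array([[10, 20, 30, 40, 50, 60]])
        groups = np.array([0, 0, 0, 1, 1, 1])
        offsets = np.log(np.array([1e4, 2e4, 1e4, 2e4, 1e4, 3e4]))
        fit = nd.fit_nb_glm(y, groups, offsets, 0.0)
        # Poisson MLE per group: sum(y) / sum(exp(offset))
        for k, g in enumerate([0, 1]):
            sel = groups == g
            expected = np.log(y[0, sel].sum() / np.exp(offsets[sel]).sum())
            assert fit.coefficients[0, k] == pytest.approx(expected, abs=1e-8)

    def test_all_zero_counts_no_nan(self):
        y = np.zeros((1, 4))
        fit = nd.fit_nb_glm(y, [0, 0, 1, 1], np.zeros(4), 0.1)
        assert np.all(fit.fitted == 0.0)
        assert np.isfinite(fit.loglik).all()

    def test_negative_dispersion_errors(self):
        with pytest.raises(ValueError):
            nd.fit_nb_glm(np.ones((1, 4)), [0, 0, 1, 1], np.zeros(4), -0.1)


class TestLRT:
    def test_null_p_uniform(self):
        groups = [0] * 8 + [1] * 8
        cm = _simulate_nb(2000, groups, mu=150, phi=0.16, seed=5)
        offsets = np.log(cm.lib_sizes)
        full = nd.fit_nb_glm(cm.values, groups, offsets, 0.16)
        null = nd.fit_nb_glm(cm.values, [0] * 16, offsets, 0.16)
        _, p = nd.lrt_contrast(full, null)
        assert kstest(p, "uniform").pvalue > 0.01

    def test_power_fourfold_change(self):
        # fixed equal offsets so the planted change is not absorbed by
        # library-size normalization
        lfc = np.full(300, 2.0)
        groups = [0] * 5 + [1] * 5
        cm = _simulate_nb(300, groups, mu=200, phi=0.05, seed=6, lfc=lfc)
        offsets = np.zeros(10)
        full = nd.fit_nb_glm(cm.values, groups, offsets, 0.05)
        null = nd.fit_nb_glm(cm.values, [0] * 10, offsets, 0.05)
        _, p = nd.lrt_contrast(full, null)
        assert np.median(p) < 1e-3

    def test_identical_fits_stat_zero(self):
        y = np.array([[5, 6, 7, 8]])
        fit = nd.fit_nb_glm(y, [0, 0, 1, 1], np.zeros(4), 0.1)
        stat, p = nd.lrt_contrast(fit, fit)
        assert stat[0] == 0.0 and p[0] == 1.0

    def test_non_nested_errors(self):
        y = np.array([[5, 6, 7, 8]])
        full = nd.fit_nb_glm(y, [0, 0, 1, 1], np.zeros(4), 0.1)
        null = nd.fit_nb_glm(y, [0] * 4, np.zeros(4), 0.1)
        with pytest.raises(ValueError):
            nd.lrt_contrast(null, full)

    def test_library_scale_invariance(self):
        y = np.array([[10, 40, 20, 80]], dtype=float)
        groups = [0, 0, 1, 1]
        off = np.log(np.array([1e4, 4e4, 2e4, 8e4]))
        s1, _ = nd.lrt_contrast(nd.fit_nb_glm(y, groups, off, 0.1),
                                nd.fit_nb_glm(y, [0] * 4, off, 0.1))
        off2 = off + np.log(7.0)
        s2, _ = nd.lrt_contrast(nd.fit_nb_glm(y, groups, off2, 0.1),
                                nd.fit_nb_glm(y, [0] * 4, off2, 0.1))
        assert s1[0] == pytest.approx(s2[0], rel=1e-8)


class TestFDR:
    def test_all_ones(self):
        assert np.allclose(nd.bh_fdr([1, 1, 1]), 1.0)

    def test_hand_computed(self):
        # BH on (0.01, 0.02, 0.03, 0.04), m=4: step-up gives all 0.04
        assert np.allclose(nd.bh_fdr([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_single_p(self):
        assert nd.bh_fdr([0.037])[0] == pytest.approx(0.037)

    def test_nan_propagation(self):
        out = nd.bh_fdr([0.01, np.nan, 0.5])
        assert np.isnan(out[1])
        # ranking over the 2 non-NaN values only
        assert out[0] == pytest.approx(0.02)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(11)
        p = rng.uniform(size=200)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(nd.bh_fdr(p), ref)

    def test_monotone_in_rank(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(size=100)
        fdr = nd.bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(fdr[order]) >= -1e-12).all()


class TestStoreyQ:
    def test_pure_null_pi0_near_one(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(size=1000)
        q = nd.storey_qvalue(p)
        bh = nd.bh_fdr(p)
        # q = pi0 * BH with pi0 in [0.8, 1]
        ratio = q[p < 0.9] / bh[p < 0.9]
        assert 0.8 <= ratio.mean() <= 1.0 + 1e-9

    def test_mixture_q_below_bh(self):
        rng = np.random.default_rng(14)
        p = np.concatenate([rng.beta(0.05, 10, 200), rng.uniform(size=800)])
        q = nd.storey_qvalue(p)
        bh = nd.bh_fdr(p)
        i = np.argmin(p)
        assert q[i] < bh[i]

    def test_too_few_pvalues_errors(self):
        with pytest.raises(ValueError):
            nd.storey_qvalue([0.5])


class TestRunComparisons:
    def test_recovery_and_empirical_fdr(self):
        # planted geography effects shared by both sexes, no modules
        cfg = nd.SimulationConfig(seed=21, frac_de_geo_both=0.05,
                                  frac_de_geo_female=0, frac_de_geo_male=0,
                                  frac_de_sex=0, n_modules=0, module_traits=())
        ds = nd.simulate_all(cfg)
        kept, norm = nd.normalize(ds.counts)
        res = nd.run_comparisons(kept, ds.samples, which=["geo_all"], norm=norm)
        sig = res["geo_all"].table["significant"]
        truth = ds.truth["true_lfc_geo"].reindex(sig.index) != 0
        sens = (sig & truth).sum() / truth.sum()
        fdp = (sig & ~truth).sum() / max(sig.sum(), 1)
        assert sens >= 0.7
        assert fdp <= 0.10

    def test_null_world_few_discoveries(self):
        cfg = nd.SimulationConfig(seed=22, frac_de_geo_female=0,
                                  frac_de_geo_male=0, frac_de_geo_both=0,
                                  frac_de_sex=0, n_modules=0, module_traits=())
        ds = nd.simulate_all(cfg)
        kept, norm = nd.normalize(ds.counts)
        res = nd.run_comparisons(kept, ds.samples, which=["geo_all", "sex_all"],
                                 norm=norm)
        assert res["geo_all"].n_significant <= 2
        assert res["sex_all"].n_significant <= 2

    def test_subset_mode_fdr_family(self, default_dataset, normalized):
        kept, norm = normalized
        subset = kept.gene_ids[:100]
        res = nd.run_comparisons(kept, default_dataset.samples,
                                 which=["geo_all"], norm=norm,
                                 subset_gene_ids=subset)
        table = res["geo_all"].table
        assert len(table) == 100
        # FDR recomputed within the subset family
        assert np.allclose(table["fdr"].to_numpy(),
                           nd.bh_fdr(table["p"].to_numpy()), equal_nan=True)

    def test_sign_convention_sympatric_up(self):
        # plant upregulation in sympatry with a fixed positive lfc
        rng = np.random.default_rng(23)
        n = {"AF": 4, "AM": 4, "SF": 4, "SM": 4}
        rows, cols = [], []
        for tag, (geo, sex) in [("AF", ("allopatric", "female")),
                                ("AM", ("allopatric", "male")),
                                ("SF", ("sympatric", "female")),
                                ("SM", ("sympatric", "male"))]:
            for i in range(4):
                rows.append((f"{tag}{i}", geo, sex))
        samples = nd.SampleTable(
            pd.DataFrame(rows, columns=["sample_id", "geography", "sex"])
            .set_index("sample_id"))
        mu = np.full((200, 16), 100.0)
        sym_cols = [i for i, (sid, _, _) in enumerate(rows) if sid[0] == "S"]
        # shift a minority of genes so normalization keeps a stable background
        mu[np.ix_(range(20), sym_cols)] *= 4.0
        counts = rng.poisson(mu)
        cm = nd.CountMatrix(pd.DataFrame(
            counts, index=[f"g{i}" for i in range(200)],
            columns=[r[0] for r in rows]))
        res = nd.run_comparisons(cm, samples, which=["geo_all"])
        assert (res["geo_all"].table["logFC"].iloc[:20] > 0).all()

    def test_unknown_comparison_errors(self, default_dataset, normalized):
        kept, norm = normalized
        with pytest.raises(ValueError, match="unknown comparison"):
            nd.run_comparisons(kept, default_dataset.samples,
                               which=["nope"], norm=norm)

    def test_candidate_comparisons_defined(self):
        assert set(CANDIDATE_COMPARISONS) == {"geo_all", "geo_female", "geo_male"}
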