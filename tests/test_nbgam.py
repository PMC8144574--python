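"""Tests of the count-model machinery: normalization, BH, NB-GAM fits."""

import numpy as np
import pandas as pd
import pytest

from dimex.nbgam import (SmoothSpec, bh_fdr, estimate_size_factors,
                         filter_low_counts, fit_nb_gam, run_de)


class TestSizeFactors:
    def test_doubled_sample_closed_form(self):
        # sample B = 2 x sample A for every gene: geometric-mean rescaling
        # puts the factors at (1/sqrt(2), sqrt(2))
        counts = pd.DataFrame({"A": [10, 40, 100], "B": [20, 80, 200]})
        sf = estimate_size_factors(counts)
        np.testing.assert_allclose(sf.to_numpy(),
                                   [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12)

    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"A": [5, 9, 3], "B": [5, 9, 3], "C": [5, 9, 3]})
        np.testing.assert_allclose(estimate_size_factors(counts), 1.0)

    def test_geometric_mean_is_one(self, small_cohort):
        sf = estimate_size_factors(small_cohort["counts"])
        assert np.exp(np.log(sf).mean()) == pytest.approx(1.0, abs=1e-10)
        assert (sf > 0).all()

    def test_all_zero_matrix_rejected(self):
        counts = pd.DataFrame(np.zeros((4, 3), dtype=int))
        with pytest.raises(ValueError, match="filter"):
            estimate_size_factors(counts)


class TestFilter:
    def test_all_zero_gene_removed_and_zero_threshold_identity(self):
        counts = pd.DataFrame({"a": [0, 10], "b": [0, 20]}, index=["g0", "g1"])
        assert list(filter_low_counts(counts, 5).index) == ["g1"]
        pd.testing.assert_frame_equal(filter_low_counts(counts, 0), counts)

    def test_constructed_threshold_count(self, rng):
        means = np.array([1, 2, 3, 10, 20, 30, 40, 50, 60, 70], dtype=float)
        counts = pd.DataFrame(rng.poisson(means[:, None], (10, 200)))
        kept = filter_low_counts(counts, min_mean=5.0)
        assert len(kept) == 7


class TestBhFdr:
    def test_matches_brute_force_and_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.uniform(size=200)
        q = bh_fdr(p)
        # brute-force step-up: q_i = min over j with p_j >= p_i of p_j*m/rank_j
        m = len(p)
        order = np.argsort(p)
        brute = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            brute[i] = running
        np.testing.assert_allclose(q, brute, rtol=0, atol=0)
        np.testing.assert_allclose(
            q, multipletests(p, method="fdr_bh")[1], atol=1e-12)

    def test_single_p_passes_through(self):
        np.testing.assert_allclose(bh_fdr(np.array([0.037])), [0.037])

    def test_nan_excluded_from_family(self):
        q = bh_fdr(np.array([0.01, np.nan, 0.04]))
        assert np.isnan(q[1])
        np.testing.assert_allclose(q[[0, 2]], bh_fdr(np.array([0.01, 0.04])))

    def test_monotone_in_p_rank(self, rng):
        p = rng.uniform(size=100)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


def _sim_counts(rng, n, G, mu0=100.0, alpha=0.1, effect=None, x=None):
    if x is None:
        x = rng.normal(36, 15, n)
    eta = np.full((G, n), np.log(mu0))
    if effect is not None:
        eta = eta + effect(x)[None, :]
    mu = np.exp(eta)
    y = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu))
    return x, pd.DataFrame(y)


class TestFitNbGam:
    def test_penalty_limit_gives_linear_fit(self, rng):
        # forcing a huge smoothing parameter leaves only the penalty null
        # space: a straight line, edf -> 1
        x, counts = _sim_counts(rng, 150, 1)
        spec = SmoothSpec(lambda_grid=np.array([1e12]))
        fit = fit_nb_gam(counts.iloc[0].to_numpy(), x, None,
                         np.ones(150), spec)
        assert fit.edf == pytest.approx(1.0, abs=0.01)
        curve = fit.fitted_curve
        slopes = np.diff(curve) / np.diff(fit.curve_grid)
        assert np.ptp(slopes) < 1e-6 * (1 + np.abs(slopes).max())

    def test_strong_quadratic_has_high_edf(self, rng):
        xs = lambda x: ((x - x.mean()) / x.std())
        x, counts = _sim_counts(rng, 200, 1,
                                effect=lambda x: 0.6 * xs(x) ** 2)
        fit = fit_nb_gam(counts.iloc[0].to_numpy(), x, None, np.ones(200))
        assert fit.converged
        assert fit.edf > 1.5
        assert fit.p_value < 1e-4

    def test_offset_absorbs_depth_change(self, rng):
        # sequencing-depth changes must be absorbed by the offset: doubling
        # counts together with size factors leaves the coefficients unchanged
        # (exact for a global doubling in the Poisson limit at fixed
        # smoothing; single-sample doubling shifts the score root slightly)
        x, counts = _sim_counts(rng, 80, 1)
        y = counts.iloc[0].to_numpy().astype(float)
        sf = np.ones(80)
        # near-zero penalty: with any fixed penalty weight the doubled score
        # would need a doubled lambda to keep the same root
        spec = SmoothSpec(lambda_grid=np.array([1e-8]))
        fit1 = fit_nb_gam(y, x, None, sf, spec, dispersion=1e-10)
        fit2 = fit_nb_gam(2 * y, x, None, 2 * sf, spec, dispersion=1e-10)
        np.testing.assert_allclose(fit1.coefficients, fit2.coefficients,
                                   atol=1e-6)
        y3, sf3 = y.copy(), sf.copy()
        y3[3] *= 2
        sf3[3] = 2.0
        fit3 = fit_nb_gam(y3, x, None, sf3, spec, dispersion=0.1)
        np.testing.assert_allclose(fit1.coefficients[0], fit3.coefficients[0],
                                   atol=0.05)

    def test_edf_bounds(self, small_cohort):
        res, _ = run_de(small_cohort["counts"],
                        small_cohort["phenotypes"]["total_pcl"],
                        small_cohort["covariates"])
        conv = res[res.converged]
        assert (conv.edf >= 1.0 - 1e-9).all()
        assert (conv.edf <= 10 - 1).all()

    def test_too_few_samples_rejected(self, rng):
        x, counts = _sim_counts(rng, 9, 1)
        with pytest.raises(ValueError, match="samples"):
            fit_nb_gam(counts.iloc[0].to_numpy(), x, None, np.ones(9))


class TestRunDe:
    def test_single_gene_fdr_equals_p(self, rng):
        x, counts = _sim_counts(rng, 100, 1)
        res, _ = run_de(counts, x, size_factors=pd.Series(np.ones(100)))
        assert res.fdr.iloc[0] == pytest.approx(res.p_value.iloc[0])

    def test_permuted_phenotype_yields_no_discoveries(self, small_cohort, rng):
        perm = rng.permutation(
            small_cohort["phenotypes"]["total_pcl"].to_numpy())
        res, _ = run_de(small_cohort["counts"], perm,
                        small_cohort["covariates"])
        assert (res.fdr < 0.05).sum() == 0

    def test_planted_effects_recovered(self, small_cohort):
        res, _ = run_de(small_cohort["counts"],
                        small_cohort["phenotypes"]["total_pcl"],
                        small_cohort["covariates"])
        df = res.join(small_cohort["truth"])
        effects = df[df.effect_class != "null"]
        assert (effects.fdr < 0.05).mean() > 0.8
        assert df.loc[df.effect_class == "null", "p_value"].median() > 0.2

    def test_curve_table_shape_and_centering(self, small_cohort):
        res, curves = run_de(small_cohort["counts"],
                             small_cohort["phenotypes"]["total_pcl"],
                             small_cohort["covariates"])
        assert curves.shape == (len(res), 100)

    def test_gaussian_limit_rank_agreement(self, rng):
        # large counts, tiny dispersion: NB-GAM p-value ranking should agree
        # with a Gaussian spline regression on log counts
        from dimex.splicing import run_continuous_de
        from scipy.stats import spearmanr
        n, G = 200, 150
        x = rng.normal(36, 15, n)
        xs = (x - x.mean()) / x.std()
        eta = np.log(5000) + rng.uniform(0, 0.25, (G, 1)) * xs[None, :]
        mu = np.exp(eta)
        alpha = 0.002
        y = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu))
        counts = pd.DataFrame(y)
        # pin both engines to the penalty null space (linear fits) so the
        # comparison isolates the NB-vs-Gaussian distributional claim
        spec = SmoothSpec(lambda_grid=np.array([1e8]))
        res_nb, _ = run_de(counts, x, smooth_spec=spec,
                           size_factors=pd.Series(np.ones(n)))
        res_g, _ = run_continuous_de(np.log(counts + 1.0), x,
                                     smooth_spec=spec)
        ok = res_nb.p_value.notna() & res_g.p_value.notna()
        rho = spearmanr(res_nb.p_value[ok], res_g.p_value[ok]).statistic
        assert rho > 0.95


class TestDispersionEstimators:
    def test_ml_and_pearson_recover_known_alpha(self, rng):
        from dimex._fitters import (estimate_dispersion_ml,
                                    estimate_dispersion_pearson)
        n, G = 400, 60
        alpha = 0.15
        mu = np.full((G, n), 150.0)
        y = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu)).astype(float)
        a_ml = estimate_dispersion_ml(y, mu)
        a_pe = estimate_dispersion_pearson(y, mu, np.full(G, n - 1.0))
        assert np.median(a_ml) == pytest.approx(alpha, rel=0.15)
        assert np.median(a_pe) == pytest.approx(alpha, rel=0.15)
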