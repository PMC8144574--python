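"""Tests of cross-dimension comparison: uniqueness, correlations, Venn, chi-square."""

import itertools

import numpy as np
import pandas as pd
import pytest

from dimex.compare import (MultiDimResults, as_proportion_test, call_unique,
                           neglogp_correlation, overlap_counts,
                           significance_curves)

DIMS = ["reexperiencing", "avoidance", "numbing", "hyperarousal"]


def _results(p_by_dim: dict[str, list[float]],
             fdr_by_dim: dict[str, list[float]] | None = None):
    n = len(next(iter(p_by_dim.values())))
    idx = pd.Index([f"g{i}" for i in range(n)], name="feature_id")
    tables = {}
    for d, p in p_by_dim.items():
        fdr = fdr_by_dim[d] if fdr_by_dim else p
        tables[d] = pd.DataFrame({"p_value": p, "fdr": fdr}, index=idx)
    return MultiDimResults(tables)


class TestCallUnique:
    def test_definition_positive_and_negative(self):
        res = _results(
            {d: [0.5] for d in DIMS},
            None)
        # g0: target fdr 0.04, others p 0.2/0.3/0.5 -> unique
        res.fdr.loc["g0", "avoidance"] = 0.04
        res.p.loc["g0", "reexperiencing"] = 0.2
        res.p.loc["g0", "numbing"] = 0.3
        res.p.loc["g0", "hyperarousal"] = 0.5
        assert call_unique(res, "avoidance") == ["g0"]
        # one other dimension at p = 0.05 destroys uniqueness
        res.p.loc["g0", "numbing"] = 0.05
        assert call_unique(res, "avoidance") == []

    def test_empty_significant_set(self):
        res = _results({d: [0.9, 0.8] for d in DIMS})
        assert call_unique(res, "numbing") == []

    def test_unknown_dimension_rejected(self):
        res = _results({d: [0.5] for d in DIMS})
        with pytest.raises(KeyError, match="total_burden"):
            call_unique(res, "total_burden")

    def test_unique_set_disjoint_from_other_significants(self, rng):
        p = {d: rng.uniform(size=300) for d in DIMS}
        res = _results({d: list(v) for d, v in p.items()})
        for target in DIMS:
            uniq = set(call_unique(res, target, fdr_threshold=0.3))
            for other in DIMS:
                if other == target:
                    continue
                others_sig = set(res.features[res.p[other] <= 0.1])
                assert uniq.isdisjoint(others_sig)


class TestNeglogpCorrelation:
    def test_diagonal_and_identical_vectors(self, rng):
        p = list(rng.uniform(size=50))
        res = _results({d: p for d in DIMS})
        corr = neglogp_correlation(res)
        np.testing.assert_allclose(corr.to_numpy(), 1.0, atol=1e-12)

    def test_independent_vectors_near_zero(self, rng):
        res = _results({d: list(rng.uniform(size=10000)) for d in DIMS})
        corr = neglogp_correlation(res)
        off = corr.to_numpy()[np.triu_indices(4, 1)]
        assert np.abs(off).max() < 0.05

    def test_log_base_does_not_change_r(self, rng):
        # Pearson r is invariant to the logarithm base (a positive rescale)
        p1, p2 = rng.uniform(size=200), rng.uniform(size=200)
        r10 = np.corrcoef(-np.log10(p1), -np.log10(p2))[0, 1]
        rln = np.corrcoef(-np.log(p1), -np.log(p2))[0, 1]
        assert r10 == pytest.approx(rln, abs=1e-12)

    def test_zero_variance_warns_nan(self):
        res = _results({**{d: [0.1, 0.2, 0.3] for d in DIMS},
                        "avoidance": [0.5, 0.5, 0.5]})
        with pytest.warns(UserWarning, match="zero-variance"):
            corr = neglogp_correlation(res)
        assert np.isnan(corr.loc["avoidance", "numbing"])


class TestOverlapCounts:
    def test_disjoint_and_identical_sets(self):
        p = {d: [0.9] * 8 for d in DIMS}
        fdr = {d: [0.9] * 8 for d in DIMS}
        for i, d in enumerate(DIMS):
            fdr[d][i] = 0.01
        res = _results(p, fdr)
        counts = overlap_counts(res)
        assert counts.sum() == 4
        assert all(counts["&".join(c)] == 0
                   for r in (2, 3, 4) for c in itertools.combinations(DIMS, r))
        fdr2 = {d: [0.01, 0.9] for d in DIMS}
        res2 = _results({d: [0.5, 0.9] for d in DIMS}, fdr2)
        counts2 = overlap_counts(res2)
        assert counts2["&".join(DIMS)] == 1
        assert counts2.sum() == 1

    def test_matches_brute_force_enumeration(self, rng):
        fdr = {d: list(rng.uniform(size=60)) for d in DIMS}
        res = _results({d: [0.5] * 60 for d in DIMS}, fdr)
        counts = overlap_counts(res, fdr_threshold=0.4)
        sig = {d: {f"g{i}" for i in range(60) if fdr[d][i] < 0.4}
               for d in DIMS}
        union = set().union(*sig.values())
        assert counts.sum() == len(union)
        for g in union:
            member = [d for d in DIMS if g in sig[d]]
            region = "&".join(member)
            # each feature sits in exactly its membership region
            assert counts[region] >= 1

    def test_permutation_invariance_of_regions(self, rng):
        fdr = {d: list(rng.uniform(size=40)) for d in DIMS}
        res = _results({d: [0.5] * 40 for d in DIMS}, fdr)
        c1 = overlap_counts(res, 0.3, dimensions=DIMS)
        c2 = overlap_counts(res, 0.3, dimensions=DIMS[::-1])
        for name, v in c1.items():
            flipped = "&".join([d for d in DIMS[::-1] if d in name.split("&")])
            assert c2[flipped] == v


class TestSignificanceCurves:
    def test_extreme_thresholds(self, rng):
        res = _results({d: list(rng.uniform(size=100)) for d in DIMS})
        curves = significance_curves(res, [1.0])
        assert (curves.loc[1.0] == 100).all()
        with pytest.raises(ValueError, match="thresholds"):
            significance_curves(res, [0.0])

    def test_uniform_null_expectation_and_monotonicity(self, rng):
        res = _results({d: list(rng.uniform(size=1000)) for d in DIMS})
        curves = significance_curves(res, [0.01, 0.05, 0.2, 1.0])
        assert (curves.diff().dropna() >= 0).all().all()
        assert curves.loc[0.05].between(25, 80).all()


class TestAsProportionTest:
    def test_exact_match_gives_zero_statistic(self):
        bg = {"SE": 0.5, "AF": 0.3, "RI": 0.2}
        out = as_proportion_test({"SE": 50, "AF": 30, "RI": 20}, bg)
        assert out["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert out["p_value"] == pytest.approx(1.0)

    def test_two_category_hand_computation(self):
        bg = {"SE": 0.5, "AF": 0.5, "A3": 0.0, "A5": 0.0, "AL": 0.0,
              "MX": 0.0, "RI": 0.0}
        out = as_proportion_test({"SE": 10, "AF": 40}, bg)
        assert out["statistic"] == pytest.approx(18.0)
        assert out["df"] == 1

    def test_matches_scipy_after_merging(self, rng):
        from scipy import stats
        bg = {"SE": 0.435, "A3": 0.14, "A5": 0.12, "RI": 0.12, "AF": 0.10,
              "MX": 0.05, "AL": 0.035}
        obs = {"SE": 40, "A3": 12, "A5": 9, "RI": 11, "AF": 20, "MX": 5,
               "AL": 3}
        out = as_proportion_test(obs, bg)
        chi, p = stats.chisquare(out["observed"], out["expected"])
        assert out["statistic"] == pytest.approx(chi, abs=1e-10)
        assert out["p_value"] == pytest.approx(p, abs=1e-10)

    def test_merging_preserves_totals_and_floor(self):
        bg = {"SE": 0.435, "A3": 0.14, "A5": 0.12, "RI": 0.12, "AF": 0.10,
              "MX": 0.05, "AL": 0.035}
        obs = {"SE": 20, "A3": 5, "A5": 4, "RI": 4, "AF": 5, "MX": 1, "AL": 1}
        out = as_proportion_test(obs, bg)
        total = sum(obs.values())
        assert sum(out["observed"]) == total
        assert sum(out["expected"]) == pytest.approx(total)
        assert len(out["merged"]) > 0
        # every tested category respects the expected-count floor (or the
        # merge hit the 2-category backstop)
        if len(out["categories"]) > 2:
            assert min(out["expected"]) >= 5.0 - 1e-9

    def test_empty_observed_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            as_proportion_test({"SE": 0}, {"SE": 0.5, "AF": 0.5})
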