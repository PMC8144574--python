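"""Tests of preranked GSEA: ranking, filtering, ES oracle, permutation FDR."""

import numpy as np
import pandas as pd
import pytest

from dimex.gsea import (build_ranking, call_unique_sets, enrichment_score,
                        filter_sets, hypergeometric_enrichment, significance)


def _de(pvals: dict[str, float]) -> pd.DataFrame:
    return pd.DataFrame({"p_value": pd.Series(pvals)})


def brute_force_es(scores, in_set, weight=1.0):
    """Independent running-sum scan (plain loop, no shortcuts)."""
    n = len(scores)
    hits = [i for i in range(n) if in_set[i]]
    denom = sum(abs(scores[i]) ** weight for i in hits)
    running, best, best_pos = 0.0, 0.0, -1
    for i in range(n):
        if in_set[i]:
            running += (abs(scores[i]) ** weight) / denom if denom else 1 / len(hits)
        else:
            running -= 1.0 / (n - len(hits))
        if abs(running) > abs(best):
            best, best_pos = running, i
    return best, best_pos


class TestBuildRanking:
    def test_scores_and_order(self):
        r = build_ranking(_de({"a": 0.001, "b": 0.01, "c": 0.1}))
        assert list(r.index) == ["a", "b", "c"]
        np.testing.assert_allclose(r.to_numpy(), [3.0, 2.0, 1.0])

    def test_ties_stable_by_id(self):
        r = build_ranking(_de({"z": 0.05, "a": 0.05, "m": 0.5}))
        assert list(r.index) == ["a", "z", "m"]

    def test_p_one_ranks_last_with_zero_score(self):
        r = build_ranking(_de({"a": 1.0, "b": 0.5}))
        assert list(r.index) == ["b", "a"]
        assert r["a"] == 0.0

    def test_nan_excluded_empty_rejected(self):
        r = build_ranking(_de({"a": np.nan, "b": 0.2}))
        assert list(r.index) == ["b"]
        with pytest.raises(ValueError):
            build_ranking(_de({}))


class TestFilterSets:
    def test_size_bounds_after_intersection(self):
        ranking = pd.Series(np.linspace(3, 0, 100),
                            index=[f"g{i}" for i in range(100)])
        sets = {
            "tiny": [f"g{i}" for i in range(10)],
            "big": [f"x{i}" for i in range(600)],
            "partial": [f"g{i}" for i in range(14)] + ["nope1", "nope2",
                                                       "nope3", "nope4",
                                                       "nope5", "nope6"],
            "ok": [f"g{i}" for i in range(20)],
        }
        out = filter_sets(sets, ranking, min_size=15, max_size=500)
        assert set(out) == {"ok"}


class TestEnrichmentScore:
    def test_matches_brute_force_on_20_genes(self, rng):
        scores = np.sort(rng.exponential(1.0, 20))[::-1]
        ranking = pd.Series(scores, index=[f"g{i}" for i in range(20)])
        for members in ([0, 1, 2, 3], [16, 17, 18, 19], [0, 5, 10, 15],
                        [3, 4, 11]):
            gene_set = [f"g{i}" for i in members]
            in_set = [i in members for i in range(20)]
            es, peak = enrichment_score(ranking, gene_set)
            es_bf, peak_bf = brute_force_es(scores, in_set)
            assert es == pytest.approx(es_bf, abs=1e-12)
            assert peak == peak_bf

    def test_top_set_positive_bottom_set_negative(self, rng):
        scores = np.sort(rng.uniform(0.1, 3, 50))[::-1]
        ranking = pd.Series(scores, index=[f"g{i}" for i in range(50)])
        assert enrichment_score(ranking, [f"g{i}" for i in range(5)])[0] > 0
        assert enrichment_score(ranking, [f"g{i}" for i in range(45, 50)])[0] < 0

    def test_weight_zero_reduces_to_ks_on_ranks(self, rng):
        scores = np.sort(rng.uniform(0.1, 3, 30))[::-1]
        ranking = pd.Series(scores, index=[f"g{i}" for i in range(30)])
        members = [2, 7, 8, 20]
        es, _ = enrichment_score(ranking, [f"g{i}" for i in members], weight=0)
        es_bf, _ = brute_force_es(scores, [i in members for i in range(30)],
                                  weight=0)
        assert es == pytest.approx(es_bf, abs=1e-12)

    def test_running_sum_conservation(self, rng):
        # increments sum to +1, decrements to -1: the walk ends at zero
        scores = rng.exponential(1.0, 40)
        ranking = pd.Series(np.sort(scores)[::-1],
                            index=[f"g{i}" for i in range(40)])
        members = set(f"g{i}" for i in rng.choice(40, 10, replace=False))
        w = np.abs(ranking.to_numpy())
        in_set = np.array([g in members for g in ranking.index])
        inc = np.where(in_set, w / w[in_set].sum(), 0.0)
        dec = np.where(in_set, 0.0, 1.0 / (40 - in_set.sum()))
        assert np.cumsum(inc - dec)[-1] == pytest.approx(0.0, abs=1e-9)

    def test_empty_intersection_is_nan(self):
        ranking = pd.Series([1.0, 0.5], index=["a", "b"])
        es, _ = enrichment_score(ranking, ["zz"])
        assert np.isnan(es)


@pytest.fixture(scope="module")
def null_table():
    rng = np.random.default_rng(11)
    genes = [f"g{i}" for i in range(500)]
    ranking = pd.Series(np.sort(-np.log10(rng.uniform(size=500)))[::-1],
                        index=rng.permutation(genes))
    sets = {f"S{j}": list(rng.choice(genes, 25, replace=False))
            for j in range(40)}
    sets["TOP"] = list(ranking.index[:25])
    return ranking, sets, significance(ranking, sets, n_perm=300, seed=2)


class TestSignificance:
    def test_null_sets_near_nominal(self, null_table):
        _, _, table = null_table
        rand = table.drop(index="TOP")
        assert (rand.p_value < 0.05).mean() < 0.2

    def test_planted_top_set_flagged(self, null_table):
        _, _, table = null_table
        assert table.loc["TOP", "fdr_q"] < 0.1
        assert table.loc["TOP", "report"]

    def test_smoothed_p_in_unit_interval(self, null_table):
        _, _, table = null_table
        p = table.p_value.dropna()
        assert ((p > 0) & (p <= 1)).all()

    def test_es_bounded(self, null_table):
        _, _, table = null_table
        assert (table.es.abs() <= 1.0 + 1e-12).all()

    def test_seed_determinism(self, null_table):
        ranking, sets, table = null_table
        again = significance(ranking, sets, n_perm=300, seed=2)
        pd.testing.assert_frame_equal(table, again)

    def test_low_n_perm_warns(self, null_table):
        ranking, sets, _ = null_table
        with pytest.warns(UserWarning, match="n_perm"):
            significance(ranking, dict(list(sets.items())[:2]), n_perm=50,
                         seed=0)


class TestCallUniqueSets:
    def _tables(self):
        dims = ["reexperiencing", "avoidance", "numbing", "hyperarousal"]
        idx = ["P1", "P2", "P3"]
        out = {}
        for d in dims:
            out[d] = pd.DataFrame({"p_value": [0.5, 0.5, 0.5],
                                   "fdr_q": [0.5, 0.5, 0.5]}, index=idx)
        return out

    def test_q_branch_and_p_branch(self):
        t = self._tables()
        t["numbing"].loc["P1"] = [0.01, 0.05]        # q-branch
        t["numbing"].loc["P2"] = [0.0005, 0.3]       # p-branch
        assert call_unique_sets(t, "numbing") == ["P1", "P2"]

    def test_other_dimension_near_significance_blocks(self):
        t = self._tables()
        t["avoidance"].loc["P3"] = [0.01, 0.05]
        t["numbing"].loc["P3", "p_value"] = 0.09
        assert call_unique_sets(t, "avoidance") == []

    def test_missing_dimension_rejected(self):
        t = self._tables()
        with pytest.raises(KeyError):
            call_unique_sets(t, "total")


class TestHypergeometric:
    def test_matches_direct_scipy_tail(self):
        from scipy import stats
        universe = [f"g{i}" for i in range(100)]
        sets = {"A": universe[:20]}
        query = universe[:5] + universe[50:55]
        out = hypergeometric_enrichment(query, sets, universe)
        assert out.loc["A", "overlap"] == 5
        assert out.loc["A", "p_value"] == pytest.approx(
            stats.hypergeom.sf(4, 100, 20, 10))
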