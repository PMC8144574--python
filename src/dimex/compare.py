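"""Cross-dimension comparison of differential-expression results.

Given aligned result tables for total PCL and the four symptom dimensions,
this module calls features unique to one dimension (significant there,
clearly null in the other three), computes -log p correlations and Venn
overlap counts between dimensions, counts significant features across
p-value thresholds, and tests whether the AS event-type mix of a significant
set differs from the transcriptome-wide background (chi-square goodness of
fit with small-expected-count categories merged).
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MultiDimResults", "call_unique", "neglogp_correlation",
    "overlap_counts", "significance_curves", "as_proportion_test",
    "EVENT_TYPES",
]

EVENT_TYPES = ("A3", "A5", "AF", "AL", "MX", "RI", "SE")


class MultiDimResults:
    """Aligned per-dimension p-value and FDR tables.

    Construct from a mapping {dimension: DEResultTable}; feature ids are
    aligned to their intersection, preserving the first table's order.
    """

    def __init__(self, tables: dict[str, pd.DataFrame]):
        if not tables:
            raise ValueError("no result tables given")
        self.dimensions = list(tables)
        common = None
        for t in tables.values():
            idx = t.index
            common = idx if common is None else common.intersection(idx)
        first = tables[self.dimensions[0]].index
        self.features = first[first.isin(common)]
        self.p = pd.DataFrame(
            {d: tables[d].loc[self.features, "p_value"] for d in self.dimensions})
        self.fdr = pd.DataFrame(
            {d: tables[d].loc[self.features, "fdr"] for d in self.dimensions})

    def __contains__(self, dim: str) -> bool:
        return dim in self.dimensions


def _check_dim(results: MultiDimResults, dim: str) -> None:
    if dim not in results.dimensions:
        raise KeyError(f"unknown dimension {dim!r}; have {results.dimensions}")


def call_unique(results: MultiDimResults, target_dimension: str,
                fdr_threshold: float = 0.05, other_p_threshold: float = 0.1,
                other_dimensions: list[str] | None = None) -> list[str]:
    """Features unique to one dimension.

    Significant (FDR < threshold) in the target dimension and clearly
    non-significant (p > other_p_threshold) in every other compared
    dimension.  By default the others are all remaining dimensions of the
    result set (for the four-dimension comparison: the other three).
    """
    _check_dim(results, target_dimension)
    others = (other_dimensions if other_dimensions is not None
              else [d for d in results.dimensions if d != target_dimension])
    for d in others:
        _check_dim(results, d)
    sig = results.fdr[target_dimension] < fdr_threshold
    mask = sig.fillna(False)
    for d in others:
        mask &= (results.p[d] > other_p_threshold).fillna(False)
    return list(results.features[mask.to_numpy()])


def neglogp_correlation(results: MultiDimResults,
                        dimensions: list[str] | None = None) -> pd.DataFrame:
    """Pearson correlation matrix of -log10 p across dimensions.

    NaN p-values are excluded pairwise; a zero-variance vector yields NaN
    entries with a warning.
    """
    import warnings

    dims = dimensions or results.dimensions
    if len(results.features) < 3:
        raise ValueError("need at least 3 shared features")
    neglog = -np.log10(results.p[dims])
    out = pd.DataFrame(np.eye(len(dims)), index=dims, columns=dims)
    for a, b in itertools.combinations(dims, 2):
        ok = neglog[a].notna() & neglog[b].notna()
        x, y = neglog.loc[ok, a], neglog.loc[ok, b]
        if ok.sum() < 3 or x.std() < 1e-15 or y.std() < 1e-15:
            warnings.warn(f"zero-variance -log p vector for {a} or {b}")
            r = np.nan
        else:
            r = float(np.corrcoef(x, y)[0, 1])
        out.loc[a, b] = out.loc[b, a] = r
    return out


def overlap_counts(results: MultiDimResults, fdr_threshold: float = 0.05,
                   dimensions: list[str] | None = None) -> pd.Series:
    """All 2^d - 1 exclusive region counts of the significant-set Venn.

    Region labels join member dimensions with '&'; counts are exclusive
    (each feature counts in exactly one region), so they sum to the size of
    the union of the significant sets.
    """
    dims = dimensions or results.dimensions
    sig = {d: set(results.features[(results.fdr[d] < fdr_threshold)
                                   .fillna(False).to_numpy()])
           for d in dims}
    regions = {}
    for r in range(1, len(dims) + 1):
        for combo in itertools.combinations(dims, r):
            inside = set.intersection(*(sig[d] for d in combo))
            outside = set.union(set(), *(sig[d] for d in dims if d not in combo))
            regions["&".join(combo)] = len(inside - outside)
    return pd.Series(regions, name="count")


def significance_curves(results: MultiDimResults, thresholds,
                        dimensions: list[str] | None = None) -> pd.DataFrame:
    """Number of features with p < t per dimension, for each threshold t."""
    dims = dimensions or results.dimensions
    thr = np.asarray(list(thresholds), dtype=float)
    if ((thr <= 0) | (thr > 1)).any():
        raise ValueError("thresholds must lie in (0, 1]")
    rows = {d: [(results.p[d] < t).sum() for t in thr] for d in dims}
    return pd.DataFrame(rows, index=pd.Index(thr, name="threshold"))


def as_proportion_test(observed: dict[str, int] | pd.Series,
                       background: dict[str, float] | pd.Series,
                       min_expected: float = 5.0) -> dict:
    """Chi-square goodness of fit of event-type proportions with merging.

    Compares the event-type counts of a significant AS set against
    transcriptome-wide background proportions.  Categories with expected
    count below ``min_expected`` are combined: repeatedly, the smallest-
    expected remaining category joins a pooled 'merged' category until every
    category (including the pool) meets the floor or only two categories
    remain.  Ties on expected count break alphabetically by type code.

    Returns dict with statistic, df, p_value, merged categories and the
    observed/expected vectors actually tested.
    """
    obs = pd.Series(observed, dtype=float)
    bg = pd.Series(background, dtype=float)
    bg = bg / bg.sum()
    obs = obs.reindex(bg.index, fill_value=0.0)
    total = obs.sum()
    if total < 1:
        raise ValueError("observed set is empty")
    expected = total * bg
    # categories absent from the background carry no information when also
    # unobserved; observed events of a zero-background type are a data error
    zero = expected.index[expected <= 0]
    if (obs[zero] > 0).any():
        bad = list(obs[zero][obs[zero] > 0].index)
        raise ValueError(f"observed events of types {bad} have zero "
                         "background proportion")
    obs = obs.drop(zero)
    expected = expected.drop(zero)
    cats = sorted(expected.index, key=lambda c: (expected[c], c))
    kept = list(cats)
    merged: list[str] = []
    # pool smallest-expected categories until the floor holds everywhere
    while len(kept) + (1 if merged else 0) > 2:
        exp_now = {c: expected[c] for c in kept}
        pool = sum(expected[c] for c in merged)
        smallest = min(kept, key=lambda c: (exp_now[c], c))
        if (exp_now[smallest] >= min_expected
                and (not merged or pool >= min_expected)):
            break
        merged.append(smallest)
        kept.remove(smallest)
    if not kept and not merged:
        raise ValueError("test not defined: no categories")
    obs_v, exp_v, labels = [], [], []
    for c in sorted(kept):
        obs_v.append(obs[c])
        exp_v.append(expected[c])
        labels.append(c)
    if merged:
        obs_v.append(sum(obs[c] for c in merged))
        exp_v.append(sum(expected[c] for c in merged))
        labels.append("+".join(sorted(merged)))
    if len(labels) < 2:
        raise ValueError("test not defined: fewer than 2 categories after merging")
    obs_v = np.asarray(obs_v)
    exp_v = np.asarray(exp_v)
    statistic = float(((obs_v - exp_v) ** 2 / exp_v).sum())
    df = len(labels) - 1
    p = float(stats.chi2.sf(statistic, df))
    return {
        "statistic": statistic, "df": df, "p_value": p,
        "categories": labels,
        "observed": obs_v.tolist(), "expected": exp_v.tolist(),
        "merged": sorted(merged),
    }
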