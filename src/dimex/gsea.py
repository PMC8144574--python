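"""Preranked gene-set enrichment analysis.

Genes are ranked by -log10 p from a differential-expression table; the
enrichment score (ES) of a gene set is the extremum of the classical
weighted Kolmogorov-Smirnov running sum over that ranking: the sum gains
|score|^w / sum(|score|^w) at member genes and loses 1/(N - n_set) at
non-members.  Significance comes from gene-label permutations: nominal p is
the one-sided tail frequency (with +1 smoothing), NES normalizes ES by the
mean null |ES| of matching sign, and the FDR q pools positive and negative
NES across sets as in the original GSEA procedure.  A hypergeometric
over-representation test is included for annotating small unique-gene lists
against the same GMT collections.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "build_ranking", "filter_sets", "enrichment_score", "significance",
    "call_unique_sets", "hypergeometric_enrichment",
]


def build_ranking(de_results: pd.DataFrame, p_column: str = "p_value"
                  ) -> pd.Series:
    """Rank genes by -log10 p, descending; NaN p excluded, ties by id order.

    Returns a Series (index = gene ids, values = scores) sorted by
    decreasing score; equal scores keep stable feature-id order.
    """
    if len(de_results) == 0:
        raise ValueError("empty DE result table")
    p = de_results[p_column]
    ok = p.notna()
    if not ok.any():
        raise ValueError("no finite p-values to rank")
    score = -np.log10(np.clip(p[ok].to_numpy(dtype=float), 1e-300, None))
    ser = pd.Series(score, index=de_results.index[ok], name="score")
    ser = ser.sort_index(kind="stable")
    return ser.sort_values(ascending=False, kind="stable")


def filter_sets(sets: dict[str, list[str]], ranking: pd.Series,
                min_size: int = 15, max_size: int = 500
                ) -> dict[str, list[str]]:
    """Keep sets whose intersection with the ranked genes has size in bounds."""
    ranked = set(ranking.index)
    out = {}
    for name, members in sets.items():
        inter = [g for g in dict.fromkeys(members) if g in ranked]
        if min_size <= len(inter) <= max_size:
            out[name] = inter
    return out


def enrichment_score(ranking: pd.Series, gene_set, weight: float = 1.0
                     ) -> tuple[float, int]:
    """ES of one gene set and the running-sum extremum position.

    Returns (ES, peak index).  NaN ES when the set does not intersect the
    ranking.
    """
    members = set(gene_set)
    in_set = np.fromiter((g in members for g in ranking.index), dtype=bool,
                         count=len(ranking))
    return _es_from_mask(ranking.to_numpy(dtype=float), in_set, weight)


def _es_from_mask(scores: np.ndarray, in_set: np.ndarray, weight: float
                  ) -> tuple[float, int]:
    n = scores.size
    n_hit = int(in_set.sum())
    if n_hit == 0 or n_hit == n:
        return float("nan"), -1
    w = np.abs(scores) ** weight
    hit_sum = w[in_set].sum()
    if hit_sum <= 0:
        # all member scores zero: fall back to unweighted steps
        inc = np.where(in_set, 1.0 / n_hit, 0.0)
    else:
        inc = np.where(in_set, w / hit_sum, 0.0)
    dec = np.where(in_set, 0.0, 1.0 / (n - n_hit))
    running = np.cumsum(inc - dec)
    peak = int(np.argmax(np.abs(running)))
    return float(running[peak]), peak


def _null_es(scores: np.ndarray, set_sizes: list[int], weight: float,
             n_perm: int, rng: np.random.Generator) -> dict[int, np.ndarray]:
    """Gene-label permutation nulls, shared across sets of equal size."""
    n = scores.size
    out: dict[int, np.ndarray] = {}
    uniq = sorted(set(set_sizes))
    for size in uniq:
        null = np.empty(n_perm)
        for b in range(n_perm):
            idx = rng.choice(n, size=size, replace=False)
            mask = np.zeros(n, dtype=bool)
            mask[idx] = True
            null[b], _ = _es_from_mask(scores, mask, weight)
        out[size] = null
    return out


def significance(ranking: pd.Series, sets: dict[str, list[str]],
                 n_perm: int = 1000, seed: int = 0, weight: float = 1.0,
                 fdr_threshold: float = 0.1, p_fallback: float = 0.001
                 ) -> pd.DataFrame:
    """Permutation significance of every (filtered) gene set.

    Per set: ES, NES = ES / mean |null ES| of matching sign, nominal p as
    the one-sided smoothed tail frequency, and FDR q by the positive/
    negative-NES pooling of the standard GSEA procedure.  The ``report``
    column flags sets significant at q < fdr_threshold, or — when no set
    reaches that — sets at the nominal-p fallback.
    """
    import warnings

    if n_perm < 100:
        warnings.warn("n_perm < 100: FDR q estimates will be unstable")
    rng = np.random.default_rng(seed)
    scores = ranking.to_numpy(dtype=float)
    names = list(sets)
    sizes = [len(sets[s]) for s in names]
    nulls = _null_es(scores, sizes, weight, n_perm, rng)
    rows = []
    norm_null_pos: list[np.ndarray] = []
    norm_null_neg: list[np.ndarray] = []
    for name, size in zip(names, sizes):
        es, peak = enrichment_score(ranking, sets[name], weight)
        null = nulls[size]
        pos = null[null >= 0]
        neg = null[null < 0]
        if np.isnan(es):
            rows.append((name, size, es, np.nan, np.nan, peak))
            continue
        if es >= 0:
            p = (1.0 + (pos >= es).sum()) / (1.0 + pos.size)
            mean_pos = pos.mean() if pos.size else np.nan
            nes = es / mean_pos if mean_pos and mean_pos > 0 else np.nan
        else:
            p = (1.0 + (neg <= es).sum()) / (1.0 + neg.size)
            mean_neg = np.abs(neg).mean() if neg.size else np.nan
            nes = es / mean_neg if mean_neg and mean_neg > 0 else np.nan
        rows.append((name, size, es, nes, p, peak))
        # normalized null ES for the pooled FDR
        with np.errstate(invalid="ignore", divide="ignore"):
            npos = pos / pos.mean() if pos.size else pos
            nneg = neg / np.abs(neg).mean() if neg.size else neg
        norm_null_pos.append(npos)
        norm_null_neg.append(nneg)
    table = pd.DataFrame(
        rows, columns=["name", "size", "es", "nes", "p_value", "peak"]
    ).set_index("name")
    all_pos = np.concatenate(norm_null_pos) if norm_null_pos else np.array([])
    all_neg = np.concatenate(norm_null_neg) if norm_null_neg else np.array([])
    nes_obs = table["nes"].to_numpy()
    q = np.full(len(table), np.nan)
    pos_obs = nes_obs[np.isfinite(nes_obs) & (nes_obs >= 0)]
    neg_obs = nes_obs[np.isfinite(nes_obs) & (nes_obs < 0)]
    for i, nes in enumerate(nes_obs):
        if not np.isfinite(nes):
            continue
        if nes >= 0:
            null_frac = ((all_pos >= nes).mean()
                         if all_pos.size else np.nan)
            obs_frac = (pos_obs >= nes).mean() if pos_obs.size else np.nan
        else:
            null_frac = ((all_neg <= nes).mean()
                         if all_neg.size else np.nan)
            obs_frac = (neg_obs <= nes).mean() if neg_obs.size else np.nan
        if obs_frac and obs_frac > 0 and np.isfinite(null_frac):
            q[i] = min(null_frac / obs_frac, 1.0)
        else:
            q[i] = np.nan
    table["fdr_q"] = q
    any_sig = (table["fdr_q"] < fdr_threshold).any()
    if any_sig:
        table["report"] = table["fdr_q"] < fdr_threshold
    else:
        table["report"] = table["p_value"] < p_fallback
    return table


def call_unique_sets(results: dict[str, pd.DataFrame], target: str,
                     fdr_threshold: float = 0.1, p_strong: float = 0.001,
                     other_p_threshold: float = 0.1) -> list[str]:
    """Gene sets unique to one dimension.

    (q < fdr_threshold OR p < p_strong) in the target dimension and
    p > other_p_threshold in every other dimension of ``results``.
    """
    if target not in results:
        raise KeyError(f"dimension {target!r} missing from results")
    t = results[target]
    hit = (t["fdr_q"] < fdr_threshold) | (t["p_value"] < p_strong)
    out = []
    others = [d for d in results if d != target]
    for name in t.index[hit.fillna(False)]:
        ok = True
        for d in others:
            other = results[d]
            if name not in other.index:
                ok = False
                break
            p_other = other.loc[name, "p_value"]
            if not (np.isfinite(p_other) and p_other > other_p_threshold):
                ok = False
                break
        if ok:
            out.append(name)
    return out


def hypergeometric_enrichment(gene_list, sets: dict[str, list[str]],
                              universe, min_overlap: int = 1) -> pd.DataFrame:
    """Over-representation of a small gene list in GMT sets.

    One-sided hypergeometric test per set against the given universe, with
    Benjamini-Hochberg FDR across sets — a local annotation step for the
    short dimension-unique gene lists.
    """
    from .nbgam import bh_fdr

    universe = set(universe)
    query = set(gene_list) & universe
    N, n = len(universe), len(query)
    rows = []
    for name, members in sets.items():
        m = len(set(members) & universe)
        k = len(set(members) & query)
        if m == 0 or k < min_overlap:
            continue
        p = stats.hypergeom.sf(k - 1, N, m, n)
        rows.append((name, m, k, p))
    table = pd.DataFrame(rows, columns=["name", "set_size", "overlap",
                                        "p_value"]).set_index("name")
    table["fdr"] = bh_fdr(table["p_value"].to_numpy())
    return table.sort_values("p_value")
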