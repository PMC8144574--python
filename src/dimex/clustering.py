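"""Post-hoc clustering of estimated smooth functions.

Significant nonlinear features have fitted phenotype-response curves; this
module groups those curves into shape families.  Curves are evaluated on a
common phenotype grid and centered; partitioning uses PAM k-medoids (build +
swap) under Euclidean distance, and the number of clusters is chosen by the
gap statistic against uniform reference draws in the principal-component-
aligned bounding box of the data (Tibshirani's method B), with the
one-standard-error ("firstSEmax") rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SmoothCurveSet", "ClusteringResult", "extract_curves",
           "k_medoids", "gap_statistic"]


@dataclass
class SmoothCurveSet:
    """Centered fitted curves on a shared phenotype grid."""
    feature_ids: list[str]
    grid: np.ndarray
    curves: np.ndarray            # features x grid, each row mean 0

    def __post_init__(self):
        self.curves = np.atleast_2d(np.asarray(self.curves, dtype=float))
        if self.curves.shape != (len(self.feature_ids), len(self.grid)):
            raise ValueError("curve matrix shape does not match ids/grid")


@dataclass
class ClusteringResult:
    k_optimal: int
    medoid_indices: np.ndarray
    assignments: np.ndarray
    objective: float
    gap: np.ndarray | None = None
    gap_se: np.ndarray | None = None
    cluster_means: np.ndarray | None = None
    feature_ids: list[str] = field(default_factory=list)

    def assignments_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"feature_id": self.feature_ids,
                             "cluster": self.assignments}).set_index("feature_id")


def extract_curves(curves: pd.DataFrame, significant_ids,
                   scale: bool = False) -> SmoothCurveSet:
    """Select and center the fitted curves of the given features.

    ``curves`` is the wide fitted-curve table produced by the DE stages
    (features x phenotype grid).  Curves are re-centered to mean zero over
    the grid; amplitude is kept (pass scale=True to normalize to unit sd).
    """
    ids = list(significant_ids)
    missing = [i for i in ids if i not in curves.index]
    if missing:
        raise KeyError(f"no fitted curve for features {missing}")
    sub = curves.loc[ids].to_numpy(dtype=float)
    sub = sub - sub.mean(axis=1, keepdims=True)
    if scale:
        sd = sub.std(axis=1, keepdims=True)
        sub = sub / np.where(sd > 1e-12, sd, 1.0)
    grid = curves.columns.to_numpy(dtype=float)
    return SmoothCurveSet(ids, grid, sub)


def _pam(dist: np.ndarray, k: int, rng: np.random.Generator,
         max_swaps: int = 200) -> tuple[np.ndarray, np.ndarray, float]:
    """Classic PAM: greedy BUILD then SWAP until no improvement."""
    n = dist.shape[0]
    # BUILD: first medoid minimizes total distance; then greedy gain
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    while len(medoids) < k:
        d_near = dist[:, medoids].min(axis=1)
        gains = np.maximum(d_near[None, :] - dist, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids = np.array(sorted(medoids))
    current = dist[:, medoids].min(axis=1).sum()
    for _ in range(max_swaps):
        improved = False
        non_medoids = np.setdiff1d(np.arange(n), medoids)
        best = (0.0, None, None)
        for mi, m in enumerate(medoids):
            trial = medoids.copy()
            for h in non_medoids:
                trial[mi] = h
                cost = dist[:, trial].min(axis=1).sum()
                if current - cost > best[0] + 1e-12:
                    best = (current - cost, mi, h)
            trial[mi] = m
        if best[1] is not None:
            medoids[best[1]] = best[2]
            medoids = np.sort(medoids)
            current = dist[:, medoids].min(axis=1).sum()
            improved = True
        if not improved:
            break
    assign = np.argmin(dist[:, medoids], axis=1)
    return medoids, assign, float(current)


def k_medoids(curve_set: SmoothCurveSet | np.ndarray, k: int,
              seed: int = 0) -> ClusteringResult:
    """PAM k-medoids of the curves under Euclidean distance."""
    X = curve_set.curves if isinstance(curve_set, SmoothCurveSet) else np.atleast_2d(curve_set)
    ids = (curve_set.feature_ids if isinstance(curve_set, SmoothCurveSet)
           else [str(i) for i in range(len(X))])
    n = X.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of curves ({n})")
    if k < 1:
        raise ValueError("k must be >= 1")
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    dist = np.sqrt(np.maximum(d2, 0.0))
    rng = np.random.default_rng(seed)
    medoids, assign, obj = _pam(dist, k, rng)
    means = np.stack([X[assign == c].mean(axis=0) if (assign == c).any()
                      else X[medoids[c]] for c in range(k)])
    return ClusteringResult(k_optimal=k, medoid_indices=medoids,
                            assignments=assign, objective=obj,
                            cluster_means=means, feature_ids=ids)


def _within_dispersion(dist2: np.ndarray, assign: np.ndarray, k: int) -> float:
    """W_k = sum over clusters of within-cluster pairwise dispersion.

    Uses the pairwise form W = sum_r (1 / (2 n_r)) sum_{i,j in r} d^2_ij,
    the quantity the gap statistic is defined on.
    """
    W = 0.0
    for c in range(k):
        idx = np.where(assign == c)[0]
        if idx.size > 1:
            W += dist2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return W


def _pam_dispersion(X: np.ndarray, k: int, rng) -> tuple[float, np.ndarray]:
    d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    dist = np.sqrt(np.maximum(d2, 0.0))
    _, assign, _ = _pam(dist, k, rng)
    return _within_dispersion(d2, assign, k), assign


def gap_statistic(curve_set: SmoothCurveSet | np.ndarray, k_max: int = 10,
                  n_reference: int = 50, seed: int = 0
                  ) -> ClusteringResult:
    """Choose the number of curve clusters by the gap statistic.

    Gap(k) = E*[log W*_k] - log W_k with reference datasets drawn uniformly
    in the PCA-aligned bounding box of the curves; the selected k is the
    smallest k with Gap(k) >= Gap(k+1) - s_{k+1}.  Returns the PAM solution
    at the selected k together with the gap curve.
    """
    X = curve_set.curves if isinstance(curve_set, SmoothCurveSet) else np.atleast_2d(curve_set)
    ids = (curve_set.feature_ids if isinstance(curve_set, SmoothCurveSet)
           else [str(i) for i in range(len(X))])
    n = X.shape[0]
    if n_reference < 10:
        raise ValueError("n_reference must be >= 10")
    k_max = int(min(k_max, n))
    rng = np.random.default_rng(seed)
    if np.allclose(X, X[0], atol=1e-12):
        res = k_medoids(SmoothCurveSet(ids, np.arange(X.shape[1]), X), 1, seed)
        res.gap = np.zeros(1)
        res.gap_se = np.zeros(1)
        return res
    # PCA alignment (method B): rotate onto right singular vectors, draw the
    # reference uniformly in the rotated bounding box, rotate back
    mu = X.mean(axis=0)
    Xc = X - mu
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    Xp = Xc @ Vt.T
    lo, hi = Xp.min(axis=0), Xp.max(axis=0)
    logW = np.empty(k_max)
    assigns = []
    for k in range(1, k_max + 1):
        W, assign = _pam_dispersion(X, k, rng)
        logW[k - 1] = np.log(max(W, 1e-300))
        assigns.append(assign)
    logW_ref = np.empty((n_reference, k_max))
    for b in range(n_reference):
        U = rng.uniform(lo, hi, size=Xp.shape) @ Vt + mu
        for k in range(1, k_max + 1):
            Wb, _ = _pam_dispersion(U, k, rng)
            logW_ref[b, k - 1] = np.log(max(Wb, 1e-300))
    gap = logW_ref.mean(axis=0) - logW
    sdk = logW_ref.std(axis=0, ddof=0)
    se = sdk * np.sqrt(1.0 + 1.0 / n_reference)
    # globalSEmax rule: smallest k whose gap lies within one standard error
    # of the global gap maximum.  The naive "Gap(k) >= Gap(k+1) - s" stop
    # (and its first-local-max refinement) is fooled when the gap curve dips
    # below zero before rising to the true cluster number, as it does for
    # well-separated equal-size curve families.
    i_gmax = int(np.argmax(gap))
    thresh = gap[i_gmax] - se[i_gmax]
    k_opt = int(np.argmax(gap >= thresh)) + 1
    res = k_medoids(SmoothCurveSet(ids, np.arange(X.shape[1]), X),
                    k_opt, seed)
    res.gap = gap
    res.gap_se = se
    return res
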