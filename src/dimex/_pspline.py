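"""Penalized B-spline (P-spline) machinery shared by the count and Gaussian smoothers.

Builds the cubic B-spline design matrix for the phenotype, the second-order
difference penalty, and the sum-to-zero centering reparameterization that
separates the smooth from the intercept.  With a 2nd-order difference penalty
the null space of the penalty (after centering) is the linear functions, so a
fully penalized fit (lambda -> inf) reduces to a straight line and carries one
effective degree of freedom -- the property the nonlinearity call (edf > 1.5)
relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline


@dataclass(frozen=True)
class SmoothSpec:
    """Configuration of the penalized smooth term.

    n_basis cubic B-spline basis functions on equally spaced knots spanning
    the observed phenotype range; penalty_order-th order difference penalty;
    smoothing parameter selected by REML (or GCV) on a log-spaced grid.
    """

    n_basis: int = 10
    degree: int = 3
    penalty_order: int = 2
    smoothing_selection: str = "REML"
    #: parsimony margin for smoothing selection: the largest lambda whose
    #: score is within this many units of the grid minimum is chosen
    score_margin: float = 1.0
    lambda_grid: np.ndarray = field(
        default_factory=lambda: np.exp(np.linspace(-6.0, 18.0, 25))
    )

    def __post_init__(self) -> None:
        if self.n_basis < 4:
            raise ValueError(f"n_basis must be >= 4, got {self.n_basis}")
        if self.smoothing_selection not in ("REML", "GCV"):
            raise ValueError("smoothing_selection must be 'REML' or 'GCV'")
        if self.penalty_order < 1 or self.penalty_order >= self.n_basis:
            raise ValueError("penalty_order must be in [1, n_basis)")


def bspline_design(x: np.ndarray, n_basis: int, degree: int = 3,
                   xrange: tuple[float, float] | None = None) -> np.ndarray:
    """Cubic B-spline design matrix with uniform interior knots.

    Values outside ``xrange`` are clamped to the boundary so that prediction
    grids slightly wider than the training range stay well-defined.
    """
    x = np.asarray(x, dtype=float)
    if xrange is None:
        lo, hi = float(x.min()), float(x.max())
    else:
        lo, hi = map(float, xrange)
    if hi <= lo:
        hi = lo + 1.0
    # Eilers-Marx layout: evenly spaced knots extending past the data range,
    # no repeated boundary knots (uniform local support, including the edges)
    n_seg = n_basis - degree
    if n_seg < 1:
        raise ValueError("n_basis too small for requested degree")
    dx = (hi - lo) / n_seg
    knots = lo + dx * np.arange(-degree, n_seg + degree + 1)
    xc = np.clip(x, lo, hi)
    B = BSpline.design_matrix(xc, knots, degree, extrapolate=False).toarray()
    return B


def difference_penalty(n_basis: int, order: int = 2) -> np.ndarray:
    """S = D'D for the order-th difference matrix D on the coefficients."""
    D = np.diff(np.eye(n_basis), n=order, axis=0)
    return D.T @ D


class SmoothBasis:
    """Centered P-spline basis tied to one observed phenotype vector.

    The raw basis is reparameterized onto the null space of the sum-to-zero
    constraint 1'B beta = 0 (Wood's identifiability constraint), giving
    ``n_basis - 1`` identifiable smooth coefficients, a penalty matrix of the
    same size, and helper projections for evaluating the fitted smooth on an
    arbitrary grid.
    """

    def __init__(self, x: np.ndarray, spec: SmoothSpec):
        x = np.asarray(x, dtype=float)
        n_unique = np.unique(x).size
        if n_unique < 3:
            raise ValueError("phenotype needs at least 3 distinct values")
        # a discrete phenotype with few levels (e.g. a short subscale) cannot
        # identify more basis functions than it has levels; shrink the basis
        n_basis = min(spec.n_basis, max(4, n_unique - 1))
        if n_basis != spec.n_basis:
            spec = SmoothSpec(n_basis=n_basis, degree=spec.degree,
                              penalty_order=spec.penalty_order,
                              smoothing_selection=spec.smoothing_selection,
                              lambda_grid=spec.lambda_grid)
        self.spec = spec
        self.xrange = (float(x.min()), float(x.max()))
        B = bspline_design(x, spec.n_basis, spec.degree, self.xrange)
        # null-space basis of the constraint colmeans(B) @ beta = 0
        c = B.mean(axis=0)[:, None]                      # (K,1)
        q, _ = np.linalg.qr(c, mode="complete")          # (K,K)
        self.Z = q[:, 1:]                                # (K, K-1)
        self.X = B @ self.Z                              # centered design
        S_raw = difference_penalty(spec.n_basis, spec.penalty_order)
        S = self.Z.T @ S_raw @ self.Z
        # normalize the penalty scale so lambda grids are comparable across
        # phenotype scalings
        self.penalty_scale = np.linalg.norm(S, ord=2)
        self.S = S / self.penalty_scale
        self.rank_S = int(np.linalg.matrix_rank(self.S))
        self._x_mean_basis = B.mean(axis=0)

    @property
    def n_coef(self) -> int:
        return self.X.shape[1]

    def evaluate(self, beta_smooth: np.ndarray, grid: np.ndarray) -> np.ndarray:
        """Evaluate the centered smooth f(grid) for coefficient rows.

        beta_smooth may be (n_coef,) or (G, n_coef); returns matching shape
        with the trailing axis replaced by len(grid).
        """
        Bg = bspline_design(grid, self.spec.n_basis, self.spec.degree, self.xrange)
        Bg_c = Bg - self._x_mean_basis[None, :]
        M = Bg_c @ self.Z                                # (m, n_coef)
        return np.atleast_2d(beta_smooth) @ M.T if np.ndim(beta_smooth) > 1 else M @ beta_smooth


def build_design(covariates: np.ndarray | None, basis: SmoothBasis
                 ) -> tuple[np.ndarray, np.ndarray, slice]:
    """Assemble [intercept | covariates | smooth] design and block penalty.

    Returns (X, P, smooth_slice) where P carries the (unit-scaled) smooth
    penalty in its lower-right block and zeros elsewhere.
    """
    n = basis.X.shape[0]
    parts = [np.ones((n, 1))]
    if covariates is not None and covariates.size:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        parts.append(C)
    q = sum(p.shape[1] for p in parts)
    X = np.column_stack(parts + [basis.X])
    p = X.shape[1]
    P = np.zeros((p, p))
    P[q:, q:] = basis.S
    # hard identifiability check on the unpenalized block only (the penalty
    # regularizes the smooth); name the offending columns
    U = X[:, :q]
    rank = np.linalg.matrix_rank(U)
    if rank < q:
        _, R, piv = __import__("scipy.linalg", fromlist=["qr"]).qr(
            U, pivoting=True)
        diag = np.abs(np.diag(R))
        bad = sorted(int(piv[i]) for i in range(q) if i >= rank or
                     diag[i] < diag[0] * 1e-10)
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient: collinear columns "
            f"{bad} (0 = intercept, then covariates in order)")
    return X, P, slice(q, p)


def smooth_wald_pvalue(beta_s: np.ndarray, Vb_s: np.ndarray, edf: np.ndarray,
                       residual_df: np.ndarray | None = None,
                       scale: np.ndarray | None = None) -> np.ndarray:
    """Approximate test of H0: f == 0 for a penalized smooth (batched).

    Wald-type statistic on the smooth coefficients using a rank-r
    pseudo-inverse of their Bayesian covariance, with r tied to the effective
    degrees of freedom; the fractional part of the edf enters as a partial
    weight on the next eigen-direction.  The reference distribution is
    chi-squared with edf degrees of freedom, or an F with (edf, residual_df)
    when a scale estimate is supplied (Gaussian case).
    """
    from scipy import stats

    beta_s = np.atleast_2d(beta_s)
    Vb_s = Vb_s.reshape((-1,) + Vb_s.shape[-2:])
    edf = np.atleast_1d(np.asarray(edf, dtype=float))
    G, ps = beta_s.shape
    # eigh returns ascending eigenvalues; flip to descending
    evals, evecs = np.linalg.eigh(Vb_s)
    evals = evals[:, ::-1]
    evecs = evecs[:, :, ::-1]
    c = np.einsum("gij,gi->gj", evecs, beta_s)           # coords in eigenbasis
    tol = np.maximum(evals[:, 0], 1e-300) * 1e-10
    inv = np.where(evals > tol[:, None], 1.0 / np.maximum(evals, 1e-300), 0.0)
    r = np.clip(edf, 1.0, float(ps))
    k = np.floor(r).astype(int)
    frac = r - k
    idx = np.arange(ps)[None, :]
    w_full = (idx < k[:, None]).astype(float)
    # partial weight on the (k+1)-th direction for non-integer edf
    has_frac = (frac > 1e-8) & (k < ps)
    w_frac = np.where((idx == k[:, None]) & has_frac[:, None], frac[:, None], 0.0)
    T = np.einsum("gj,gj,gj->g", c * (w_full + w_frac), c, inv)
    if scale is not None:
        T = T / np.maximum(scale, 1e-300)
    if residual_df is None:
        p = stats.chi2.sf(T, df=r)
    else:
        p = stats.f.sf(T / r, r, np.maximum(residual_df, 1.0))
    return p
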