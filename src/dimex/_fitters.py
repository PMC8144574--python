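"""Batched penalized-spline fitters.

Both differential-expression engines (negative-binomial counts, Gaussian
continuous features) reduce to the same computation: for every feature, solve
a penalized (iteratively re-)weighted least squares problem at each smoothing
parameter on a log-spaced grid, score the fits with REML (or GCV), and keep
the per-feature optimum.  Fitting all features simultaneously with batched
linear algebra is what makes genome-scale smoothing-parameter selection cheap.
"""

from __future__ import annotations

import numpy as np

_MU_MIN, _MU_MAX = 1e-10, 1e10
_ETA_CLIP = 30.0


def _batched_solve(A: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Solve A[g] x = b[g]; jitter the diagonal on failure. Returns (x, ok)."""
    G, p, _ = A.shape
    ok = np.ones(G, dtype=bool)
    try:
        x = np.linalg.solve(A, b[..., None])[..., 0]
    except np.linalg.LinAlgError:
        x = np.empty_like(b)
        for g in range(G):
            try:
                x[g] = np.linalg.solve(A[g], b[g])
            except np.linalg.LinAlgError:
                try:
                    x[g] = np.linalg.solve(
                        A[g] + 1e-8 * np.trace(A[g]) / p * np.eye(p), b[g])
                except np.linalg.LinAlgError:
                    x[g] = 0.0
                    ok[g] = False
    bad = ~np.isfinite(x).all(axis=1)
    x[bad] = 0.0
    ok &= ~bad
    return x, ok


def _logdet_psd(A: np.ndarray) -> np.ndarray:
    sign, logdet = np.linalg.slogdet(A)
    logdet = np.where(sign > 0, logdet, np.inf)
    return logdet


def nb_deviance(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Negative-binomial deviance summed over samples (batched, var = mu + alpha*mu^2)."""
    y = np.atleast_2d(y)
    mu = np.clip(mu, _MU_MIN, _MU_MAX)
    a = alpha[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(y / mu), 0.0)
    term2 = (y + 1.0 / a) * np.log((1.0 + a * y) / (1.0 + a * mu))
    return 2.0 * np.sum(term1 - term2, axis=1)


def _irls_nb(Y, X, P, offset, alpha, lam, max_iter, tol, eta0=None):
    """Penalized IRLS for NB log-link at one smoothing parameter, all genes at once.

    ``eta0`` warm-starts the linear predictor (e.g. from the fit at the
    previous smoothing parameter on a grid sweep).
    """
    G, n = Y.shape
    p = X.shape[1]
    if eta0 is None:
        mu = np.clip(Y + 0.5, 0.5, None)
        eta = np.log(mu)
    else:
        eta = np.clip(eta0, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
    beta = np.zeros((G, p))
    dev = nb_deviance(Y, mu, alpha)
    converged = np.zeros(G, dtype=bool)
    ok = np.ones(G, dtype=bool)
    lamP = lam * P
    Xw = np.empty((G, n, p))
    A = np.empty((G, p, p))
    for _ in range(max_iter):
        w = mu / (1.0 + alpha[:, None] * mu)            # NB Fisher weights, log link
        z = (eta - offset[None, :]) + (Y - mu) / mu
        np.multiply(X[None, :, :], w[:, :, None], out=Xw)
        XwT = np.swapaxes(Xw, 1, 2)
        np.matmul(XwT, X[None, :, :], out=A)
        A += lamP[None, :, :]
        b = np.matmul(XwT, z[:, :, None])[..., 0]
        beta_new, solve_ok = _batched_solve(A, b)
        ok &= solve_ok
        # freeze genes that already converged to keep their stats stable
        beta = np.where(converged[:, None], beta, beta_new)
        eta = np.clip(beta @ X.T + offset[None, :], -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        dev_new = nb_deviance(Y, mu, alpha)
        delta = np.abs(dev_new - dev) / (np.abs(dev_new) + 0.1)
        converged |= delta < tol
        dev = dev_new
        if converged.all():
            break
    w = mu / (1.0 + alpha[:, None] * mu)
    return beta, mu, w, dev, converged & ok


def _fit_stats(X, P, lam, w, smooth_slice):
    """Shared post-fit quantities: A^{-1}, edf of the smooth and total edf."""
    Xw = X[None, :, :] * w[:, :, None]
    XtWX = np.swapaxes(Xw, 1, 2) @ X[None, :, :]
    A = XtWX + (lam * P)[None, :, :]
    Ainv = np.linalg.inv(A)
    F = Ainv @ XtWX                                     # influence (edf) matrix
    diagF = np.einsum("gii->gi", F)
    edf_total = diagF.sum(axis=1)
    edf_smooth = diagF[:, smooth_slice].sum(axis=1)
    return Ainv, edf_smooth, edf_total


def fit_nb_batch(Y, X, P, offset, alpha, smooth_slice, rank_S,
                 lambda_grid, selection="REML", max_iter=100, tol=1e-6,
                 score_margin: float = 0.0):
    """NB-GAM over a smoothing-parameter grid, one selected fit per gene.

    Smoothing selection minimizes REML (or GCV) on the grid; with
    ``score_margin`` > 0 a parsimony rule applies: among all grid points
    whose score lies within the margin of the minimum, the largest smoothing
    parameter wins (the regularization-path analog of the one-standard-error
    rule), which biases near-ties toward the simpler, smoother fit.

    Returns a dict of per-gene arrays: beta, lambda, edf (smooth), edf_total,
    Vb (Bayesian covariance, scale 1), mu, deviance, converged.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    G, n = Y.shape
    p = X.shape[1]
    grid = np.sort(np.asarray(lambda_grid, dtype=float))
    L = grid.size
    scores = np.full((G, L), np.inf)
    eta_warm = None
    for j, lam in enumerate(grid):
        beta, mu, w, dev, conv = _irls_nb(Y, X, P, offset, alpha, lam,
                                          max_iter, tol, eta0=eta_warm)
        eta_warm = np.log(np.clip(mu, _MU_MIN, _MU_MAX))
        pen = lam * np.einsum("gi,ij,gj->g", beta[:, smooth_slice],
                              P[smooth_slice, smooth_slice],
                              beta[:, smooth_slice])
        Xw = X[None, :, :] * w[:, :, None]
        A = np.swapaxes(Xw, 1, 2) @ X[None, :, :] + (lam * P)[None, :, :]
        sign, logdetA = np.linalg.slogdet(A)
        if selection == "GCV":
            Ainv = np.linalg.inv(A)
            F = Ainv @ (A - (lam * P)[None, :, :])
            edf_t = np.einsum("gii->g", F)
            score = n * dev / np.maximum(n - edf_t, 1.0) ** 2
        else:
            score = dev + pen + logdetA - rank_S * np.log(lam)
        scores[:, j] = np.where(conv & (sign > 0), score, np.inf)
    # per-gene selection: score minimum, then the largest lambda within margin
    jmin = np.argmin(scores, axis=1)
    smin = scores[np.arange(G), jmin]
    within = scores <= (smin + score_margin)[:, None]
    j_sel = L - 1 - np.argmax(within[:, ::-1], axis=1)
    j_sel = np.where(np.isfinite(smin), j_sel, jmin)
    out = {
        "score": smin,
        "beta": np.zeros((G, p)),
        "lambda": grid[j_sel],
        "edf": np.full(G, np.nan),
        "edf_total": np.full(G, np.nan),
        "Vb": np.zeros((G, p, p)),
        "mu": np.ones((G, n)),
        "deviance": np.full(G, np.nan),
        "converged": np.zeros(G, dtype=bool),
    }
    # refit per selected-lambda group and collect full statistics
    for j in np.unique(j_sel):
        idx = np.where(j_sel == j)[0]
        lam = grid[j]
        beta, mu, w, dev, conv = _irls_nb(Y[idx], X, P, offset, alpha[idx],
                                          lam, max_iter, tol)
        Ainv, edf_s, edf_t = _fit_stats(X, P, lam, w, smooth_slice)
        out["beta"][idx] = beta
        out["edf"][idx] = edf_s
        out["edf_total"][idx] = edf_t
        out["Vb"][idx] = Ainv
        out["mu"][idx] = mu
        out["deviance"][idx] = dev
        out["converged"][idx] = conv & np.isfinite(smin[idx])
    return out


def fit_gaussian_batch(Y, X, P, weights, smooth_slice, rank_S, n_unpenalized,
                       lambda_grid, selection="REML", score_margin: float = 0.0):
    """Gaussian penalized spline over a lambda grid with 0/1 sample weights.

    ``weights`` masks missing samples per feature (0 drops a sample).  The
    same parsimony selection rule as the count fitter applies (largest
    lambda within ``score_margin`` of the score minimum).  Returns
    per-feature beta, lambda, edf, Vb (scaled by the residual variance), rss,
    scale, residual_df and a usable flag.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    Yf = np.where(weights > 0, Y, 0.0)
    G, n = Y.shape
    p = X.shape[1]
    n_used = weights.sum(axis=1)
    m_p = n_unpenalized + (X[:, smooth_slice].shape[1] - rank_S)  # unpenalized dims
    grid = np.sort(np.asarray(lambda_grid, dtype=float))
    L = grid.size
    Xw = X[None, :, :] * weights[:, :, None]
    XtWX = np.swapaxes(Xw, 1, 2) @ X[None, :, :]
    b = np.einsum("gnp,gn->gp", Xw, Yf)

    def _solve_at(lam, idx=None):
        sl = slice(None) if idx is None else idx
        A = XtWX[sl] + (lam * P)[None, :, :]
        beta, ok = _batched_solve(A, b[sl])
        resid = (Yf[sl] - beta @ X.T) * weights[sl]
        rss = np.einsum("gn,gn->g", resid, resid)
        return A, beta, ok, rss

    scores = np.full((G, L), np.inf)
    for j, lam in enumerate(grid):
        A, beta, ok, rss = _solve_at(lam)
        pen = lam * np.einsum("gi,ij,gj->g", beta[:, smooth_slice],
                              P[smooth_slice, smooth_slice],
                              beta[:, smooth_slice])
        sign, logdetA = np.linalg.slogdet(A)
        if selection == "GCV":
            Ainv = np.linalg.inv(A)
            F = Ainv @ XtWX
            edf_t = np.einsum("gii->g", F)
            score = n_used * rss / np.maximum(n_used - edf_t, 1.0) ** 2
        else:
            score = (np.maximum(n_used - m_p, 1.0)
                     * np.log(np.maximum(rss + pen, 1e-300))
                     + logdetA - rank_S * np.log(lam))
        scores[:, j] = np.where(ok & (sign > 0), score, np.inf)
    jmin = np.argmin(scores, axis=1)
    smin = scores[np.arange(G), jmin]
    within = scores <= (smin + score_margin)[:, None]
    j_sel = L - 1 - np.argmax(within[:, ::-1], axis=1)
    j_sel = np.where(np.isfinite(smin), j_sel, jmin)
    out = {
        "score": smin,
        "beta": np.zeros((G, p)),
        "lambda": grid[j_sel],
        "edf": np.full(G, np.nan),
        "edf_total": np.full(G, np.nan),
        "Vb": np.zeros((G, p, p)),
        "rss": np.full(G, np.nan),
        "scale": np.full(G, np.nan),
        "residual_df": np.full(G, np.nan),
        "converged": np.zeros(G, dtype=bool),
    }
    for j in np.unique(j_sel):
        idx = np.where(j_sel == j)[0]
        lam = grid[j]
        A, beta, ok, rss = _solve_at(lam, idx)
        Ainv = np.linalg.inv(A)
        F = Ainv @ XtWX[idx]
        diagF = np.einsum("gii->gi", F)
        edf_t = diagF.sum(axis=1)
        edf_s = diagF[:, smooth_slice].sum(axis=1)
        dof = np.maximum(n_used[idx] - edf_t, 1.0)
        out["beta"][idx] = beta
        out["edf"][idx] = edf_s
        out["edf_total"][idx] = edf_t
        out["Vb"][idx] = Ainv
        out["rss"][idx] = rss
        out["scale"][idx] = rss / dof
        out["residual_df"][idx] = dof
        out["converged"][idx] = ok & np.isfinite(smin[idx])
    return out


def estimate_dispersion_ml(Y: np.ndarray, mu: np.ndarray,
                           grid: np.ndarray | None = None) -> np.ndarray:
    """Per-gene NB dispersion by profile ML on a log grid given fitted means.

    Maximizes the NB log-likelihood in alpha with mu held fixed; a parabolic
    refinement around the grid optimum gives sub-grid resolution.
    """
    from scipy.special import gammaln

    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    mu = np.clip(np.atleast_2d(mu), _MU_MIN, _MU_MAX)
    if grid is None:
        grid = np.exp(np.linspace(np.log(1e-4), np.log(10.0), 31))
    G = Y.shape[0]
    nll = np.empty((G, grid.size))
    for j, a in enumerate(grid):
        r = 1.0 / a
        ll = (gammaln(Y + r) - gammaln(r)
              + Y * np.log(a * mu / (1.0 + a * mu))
              - r * np.log1p(a * mu))
        nll[:, j] = -ll.sum(axis=1)
    jbest = np.argmin(nll, axis=1)
    log_a = np.log(grid)[jbest]
    # parabolic interpolation where the optimum is interior
    interior = (jbest > 0) & (jbest < grid.size - 1)
    if interior.any():
        gi = np.where(interior)[0]
        j = jbest[gi]
        x0, x1, x2 = np.log(grid)[j - 1], np.log(grid)[j], np.log(grid)[j + 1]
        y0 = nll[gi, j - 1]
        y1 = nll[gi, j]
        y2 = nll[gi, j + 1]
        denom = (y0 - 2 * y1 + y2)
        shift = np.where(np.abs(denom) > 1e-12,
                         0.5 * (y0 - y2) / np.maximum(denom, 1e-12), 0.0)
        log_a[gi] = x1 + np.clip(shift, -1.0, 1.0) * (x2 - x1)
    return np.exp(log_a)


def estimate_dispersion_pearson(Y: np.ndarray, mu: np.ndarray,
                                df_resid: np.ndarray) -> np.ndarray:
    """Per-gene NB dispersion from Pearson residuals with df correction.

    Solves sum_i (y_i - mu_i)^2 / (mu_i (1 + alpha mu_i)) = df_resid for
    alpha by bisection on the log scale.  Subtracting the model's effective
    degrees of freedom from n corrects the downward bias that a fitted-mean
    plug-in estimator would otherwise have, which matters for test
    calibration downstream.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    mu = np.clip(np.atleast_2d(mu), _MU_MIN, _MU_MAX)
    df_resid = np.maximum(np.atleast_1d(df_resid), 1.0)
    r2 = (Y - mu) ** 2
    lo = np.full(Y.shape[0], np.log(1e-6))
    hi = np.full(Y.shape[0], np.log(100.0))

    def excess(log_a):
        a = np.exp(log_a)[:, None]
        return (r2 / (mu * (1.0 + a * mu))).sum(axis=1) - df_resid

    # the statistic is monotone decreasing in alpha
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        val = excess(mid)
        hi = np.where(val < 0, mid, hi)
        lo = np.where(val >= 0, mid, lo)
    return np.exp(0.5 * (lo + hi))


def shrink_dispersion_to_trend(alpha_ml: np.ndarray, mean_expr: np.ndarray,
                               weight: float = 0.5) -> np.ndarray:
    """Moderate gene-wise dispersions toward a log-linear mean-dispersion trend.

    The trend regresses log(alpha) on log(mean normalized count); each gene's
    final log-dispersion is a fixed-weight blend of its ML estimate and the
    trend prediction, stabilizing small-sample fits.
    """
    la = np.log(np.clip(alpha_ml, 1e-6, None))
    lm = np.log(np.clip(mean_expr, 1e-6, None))
    if la.size < 3 or np.ptp(lm) < 1e-12:
        trend = np.full_like(la, la.mean())
    else:
        coef = np.polyfit(lm, la, 1)
        trend = np.polyval(coef, lm)
    return np.exp((1.0 - weight) * la + weight * trend)
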