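"""Gene-level differential expression with a negative-binomial GAM.

The phenotype (total PCL or one of the four symptom dimensions) enters the
model through a penalized cubic spline, so both linear and nonlinear
expression-phenotype relationships are captured by one fit:

    log E[count_gi] = log(s_i) + beta_0 + f(pheno_i) + covariates_i' gamma

with a negative-binomial likelihood (var = mu + alpha * mu^2), library-size
factors s_i as an offset, and the smoothness of f chosen by REML.  The
effective degrees of freedom (edf) of f quantify nonlinearity: edf = 1 means
the fit collapsed to a straight line; significant genes with edf > 1.5 are
called nonlinear.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._fitters import (estimate_dispersion_pearson, fit_nb_batch,
                       nb_deviance, shrink_dispersion_to_trend)
from ._pspline import SmoothBasis, SmoothSpec, build_design, smooth_wald_pvalue

__all__ = [
    "SmoothSpec", "GeneFit", "estimate_size_factors", "filter_low_counts",
    "bh_fdr", "fit_nb_gam", "run_de", "CURVE_GRID_SIZE",
]

CURVE_GRID_SIZE = 100


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library-size factors, rescaled to geometric mean 1.

    Per sample: the median across all-sample-expressed genes of
    count / geometric-mean(gene).  Raises if no gene is expressed in every
    sample (the estimator is undefined; filter first).
    """
    mat = counts.to_numpy(dtype=float)
    expressed = (mat > 0).all(axis=1)
    if not expressed.any():
        raise ValueError(
            "no gene has nonzero counts in all samples; "
            "filter the count matrix or check sample quality")
    sub = mat[expressed]
    log_geo = np.log(sub).mean(axis=1, keepdims=True)
    ratios = np.log(sub) - log_geo
    log_sf = np.median(ratios, axis=0)
    log_sf = log_sf - log_sf.mean()                      # geometric mean 1
    return pd.Series(np.exp(log_sf), index=counts.columns, name="size_factor")


def filter_low_counts(counts: pd.DataFrame, min_mean: float = 5.0,
                      logger=None) -> pd.DataFrame:
    """Drop features whose mean raw count falls below ``min_mean``."""
    keep = counts.mean(axis=1) >= min_mean
    removed = 1.0 - keep.mean() if len(keep) else 0.0
    if logger is not None:
        logger.info("low-count filter: removed %.1f%% of %d features",
                    100 * removed, len(keep))
    return counts.loc[keep]


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values; NaNs pass through."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    m = ok.sum()
    if m == 0:
        return q
    ps = p[ok]
    order = np.argsort(ps, kind="stable")
    ranked = ps[order] * m / (np.arange(m) + 1.0)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    q[ok] = out
    return q


@dataclass
class GeneFit:
    """One gene's fitted NB-GAM."""
    gene_id: str
    coefficients: np.ndarray
    smoothing_parameter: float
    dispersion: float
    edf: float
    p_value: float
    fitted_curve: np.ndarray
    curve_grid: np.ndarray
    converged: bool


def _prepare_design(phenotype, covariates, spec):
    pheno = np.asarray(phenotype, dtype=float)
    basis = SmoothBasis(pheno, spec)
    cov = None
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        # standardize covariates for numerical stability; offsets absorb into
        # the intercept, scalings into the coefficients
        sd = cov.std(axis=0)
        sd[sd == 0] = 1.0
        cov = (cov - cov.mean(axis=0)) / sd
    X, P, sm = build_design(cov, basis)
    return basis, X, P, sm


def _run_batch(Y, phenotype, covariates, size_factors, spec, dispersion=None,
               dispersion_shrink=0.5):
    """Two-pass batched fit: initial dispersion -> ML + trend shrink -> final fit."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n = Y.shape[1]
    basis, X, P, sm = _prepare_design(phenotype, covariates, spec)
    if X.shape[1] + 1 >= n:
        raise ValueError(
            f"model has {X.shape[1]} coefficients but only {n} samples")
    sf = np.asarray(size_factors, dtype=float)
    offset = np.log(sf)
    norm = Y / sf[None, :]
    mean_expr = norm.mean(axis=1)
    if dispersion is None:
        # method-of-moments start, ignoring covariates (upward biased, safe)
        v = norm.var(axis=1, ddof=1)
        alpha0 = np.clip((v - mean_expr) / np.maximum(mean_expr, 1e-8) ** 2,
                         1e-4, 10.0)
        # coarse smoothing grid suffices for the pilot fit: only the fitted
        # means and total edf feed the dispersion estimator
        coarse = spec.lambda_grid[:: max(1, len(spec.lambda_grid) // 7)]
        fit0 = fit_nb_batch(Y, X, P, offset, alpha0, sm, basis.rank_S,
                            coarse, spec.smoothing_selection,
                            score_margin=spec.score_margin)
        alpha_gw = estimate_dispersion_pearson(Y, fit0["mu"],
                                               n - fit0["edf_total"])
        trended = shrink_dispersion_to_trend(alpha_gw, mean_expr,
                                             weight=dispersion_shrink)
        # moderate upward only: genes below the mean-dispersion trend are
        # pulled toward it, above-trend genes keep their own estimate
        alpha = np.maximum(alpha_gw, trended)
    else:
        alpha = np.broadcast_to(np.asarray(dispersion, dtype=float),
                                (Y.shape[0],)).copy()
    fit = fit_nb_batch(Y, X, P, offset, alpha, sm, basis.rank_S,
                       spec.lambda_grid, spec.smoothing_selection,
                       score_margin=spec.score_margin)
    edf = np.clip(fit["edf"], 1.0, None)
    Vb_s = fit["Vb"][:, sm, sm.start:]
    pvals = smooth_wald_pvalue(fit["beta"][:, sm], Vb_s, edf)
    pvals = np.where(fit["converged"], pvals, np.nan)
    return {
        "basis": basis, "design": X, "smooth_slice": sm, "alpha": alpha,
        "beta": fit["beta"], "lambda": fit["lambda"], "edf": edf,
        "p": pvals, "converged": fit["converged"], "mu": fit["mu"],
        "deviance": fit["deviance"], "mean_expr": mean_expr,
    }


def fit_nb_gam(gene_counts, phenotype, covariates, size_factors,
               smooth_spec: SmoothSpec | None = None,
               dispersion: float | None = None,
               gene_id: str = "gene") -> GeneFit:
    """Fit the NB-GAM for a single gene and return its :class:`GeneFit`."""
    spec = smooth_spec or SmoothSpec()
    res = _run_batch(np.atleast_2d(gene_counts), phenotype, covariates,
                     size_factors, spec, dispersion=dispersion)
    basis = res["basis"]
    grid = np.linspace(*basis.xrange, CURVE_GRID_SIZE)
    curve = basis.evaluate(res["beta"][0, res["smooth_slice"]], grid)
    return GeneFit(
        gene_id=gene_id,
        coefficients=res["beta"][0],
        smoothing_parameter=float(res["lambda"][0]),
        dispersion=float(res["alpha"][0]),
        edf=float(res["edf"][0]),
        p_value=float(res["p"][0]),
        fitted_curve=np.asarray(curve),
        curve_grid=grid,
        converged=bool(res["converged"][0]),
    )


def run_de(counts: pd.DataFrame, phenotype, covariates=None,
           smooth_spec: SmoothSpec | None = None,
           size_factors: pd.Series | None = None,
           alpha: float = 0.05, edf_nonlinear: float = 1.5,
           dispersion_shrink: float = 0.5) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Differential expression of every gene against one phenotype.

    Parameters
    ----------
    counts : genes x samples integer DataFrame (already low-count filtered).
    phenotype : per-sample phenotype vector (aligned with columns).
    covariates : optional samples x k array/DataFrame of adjustment covariates
        (age, race, cell-type proportions, surrogate variables).
    alpha, edf_nonlinear : FDR cutoff and edf cutoff of the nonlinearity call.

    Returns
    -------
    (results, curves): results has per-gene p_value, fdr, edf, nonlinear,
    mean_expression, converged; curves holds each gene's centered fitted
    smooth evaluated on a common 100-point phenotype grid.
    """
    spec = smooth_spec or SmoothSpec()
    if isinstance(covariates, pd.DataFrame):
        covariates = covariates.to_numpy(dtype=float)
    if size_factors is None:
        size_factors = estimate_size_factors(counts)
    res = _run_batch(counts.to_numpy(dtype=float), phenotype, covariates,
                     size_factors.to_numpy(), spec,
                     dispersion_shrink=dispersion_shrink)
    p = res["p"]
    fdr = bh_fdr(p)   # non-converged genes carry NaN p and are excluded
    nonlinear = (fdr < alpha) & (res["edf"] > edf_nonlinear)
    results = pd.DataFrame({
        "p_value": p,
        "fdr": fdr,
        "edf": res["edf"],
        "nonlinear": nonlinear,
        "mean_expression": res["mean_expr"],
        "dispersion": res["alpha"],
        "converged": res["converged"],
    }, index=counts.index.rename("feature_id"))
    basis = res["basis"]
    grid = np.linspace(*basis.xrange, CURVE_GRID_SIZE)
    curves = basis.evaluate(res["beta"][:, res["smooth_slice"]], grid)
    curves = pd.DataFrame(np.atleast_2d(curves), index=results.index,
                          columns=[f"{g:.6g}" for g in grid])
    return results, curves


def nb_gam_deviance(y, mu, alpha):
    """Public wrapper around the NB deviance used by the fitter."""
    return nb_deviance(np.atleast_2d(y), np.atleast_2d(mu),
                       np.atleast_1d(alpha))
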