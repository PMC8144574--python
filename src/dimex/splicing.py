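"""Isoform and alternative-splicing differential analysis.

Percent-spliced-in (PSI) of an AS event is the TPM of its inclusion
transcripts over the TPM of all its transcripts.  Analysis happens on the
log-odds scale, PSI_logit = log(PSI / (1 - PSI)), which frees the spline
regression from the [0, 1] boundary.  Isoform-level analysis models
log(TPM + 1).  Both feed the same Gaussian penalized-spline engine: a smooth
in the phenotype plus linear covariates, an F-type test of the smooth, and
Benjamini-Hochberg FDR — the continuous-response analog of the count model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._fitters import fit_gaussian_batch
from ._pspline import SmoothBasis, SmoothSpec, build_design, smooth_wald_pvalue
from .nbgam import CURVE_GRID_SIZE, bh_fdr

__all__ = [
    "compute_psi", "compute_psi_matrix", "logit_psi", "transform_isoforms",
    "filter_low_tpm", "run_continuous_de",
]


def compute_psi(inclusion: list[str], total: list[str], tpm: pd.DataFrame,
                min_total_tpm: float = 1.0, event_id: str = "?") -> pd.Series:
    """PSI of one event: sum TPM(inclusion) / sum TPM(total) per sample.

    Samples whose total transcript abundance falls below ``min_total_tpm``
    get NaN — a ratio of near-zero abundances carries no splicing signal.
    """
    missing = [t for t in set(inclusion) | set(total) if t not in tpm.index]
    if missing:
        raise KeyError(
            f"event {event_id}: transcripts {sorted(missing)} absent from TPM matrix")
    if not inclusion or not total:
        raise ValueError(f"event {event_id}: empty transcript set")
    inc = tpm.loc[list(inclusion)].sum(axis=0)
    tot = tpm.loc[list(total)].sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        psi = inc / tot
    return psi.where(tot >= min_total_tpm)


def compute_psi_matrix(catalog: pd.DataFrame, tpm: pd.DataFrame,
                       min_total_tpm: float = 1.0) -> pd.DataFrame:
    """PSI for every event of an ioe catalog (events x samples)."""
    rows = {}
    for event_id, row in catalog.iterrows():
        inc = str(row["inclusion_transcripts"]).split(",")
        tot = str(row["total_transcripts"]).split(",")
        if not set(inc) < set(tot):
            raise ValueError(
                f"event {event_id}: inclusion transcripts must be a proper "
                "subset of total transcripts")
        rows[event_id] = compute_psi(inc, tot, tpm, min_total_tpm, event_id)
    out = pd.DataFrame(rows).T
    out.index.name = "event_id"
    return out


def logit_psi(psi_ori, eps: float = 0.01):
    """Natural-log odds of PSI, clipped to [eps, 1-eps]; NaN passes through."""
    if not 0.0 < eps < 0.5:
        raise ValueError(f"eps must lie in (0, 0.5), got {eps}")
    arr = np.asarray(psi_ori, dtype=float)
    clipped = np.clip(arr, eps, 1.0 - eps)
    out = np.where(np.isnan(arr), np.nan, np.log(clipped / (1.0 - clipped)))
    if isinstance(psi_ori, pd.DataFrame):
        return pd.DataFrame(out, index=psi_ori.index, columns=psi_ori.columns)
    if isinstance(psi_ori, pd.Series):
        return pd.Series(out, index=psi_ori.index)
    return out if out.ndim else float(out)


def transform_isoforms(tpm: pd.DataFrame) -> pd.DataFrame:
    """log(TPM + 1), elementwise."""
    if (tpm.to_numpy() < 0).any():
        raise ValueError("TPM matrix contains negative values")
    return np.log1p(tpm)


def filter_low_tpm(tpm: pd.DataFrame, min_mean_tpm: float = 1.0,
                   logger=None) -> pd.DataFrame:
    """Drop isoforms with mean TPM below threshold; logs the removed share."""
    keep = tpm.mean(axis=1) >= min_mean_tpm
    if logger is not None:
        logger.info("low-TPM filter: removed %.1f%% of %d isoforms",
                    100 * (1 - keep.mean()), len(keep))
    return tpm.loc[keep]


def run_continuous_de(features: pd.DataFrame, phenotype, covariates=None,
                      smooth_spec: SmoothSpec | None = None,
                      alpha: float = 0.05, edf_nonlinear: float = 1.5,
                      min_frac_present: float = 0.8
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spline-regression DE for continuous features (logit-PSI, log TPM).

    Per feature, samples with NaN are dropped (weight 0); features usable in
    fewer than ``min_frac_present`` of samples, or with too few samples to
    identify the model, or with zero variance, are excluded and reported
    with NaN p.  Returns (results, fitted curves on a common grid), with the
    same schema as the count-model output.
    """
    spec = smooth_spec or SmoothSpec()
    if isinstance(covariates, pd.DataFrame):
        covariates = covariates.to_numpy(dtype=float)
    Y = features.to_numpy(dtype=float)
    G, n = Y.shape
    pheno = np.asarray(phenotype, dtype=float)
    basis = SmoothBasis(pheno, spec)
    cov = None
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        sd = cov.std(axis=0)
        sd[sd == 0] = 1.0
        cov = (cov - cov.mean(axis=0)) / sd
    X, P, sm = build_design(cov, basis)
    p_coef = X.shape[1]
    weights = np.isfinite(Y).astype(float)
    n_used = weights.sum(axis=1)
    variance = np.nanvar(Y, axis=1)
    usable = ((n_used >= min_frac_present * n)
              & (n_used >= p_coef + 2)
              & (variance > 1e-12))
    fit = fit_gaussian_batch(np.where(usable[:, None], Y, 0.0), X, P, weights,
                             sm, basis.rank_S,
                             n_unpenalized=sm.start,
                             lambda_grid=spec.lambda_grid,
                             selection=spec.smoothing_selection,
                             score_margin=spec.score_margin)
    edf = np.clip(fit["edf"], 1.0, None)
    Vb_s = fit["Vb"][:, sm, sm.start:] * fit["scale"][:, None, None]
    pvals = smooth_wald_pvalue(fit["beta"][:, sm], Vb_s, edf,
                               residual_df=fit["residual_df"])
    pvals = np.where(usable & fit["converged"], pvals, np.nan)
    fdr = bh_fdr(pvals)
    nonlinear = (fdr < alpha) & (edf > edf_nonlinear)
    results = pd.DataFrame({
        "p_value": pvals,
        "fdr": fdr,
        "edf": np.where(usable, edf, np.nan),
        "nonlinear": nonlinear,
        "mean_expression": np.nanmean(Y, axis=1),
        "converged": usable & fit["converged"],
    }, index=features.index.rename("feature_id"))
    grid = np.linspace(*basis.xrange, CURVE_GRID_SIZE)
    curves = basis.evaluate(fit["beta"][:, sm], grid)
    curves = pd.DataFrame(np.atleast_2d(curves), index=results.index,
                          columns=[f"{g:.6g}" for g in grid])
    return results, curves
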