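"""Synthetic PTSD cohort generator.

Emulates the statistical structure of a male trauma-exposed cohort assessed
with the 17-item PTSD Checklist (PCL-17): items scored 1-5, four correlated
symptom subdimensions (re-experiencing, avoidance, numbing, hyperarousal),
total = sum of items, plus the adjustment covariates the differential
expression models expect (age, race, five immune cell proportions, surrogate
variables).  Expression data are negative-binomial counts and isoform TPMs
with planted null / linear / nonlinear phenotype effects, and alternative
splicing events whose percent-spliced-in values carry logit-scale effects.
Every generated feature is annotated in a ground-truth table so downstream
stages can be scored for recovery.

Item scores come from a latent multivariate normal: four equicorrelated
dimension factors, one loading per item, and thresholds chosen so the item
(hence total) distribution matches the cohort descriptives the generator
targets (mean total around 36.6, dimension correlations in the 0.6-0.85
band).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec", "DIMENSIONS", "ITEM_MAP", "COVARIATE_COLUMNS",
    "NONLINEAR_SHAPES", "shape_function", "generate_truth",
    "generate_phenotypes", "generate_counts", "generate_isoform_tpm",
    "generate_psi_truth",
]

#: the four PCL symptom dimensions, in fixed order
DIMENSIONS = ("reexperiencing", "avoidance", "numbing", "hyperarousal")

#: DSM-IV four-factor split of the 17 items (5/2/5/5)
ITEM_MAP = {
    "reexperiencing": tuple(range(1, 6)),
    "avoidance": (6, 7),
    "numbing": tuple(range(8, 13)),
    "hyperarousal": tuple(range(13, 18)),
}

CELL_TYPES = ("CD4T", "CD8T", "monocytes", "NK", "B")
COVARIATE_COLUMNS = ("age", "race") + CELL_TYPES + ("sv1", "sv2")

#: five nonlinear smooth archetypes planted in expression-phenotype effects
NONLINEAR_SHAPES = ("quadratic", "saturating", "sigmoid", "U", "inverted_U")

#: marginal item-score distribution (scores 1..5); right-skewed as symptom
#: checklists in mostly subclinical cohorts are, tuned so E[total] ~ 36.6
_ITEM_PROBS = np.array([0.45, 0.22, 0.15, 0.11, 0.07])

#: default AS event-type mix (SE modal, as in transcriptome-wide catalogs)
EVENT_TYPE_PROBS = {
    "SE": 0.435, "A3": 0.14, "A5": 0.12, "RI": 0.12,
    "AF": 0.10, "MX": 0.05, "AL": 0.035,
}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort."""

    n_subjects: int = 226
    n_genes: int = 500
    n_isoforms: int = 300
    n_events: int = 200
    frac_null: float = 0.8
    frac_linear: float = 0.1
    frac_nonlinear: float = 0.1
    effect_size: float = 0.5          # log-scale amplitude of planted effects
    dispersion_mean: float = 0.1      # log-normal center of NB dispersions
    dispersion_sd: float = 0.5        # log-normal sd of NB dispersions
    dimension_correlation: float = 0.85
    item_loading: float = 0.70        # variance share of the dimension factor
    library_sd: float = 0.15          # log-normal spread of library factors
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_genes", "n_isoforms", "n_events"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        total = self.frac_null + self.frac_linear + self.frac_nonlinear
        if abs(total - 1.0) > 1e-8:
            raise ValueError(
                f"effect-class fractions must sum to 1, got {total}")
        if not 0.0 < self.dimension_correlation < 1.0:
            raise ValueError("dimension_correlation must lie in (0, 1)")
        if not 0.0 < self.item_loading < 1.0:
            raise ValueError("item_loading must lie in (0, 1)")


def _rng(spec: CohortSpec, stream: int) -> np.random.Generator:
    # one independent child stream per operation so each output is
    # reproducible regardless of call order
    return np.random.default_rng([spec.seed, stream])


def shape_function(shape_id: str, x01: np.ndarray) -> np.ndarray:
    """Evaluate a named effect archetype on phenotype scaled to [0, 1].

    Shapes are standardized downstream, so only their form matters here.
    """
    x = np.asarray(x01, dtype=float)
    if shape_id == "linear":
        return x
    if shape_id == "quadratic":
        return x**2
    if shape_id == "saturating":
        return 1.0 - np.exp(-4.0 * x)
    if shape_id == "sigmoid":
        return 1.0 / (1.0 + np.exp(-10.0 * (x - 0.5)))
    if shape_id == "U":
        return (x - 0.5) ** 2
    if shape_id == "inverted_U":
        return -((x - 0.5) ** 2)
    raise ValueError(f"unknown shape_id {shape_id!r}")


def _standardized_effect(shape_id: str, x01: np.ndarray) -> np.ndarray:
    f = shape_function(shape_id, x01)
    sd = f.std()
    if sd < 1e-12:
        return np.zeros_like(f)
    return (f - f.mean()) / sd


def generate_truth(spec: CohortSpec, n_features: int | None = None,
                   prefix: str = "gene", stream: int = 11) -> pd.DataFrame:
    """Assign effect classes, shapes, and amplitudes to features.

    Null features have amplitude 0; nonlinear features draw one of the five
    shape archetypes; amplitudes are the spec's effect size with random sign.
    """
    rng = _rng(spec, stream)
    n = spec.n_genes if n_features is None else n_features
    classes = rng.choice(
        ["null", "linear", "nonlinear"], size=n,
        p=[spec.frac_null, spec.frac_linear, spec.frac_nonlinear])
    shapes = np.where(
        classes == "nonlinear",
        rng.choice(NONLINEAR_SHAPES, size=n), "")
    signs = rng.choice([-1.0, 1.0], size=n)
    amplitude = np.where(classes == "null", 0.0, spec.effect_size * signs)
    return pd.DataFrame({
        "feature_id": [f"{prefix}{i:05d}" for i in range(n)],
        "effect_class": classes,
        "shape_id": shapes,
        "amplitude": amplitude,
    }).set_index("feature_id")


def generate_phenotypes(spec: CohortSpec) -> pd.DataFrame:
    """Draw the per-subject phenotype table.

    Latent model: four equicorrelated standard-normal dimension factors;
    each item loads on its dimension with loading sqrt(item_loading) and is
    thresholded to the 1-5 ordinal scale.  Subscales are sums of their
    items; total PCL is the sum of all 17.
    """
    rng = _rng(spec, 1)
    n = spec.n_subjects
    rho = spec.dimension_correlation
    cov = np.full((4, 4), rho)
    np.fill_diagonal(cov, 1.0)
    zdim = rng.multivariate_normal(np.zeros(4), cov, size=n)   # (n, 4)
    lam = np.sqrt(spec.item_loading)
    from scipy.stats import norm
    thresholds = norm.ppf(np.cumsum(_ITEM_PROBS)[:-1])
    items = np.empty((n, 17), dtype=int)
    for d, dim in enumerate(DIMENSIONS):
        for item in ITEM_MAP[dim]:
            latent = lam * zdim[:, d] + np.sqrt(1 - lam**2) * rng.normal(size=n)
            items[:, item - 1] = 1 + np.searchsorted(thresholds, latent,
                                                     side="left")
            # searchsorted against the 4 thresholds yields 0..4
    table = pd.DataFrame(
        items, columns=[f"item_{i:02d}" for i in range(1, 18)],
        index=pd.Index([f"S{i:03d}" for i in range(n)], name="subject_id"))
    for dim in DIMENSIONS:
        table[dim] = items[:, [i - 1 for i in ITEM_MAP[dim]]].sum(axis=1)
    table["total_pcl"] = items.sum(axis=1)
    table["age"] = np.round(rng.normal(52.67, 8.02, size=n), 1)
    table["race"] = rng.binomial(1, 0.845, size=n)
    # five lymphoid/myeloid proportions; granulocytes take the (variable)
    # remainder, so the five do not sum to a constant
    lymphoid_total = rng.beta(9.0, 11.0, size=n)[:, None]
    props = rng.dirichlet([15.0, 8.0, 8.0, 6.0, 4.0], size=n) * lymphoid_total
    for j, ct in enumerate(CELL_TYPES):
        table[ct] = props[:, j]
    table["sv1"] = rng.normal(size=n)
    table["sv2"] = rng.normal(size=n)
    return table


def _scaled_phenotype(phenotypes: pd.DataFrame, column: str) -> np.ndarray:
    x = phenotypes[column].to_numpy(dtype=float)
    lo, hi = x.min(), x.max()
    return (x - lo) / (hi - lo) if hi > lo else np.zeros_like(x)


def _covariate_effects(phenotypes: pd.DataFrame, n_features: int,
                       rng: np.random.Generator, sd: float = 0.05
                       ) -> np.ndarray:
    C = phenotypes.loc[:, list(COVARIATE_COLUMNS)].to_numpy(dtype=float)
    C = (C - C.mean(axis=0)) / np.where(C.std(axis=0) > 0, C.std(axis=0), 1.0)
    coef = rng.normal(0.0, sd, size=(n_features, C.shape[1]))
    return coef @ C.T                                      # (features, subjects)


def _effect_matrix(truth: pd.DataFrame, x01: np.ndarray) -> np.ndarray:
    eff = np.zeros((len(truth), x01.size))
    for shape in ("linear",) + NONLINEAR_SHAPES:
        rows = ((truth["effect_class"] == ("linear" if shape == "linear"
                                           else "nonlinear"))
                & ((truth["shape_id"] == shape) | (shape == "linear")))
        if rows.any():
            f = _standardized_effect(shape, x01)
            eff[rows.to_numpy()] = f[None, :]
    return eff * truth["amplitude"].to_numpy()[:, None]


def generate_counts(spec: CohortSpec, phenotypes: pd.DataFrame,
                    truth: pd.DataFrame, phenotype_column: str = "total_pcl",
                    library_factors: np.ndarray | None = None) -> pd.DataFrame:
    """Negative-binomial gene counts with planted phenotype effects.

    log-mean = baseline + amplitude * f_shape(scaled phenotype)
             + covariate effects + log(library factor);
    dispersion per gene is log-normal around ``dispersion_mean``.
    """
    if not truth.index.is_unique or len(truth) < spec.n_genes:
        raise ValueError("truth table must cover all genes with unique ids")
    rng = _rng(spec, 2)
    n, G = spec.n_subjects, spec.n_genes
    truth = truth.iloc[:G]
    x01 = _scaled_phenotype(phenotypes, phenotype_column)
    baseline = rng.uniform(np.log(20.0), np.log(500.0), size=G)
    alpha = np.exp(rng.normal(np.log(spec.dispersion_mean),
                              spec.dispersion_sd, size=G))
    if library_factors is None:
        lib = np.exp(rng.normal(0.0, spec.library_sd, size=n))
        lib /= np.exp(np.log(lib).mean())
    else:
        lib = np.asarray(library_factors, dtype=float)
    logmu = (baseline[:, None]
             + _effect_matrix(truth, x01)
             + _covariate_effects(phenotypes, G, rng)
             + np.log(lib)[None, :])
    mu = np.exp(np.clip(logmu, -30, 30))
    counts = rng.negative_binomial(1.0 / alpha[:, None],
                                   1.0 / (1.0 + alpha[:, None] * mu))
    return pd.DataFrame(counts, index=truth.index.copy(),
                        columns=phenotypes.index.copy())


def generate_isoform_tpm(spec: CohortSpec, phenotypes: pd.DataFrame,
                         truth: pd.DataFrame,
                         phenotype_column: str = "total_pcl",
                         tpm_total: float = 1e6) -> pd.DataFrame:
    """Isoform abundances with planted effects, normalized to TPM columns."""
    if len(truth) < spec.n_isoforms:
        raise ValueError("truth table must cover all isoforms")
    rng = _rng(spec, 3)
    n, K = spec.n_subjects, spec.n_isoforms
    truth = truth.iloc[:K]
    x01 = _scaled_phenotype(phenotypes, phenotype_column)
    baseline = rng.uniform(np.log(1.0), np.log(200.0), size=K)
    noise = rng.normal(0.0, 0.4, size=(K, n))
    logab = (baseline[:, None] + _effect_matrix(truth, x01)
             + _covariate_effects(phenotypes, K, rng) + noise)
    ab = np.exp(np.clip(logab, -30, 30))
    tpm = ab / ab.sum(axis=0, keepdims=True) * tpm_total
    return pd.DataFrame(tpm, index=truth.index.copy(),
                        columns=phenotypes.index.copy())


def generate_psi_truth(spec: CohortSpec, phenotypes: pd.DataFrame,
                       truth: pd.DataFrame,
                       phenotype_column: str = "total_pcl",
                       psi_noise_sd: float = 0.4,
                       tpm_total: float = 1e6
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Alternative-splicing events with logit-scale planted PSI effects.

    Returns (event catalog, transcript TPM matrix).  Each event owns one or
    two inclusion transcripts and one or two exclusion transcripts; the
    event's gene-level abundance is split between them according to a PSI
    drawn as sigmoid(baseline logit + amplitude * f_shape + noise).  Because
    PSI is a within-event ratio, TPM renormalization leaves it intact.
    """
    if len(truth) < spec.n_events:
        raise ValueError("truth table must cover all events")
    rng = _rng(spec, 4)
    n, E = spec.n_subjects, spec.n_events
    truth = truth.iloc[:E]
    x01 = _scaled_phenotype(phenotypes, phenotype_column)
    types = rng.choice(list(EVENT_TYPE_PROBS), size=E,
                       p=list(EVENT_TYPE_PROBS.values()))
    effect = _effect_matrix(truth, x01)                    # logit-scale
    base_logit = rng.normal(0.0, 0.8, size=E)
    logit = base_logit[:, None] + effect + rng.normal(0.0, psi_noise_sd,
                                                      size=(E, n))
    psi = 1.0 / (1.0 + np.exp(-logit))
    gene_ab = np.exp(rng.normal(np.log(50.0), 0.5, size=(E, n)))
    rows, index, cat = [], [], []
    for e in range(E):
        ev = truth.index[e]
        n_inc = int(rng.integers(1, 3))
        n_exc = int(rng.integers(1, 3))
        inc = [f"{ev}_inc{j}" for j in range(n_inc)]
        exc = [f"{ev}_exc{j}" for j in range(n_exc)]
        inc_share = rng.dirichlet(np.ones(n_inc))
        exc_share = rng.dirichlet(np.ones(n_exc))
        for t, share in zip(inc, inc_share):
            rows.append(gene_ab[e] * psi[e] * share)
            index.append(t)
        for t, share in zip(exc, exc_share):
            rows.append(gene_ab[e] * (1.0 - psi[e]) * share)
            index.append(t)
        cat.append({
            "seqname": f"chr{1 + e % 22}",
            "gene_id": f"g_{ev}",
            "event_id": f"{ev};{types[e]}",
            "event_type": types[e],
            "inclusion_transcripts": ",".join(inc),
            "total_transcripts": ",".join(inc + exc),
        })
    ab = np.vstack(rows)
    tpm = ab / ab.sum(axis=0, keepdims=True) * tpm_total
    tpm_df = pd.DataFrame(tpm, index=pd.Index(index, name="transcript_id"),
                          columns=phenotypes.index.copy())
    catalog = pd.DataFrame(cat).set_index("event_id")
    return catalog, tpm_df
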