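import numpy as np
import pandas as pd
import pytest

from dimex.synthetic import (COVARIATE_COLUMNS, CohortSpec,
                             generate_counts, generate_phenotypes,
                             generate_truth)


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic cohort shared across tests (mixed effect classes)."""
    spec = CohortSpec(seed=42, n_subjects=120, n_genes=150, n_isoforms=60,
                      n_events=40, frac_null=0.6, frac_linear=0.2,
                      frac_nonlinear=0.2)
    phenotypes = generate_phenotypes(spec)
    truth = generate_truth(spec, spec.n_genes)
    counts = generate_counts(spec, phenotypes, truth)
    return {
        "spec": spec,
        "phenotypes": phenotypes,
        "truth": truth,
        "counts": counts,
        "covariates": phenotypes.loc[:, list(COVARIATE_COLUMNS)],
    }


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
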