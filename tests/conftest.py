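import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cmsig import (
    ClassifierConfig,
    ExpressionMatrix,
    SimulationConfig,
    simulate_cohort,
    ssgsea_spectra,
    train_classifier,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

warnings.filterwarnings("ignore", category=UserWarning, module="lifelines")


def make_expr(values, gene_ids=None, sample_ids=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    G, n = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(G)]
    sample_ids = sample_ids or [f"s{j}" for j in range(n)]
    return ExpressionMatrix(gene_ids, sample_ids, values)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition synthetic cohort shared across tests."""
    return simulate_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def default_spectra(default_cohort):
    expr, _, sets, _ = default_cohort
    return ssgsea_spectra(expr, sets, alpha=0.25, normalize=True)


@pytest.fixture(scope="session")
def default_classifier(default_cohort, default_spectra):
    _, clinical, _, _ = default_cohort
    return train_classifier(default_spectra, clinical.subtype, ClassifierConfig(seed=11))
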