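import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_cohort():
    """A 400-patient synthetic cohort with marker status set from truth."""
    import markerpipe as mp

    cfg = mp.CohortConfig(n_patients=400, n_genes=5, seed=42)
    expr, truth = mp.generate_expression(cfg)
    cohort = mp.generate_clinical(cfg, truth)
    cohort.data["marker_status"] = np.where(truth, "H+", "H-")
    return cfg, expr, truth, cohort
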