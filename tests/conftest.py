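import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mhcescape.synthetic_cohort import CohortConfig, VAFModel, generate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def null_config(n_patients: int, seed: int) -> CohortConfig:
    """Cohort configuration with every group effect switched off."""
    return CohortConfig(
        n_patients=n_patients,
        seed=seed,
        msi_enrichment_or=1.0,
        burden_multiplier_b2m=1.0,
        burden_multiplier_hla=1.0,
        burden_multiplier_msi=1.0,
        bias_strength=0.0,
        immune_shift=0.0,
        vaf_model=VAFModel(1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 0.5),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 120-patient cohort at the default effect sizes (shared, read-only)."""
    return generate_cohort(CohortConfig(n_patients=120, seed=11))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
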