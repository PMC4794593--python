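import pytest
from hypothesis import HealthCheck, settings

from glycoburden.synthetic_data import SimConfig, generate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def planted_cohort():
    """Cohort with strong planted silencing, load coupling and hazard ratio."""
    cfg = SimConfig(
        cancer_label="PLNT",
        n_tumor=300,
        n_normal=30,
        silenced_fraction=0.5,
        silencing_expression_factor=0.2,
        silenced_beta_shift=0.4,
        load_coupling=0.5,
        hazard_ratio=2.0,
        coexpression={"NEIL3": 0.4, "APOBEC3B": 0.4},
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort with no planted effects at all."""
    cfg = SimConfig(cancer_label="NULL", n_tumor=300, n_normal=30, seed=13)
    return generate_cohort(cfg)
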