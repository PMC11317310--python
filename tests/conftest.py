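import numpy as np
import pytest
from hypothesis import settings

from amiohet import apply_exclusions, default_config, generate_cohort

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def default_cohort_2333():
    """One default synthetic cohort at study scale, with ground truth."""
    raw, truth = generate_cohort(default_config(n_patients=2333, seed=20240722))
    cohort, _ = apply_exclusions(raw)
    return cohort, truth


@pytest.fixture(scope="session")
def null_cohort_1000():
    """Cohort with no treatment effect at all (benefit coefficients zero)."""
    cfg = default_config(n_patients=1000, seed=77, benefit_coefs=np.zeros(11))
    raw, truth = generate_cohort(cfg)
    cohort, _ = apply_exclusions(raw)
    return cohort, truth


@pytest.fixture(scope="session")
def large_cohort_20k():
    """Default-structure cohort at n=20,000 for recovery/balance checks."""
    raw, truth = generate_cohort(default_config(n_patients=20000, seed=4242))
    cohort, _ = apply_exclusions(raw)
    return cohort, truth
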