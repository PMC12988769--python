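import numpy as np
import pytest

from klgrade.experiments import run_domain_shift_study
from klgrade.manifest import CohortManifest
from klgrade.synthetic import SyntheticSpec, generate_roster


@pytest.fixture(scope="session")
def study():
    """One full desk-scale study: train internally, zero-shot, fine-tune.

    Expensive (tens of seconds); shared across every test that needs a
    trained model or its prediction tables.
    """
    return run_domain_shift_study(seed=42)


@pytest.fixture(scope="session")
def oai_like_roster() -> CohortManifest:
    """Bilateral roster with the structure of the internal cohort (4130 patients)."""
    return generate_roster(SyntheticSpec(n_patients=4130, bilateral=True, seed=7))


@pytest.fixture(scope="session")
def external_like_roster() -> CohortManifest:
    """Single-image roster with the structure of the external cohort (2295 patients)."""
    return generate_roster(SyntheticSpec(n_patients=2295, bilateral=False, seed=8))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
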