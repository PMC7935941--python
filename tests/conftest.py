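import numpy as np
import pytest

from raskinetics.mechanism import AssayDesign, KineticParameters
from raskinetics.synthetic import (REFERENCE_TRUTH, NoiseModel,
                                   build_ras_titration_suite, simulate_suite)


@pytest.fixture(scope="session")
def truth_active():
    """Reference truth for the imidazole-dependent protease vs active RAS."""
    return REFERENCE_TRUTH[("I", "active")]


@pytest.fixture(scope="session")
def truth_inactive():
    return REFERENCE_TRUTH[("I", "inactive")]


@pytest.fixture(scope="session")
def active_suite_noiseless(truth_active):
    return build_ras_titration_suite("active", truth_active,
                                     cofactor_id="imidazole",
                                     cofactor_conc=1e-3,
                                     noise=NoiseModel(sigma=0.0, seed=0))


@pytest.fixture(scope="session")
def active_curves_noiseless(active_suite_noiseless):
    return simulate_suite(active_suite_noiseless, noisy=False)


@pytest.fixture
def short_design():
    """A small, quick-to-integrate design for derivative/oracle checks."""
    return AssayDesign(protease_total=100e-9, ras_total=5e-6,
                       reporter_total=1e-6, r1_initial=0.2e-6,
                       time_grid=np.linspace(0.0, 600.0, 61))


@pytest.fixture
def quick_params():
    return KineticParameters(K_S=10e-6, k_2=0.1, K_P=0.5e-6, k_rep=1e4)
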