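import numpy as np
import pytest

import epicohort as ec


@pytest.fixture(scope="session")
def patient():
    """One small synthetic patient shared across tests."""
    return ec.make_virtual_patient("sub-001", n_regions=10, n_shafts=4, seed=0)


@pytest.fixture(scope="session")
def spontaneous_run(patient):
    return ec.run_spontaneous(patient, duration_s=20.0, seed=11)


@pytest.fixture(scope="session")
def interictal_run(patient):
    return ec.run_interictal(patient, duration_s=120.0, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
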