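import numpy as np
import pytest

from cmlpipe.cohort import (
    run_grid_search,
    filter_feedforward,
    reference_patient,
)
from cmlpipe.params import NormalParameterSet


@pytest.fixture(scope="session")
def ref_patient() -> NormalParameterSet:
    ps, _ss = reference_patient()
    return ps


@pytest.fixture(scope="session")
def ref_steady_state() -> np.ndarray:
    _ps, ss = reference_patient()
    return ss


@pytest.fixture(scope="session")
def small_cohort():
    """Small accepted cohort regenerated from a fixed seed (fast)."""
    return run_grid_search(300_000, seed=7)


@pytest.fixture(scope="session")
def ff_cohort(small_cohort):
    return filter_feedforward(small_cohort)


@pytest.fixture
def simple_params() -> NormalParameterSet:
    """Hand-picked parameter set with a comfortable positive equilibrium."""
    return NormalParameterSet(
        p0_max=0.8,
        p1_max=0.3,
        q1_max=0.4,
        eta1_max=0.05,
        eta2_max=3.0,
        d_l=0.02,
        d_m=0.03,
        gamma1=(2 * 0.8 - 1) / 1e5,
        gamma2=1e-6,
        gamma3=1e-6,
        gamma4=1e-7,
        gamma5=1e-4,
    )
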