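import numpy as np
import pytest
from hypothesis import settings

from sdhrev.kinetics import ClampedEnvironment

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from sdhrev.params import build_base_parameters, make_variant, zero_ros_variant


@pytest.fixture(scope="session")
def base_ps():
    return build_base_parameters()


@pytest.fixture(scope="session")
def ros_off_ps(base_ps):
    return zero_ros_variant(base_ps)


@pytest.fixture(scope="session")
def nernst_exact_ros_off_ps(ros_off_ps):
    """ROS-off set with the midpoint-derived Keqs at full precision.

    The printed constants carry up to ~4% rounding (Keq9 = 0.006 vs
    exp(-127/25) = 0.00622), which leaves a small residual circulation
    between the parallel flavin pathways at the zero-current potential;
    the exact set closes every loop and supports strict equilibrium tests.
    """
    from dataclasses import replace

    from sdhrev.params import derive_dependent_keqs, nernst_keq

    exact = {
        1: nernst_keq(60.0, 1),
        2: nernst_keq(-320.0, 1),
        3: nernst_keq(260.0, 1),
        9: nernst_keq(-127.0, 1),
        11: nernst_keq(-31.0, 1),
    }
    return derive_dependent_keqs(
        replace(ros_off_ps, keq={**ros_off_ps.keq, **exact})
    )


@pytest.fixture(scope="session")
def suc_release_variant(base_ps):
    """k14 = k16 = 1e-2 1/s: the strong tunnel-diode configuration."""
    return make_variant(base_ps, {"k14": 1e-2, "k16": 1e-2}, label="suc_off_4")


@pytest.fixture(scope="session")
def slow_fum_binding_variant(base_ps):
    """k10 = k12 = 1e-4 1/(uM s): the high-ROS configuration."""
    return make_variant(base_ps, {"k10": 1e-4, "k12": 1e-4}, label="fum_on_5")


@pytest.fixture
def anaerobic_env():
    return ClampedEnvironment(O2=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
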