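import warnings

import numpy as np
import pytest

from dres.cable import CableSpec
from dres.membrane import MembraneSpec
from dres.workbench import optimized_cable, reference_cable, reference_patch

# the frozen reference membrane legitimately has a second (depolarized)
# root of the steady-state current; the solver warns and takes the
# hyperpolarized one
warnings.filterwarnings("ignore", message=".*roots of the steady-state current.*")


@pytest.fixture(autouse=True)
def _quiet_multiroot_warning():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore",
                                message=".*roots of the steady-state current.*")
        yield


@pytest.fixture(scope="session")
def ref_membrane() -> MembraneSpec:
    return reference_patch()


@pytest.fixture(scope="session")
def ref_cable() -> CableSpec:
    return reference_cable()


@pytest.fixture(scope="session")
def ref_op(ref_cable):
    return ref_cable.operating_point()


@pytest.fixture(scope="session")
def fig3_cable():
    return optimized_cable()


@pytest.fixture(scope="session")
def passive_membrane(ref_membrane) -> MembraneSpec:
    """Same leak budget as the reference patch but no voltage-gated current."""
    return ref_membrane.with_updates(g_l=1.0, klt_gbar=0.0)


@pytest.fixture(scope="session")
def coarse_grid():
    return np.geomspace(1.0, 1500.0, 400)
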