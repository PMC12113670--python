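import numpy as np
import pytest

import bioconvect as bc


@pytest.fixture(scope="session")
def small_grid():
    """Coarse cavity mesh (A=5) used by most operator tests."""
    return bc.make_grid(31, 21, 5.0)


@pytest.fixture(scope="session")
def unit_grid():
    """Square unit-cavity mesh for manufactured-solution tests."""
    return bc.make_grid(33, 33, 1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def quiescent_config(**kw):
    """Zero-forcing configuration: no buoyancy, no thermal sources."""
    params = bc.SimulationParams(Ra=0.0, RaT=0.0, Ran=0.0).replace(
        **kw.pop("params", {})
    )
    defaults = dict(
        params=params,
        grid=bc.make_grid(31, 41, 5.0),
        sources=[],
        max_iters=kw.pop("max_iters", 50),
    )
    defaults.update(kw)
    return bc.CaseConfig(**defaults)
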