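import numpy as np
import pytest

import metaecosim as me


@pytest.fixture(scope="session")
def baseline():
    return me.ModelParams()


@pytest.fixture(scope="session")
def nested():
    return me.nested_topology()


@pytest.fixture(scope="session")
def fully_connected():
    return me.fully_connected_resource_topology()


@pytest.fixture(scope="session")
def closed_eq(baseline):
    return me.closed_ecosystem_equilibrium(baseline)


def constant_trajectory(topo, state_vec, params, t_span=5000.0, n=401):
    """Synthetic trajectory pinned at a constant state (test helper)."""
    t = np.linspace(0.0, t_span, n)
    X = np.tile(np.asarray(state_vec, dtype=float), (n, 1))
    return me.Trajectory(t, X, params, topo, transient_end=0)
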