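import numpy as np
import pytest

import hemobond as hb


@pytest.fixture(scope="session")
def toy():
    """(modules, plan, geometry) of the fixed 5-segment tree."""
    return hb.toy_tree()


@pytest.fixture(scope="session")
def toy_lumped(toy):
    modules, plan, _ = toy
    module, n_merges = hb.lump(plan)
    assert n_merges == len(modules) - 1
    return module


@pytest.fixture(scope="session")
def toy_system(toy_lumped):
    return hb.assemble_ode(toy_lumped)


@pytest.fixture(scope="session")
def toy_run(toy_system):
    """10 s beat-driven run of the composed toy network."""
    return hb.run(toy_system, {"cardiac_output": hb.DEFAULT_BEAT}, t_end=10.0)


def deriv_matrix(sys):
    """Stack of derivative coefficient rows over [1, states..., inputs...]."""
    return np.vstack([sys.deriv_rows[s] for s in sys.states])


def max_rel_rhs_diff(sys_a, sys_b, n_points=100, seed=0):
    """Worst relative disagreement of two systems' right-hand sides over
    random state/input points (systems must share state ordering)."""
    assert sys_a.states == sys_b.states
    assert sys_a.inputs == sys_b.inputs
    A, B = deriv_matrix(sys_a), deriv_matrix(sys_b)
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(A.shape[1], n_points))
    X[0] = 1.0  # constant-term slot
    FA, FB = A @ X, B @ X
    return float(np.max(np.abs(FA - FB)
                        / np.maximum(1.0, np.maximum(np.abs(FA), np.abs(FB)))))
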