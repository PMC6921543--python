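import numpy as np
import pytest

from cytobool.fixtures import load_fixture
from cytobool.fitting import ResampleGrid
from cytobool.network import BooleanNetwork, BoolRule
from cytobool.synthetic import SyntheticDesign, default_kernels, render_panel


@pytest.fixture(scope="session")
def m1():
    return load_fixture("M1")


@pytest.fixture(scope="session")
def m2a():
    return load_fixture("M2a")


@pytest.fixture(scope="session")
def m2c():
    return load_fixture("M2c")


@pytest.fixture(scope="session")
def grid():
    return ResampleGrid.standard()


@pytest.fixture(scope="session")
def ring5():
    """5-node ring with one inversion: every attractor keeps all nodes
    oscillating, so every rule row is exercised by any long trajectory."""
    rules = {
        "N1": BoolRule.from_sop(["N5"], [(("N5", True),)]),
        "N2": BoolRule.from_sop(["N1"], [(("N1", False),)]),
        "N3": BoolRule.from_sop(["N2"], [(("N2", False),)]),
        "N4": BoolRule.from_sop(["N3"], [(("N3", False),)]),
        "N5": BoolRule.from_sop(["N4"], [(("N4", False),)]),
    }
    return BooleanNetwork(rules)


@pytest.fixture(scope="session")
def ring5_panel(ring5, grid):
    """Noise-free dense panel rendered from the ring ground truth."""
    design = SyntheticDesign(
        proteins=ring5.nodes,
        times=tuple(grid.times),
        replicates=4,
        groups=("LPS",),
        noise_sigma=0.0,
        seed=7,
    )
    return render_panel(ring5, default_kernels(ring5.nodes), design)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
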