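import numpy as np
import pytest

from powderavg.sampling import build_scheme
from powderavg.simulate import TissueModel, ground_truth_average, simulate_signal

B_GRID = np.array([1.5, 3.0, 4.5, 6.0, 7.5, 9.0, 10.5, 12.0])

# closed-form orientational averages on the study's b grid (D_par = 1,
# D_perp = 0.14 um^2/ms), rounded as printed in the protocol definition
S_GT_PRINTED = np.array([0.5640, 0.3541, 0.2386, 0.1682,
                         0.1221, 0.0903, 0.0678, 0.0514])


@pytest.fixture(scope="session")
def b_grid():
    return B_GRID.copy()


@pytest.fixture(scope="session")
def gt_values():
    return ground_truth_average(B_GRID)


@pytest.fixture(scope="session")
def scheme61():
    return build_scheme("shelled_uniform", 61, seed=0)


@pytest.fixture(scope="session")
def scheme43():
    return build_scheme("shelled_lebedev", 43)


@pytest.fixture(scope="session")
def scheme19():
    return build_scheme("shelled_lebedev", 19)


@pytest.fixture(scope="session")
def signals61():
    """Noise-free signals on the 61x8 scheme for each dispersion level."""
    sch = build_scheme("shelled_uniform", 61, seed=0)
    return {k: simulate_signal(sch, TissueModel.single(k))
            for k in (1.0, 9.0, np.inf)}


@pytest.fixture(scope="session")
def signals43():
    sch = build_scheme("shelled_lebedev", 43)
    return {k: simulate_signal(sch, TissueModel.single(k))
            for k in (1.0, 9.0, np.inf)}
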