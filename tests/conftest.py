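import numpy as np
import pytest

from quenchbind import GroundTruth, simulate_titration


@pytest.fixture
def static_gt():
    """Noiseless static (dark-complex) ground truth, 1:1 binding."""
    return GroundTruth(ka=2.41e4, n_sites=1.0, tau0=4.8, mechanism="static",
                       noise_rel=0.0, seed=7)


@pytest.fixture
def ligand_grid():
    """12-point titration, 4 uM increments starting at zero."""
    return np.arange(12) * 4e-6


@pytest.fixture
def static_series(static_gt, ligand_grid):
    """Noiseless static titration at 4 uM protein."""
    return simulate_titration(static_gt, 4e-6, ligand_grid)
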