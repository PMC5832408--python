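import numpy as np
import pytest

from isingtcp import BystanderParams, DoseGrid, RegionParams, build_interaction_linearized
from isingtcp.phantoms import homogeneous_phantom

EDGE = 0.1270  # cm


@pytest.fixture
def params():
    """Intermediate/high-risk prostate region: D50 = 72.8 Gy, gamma50 = 5."""
    return RegionParams(d50=72.8, gamma50=5.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def lattice_subset_grid(n: int, doses, edge: float = EDGE) -> DoseGrid:
    """First n voxels (x-major raveling) of a 3x3x3 lattice: contiguous, so the
    minimal spacing equals the voxel edge for any n >= 2."""
    pos = homogeneous_phantom((3, 3, 3), edge, 1.0).positions[:n]
    return DoseGrid(pos, np.asarray(doses, dtype=float), edge)


def random_coupled_instance(rng, params, n=None):
    """Random small instance: doses in 40-110 Gy, random sparse couplings with
    J0 in [0, 4] Gy and lambda in [0, 0.4] cm."""
    if n is None:
        n = int(rng.integers(4, 11))
    grid = lattice_subset_grid(n, rng.uniform(40.0, 110.0, n))
    bp = BystanderParams(j0=float(rng.uniform(0.0, 4.0)), lam=float(rng.uniform(0.0, 0.4)))
    J = build_interaction_linearized(grid, params, bp)
    return grid, J
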