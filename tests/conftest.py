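import numpy as np
import pytest

import phosfold as pf
from phosfold.electrostatics import GridSpec, solve_linear_pb

# Coulomb prefactor in kT/e units at 300 K
C300 = 332.0637 / (1.9872e-3 * 300.0)


def exterior_points(seed: int, n: int = 150, rmin: float = 4.0, rmax: float = 12.0):
    """Deterministic exterior sample points in a radial shell."""
    rng = np.random.default_rng(seed)
    pts = []
    while len(pts) < n:
        p = rng.uniform(-rmax, rmax, 3)
        if rmin <= np.linalg.norm(p) <= rmax:
            pts.append(p)
    return np.array(pts)


@pytest.fixture(scope="session")
def born_ion():
    return pf.make_born_ion(1.0, 2.0)


@pytest.fixture(scope="session")
def grid65():
    return GridSpec(origin=(-16.0, -16.0, -16.0), spacing=0.5, dims=(65, 65, 65))


@pytest.fixture(scope="session")
def born_grid(born_ion, grid65):
    """Born ion, eps 2/80, zero salt on the 65^3 half-Å grid (shared: costly)."""
    return solve_linear_pb(
        born_ion, grid65, eps_in=2.0, eps_out=80.0, ionic_strength=0.0
    )


@pytest.fixture(scope="session")
def homogeneous_grid(born_ion, grid65):
    """Same charge in a uniform eps = 80 medium, zero salt."""
    return solve_linear_pb(
        born_ion, grid65, eps_in=80.0, eps_out=80.0, ionic_strength=0.0
    )
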