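import numpy as np
import pytest

from finwake.pressure import solve_pressure
from finwake.synth import gen_cylinder_potential_flow, gen_lamb_oseen


@pytest.fixture(scope="session")
def cylinder_case():
    """Potential flow past a 16-cell cylinder on a 128x128 grid, solved."""
    series, truth = gen_cylinder_potential_flow(U=0.05, D=0.016, n=128)
    field = solve_pressure(series, 1)
    return series, truth, field


@pytest.fixture(scope="session")
def lamb_oseen_case():
    """Static Lamb-Oseen vortex, domain spanning +-5 core radii, solved."""
    gamma, rc = 1.0e-3, 0.015
    series, truth = gen_lamb_oseen(
        [{"gamma": gamma, "rc": rc, "centre": (0.0, 0.0)}], n=128, extent=0.15)
    field = solve_pressure(series, 1)
    return series, truth, field, gamma, rc


@pytest.fixture
def disk_mask():
    n, dx = 96, 1e-3
    X, Y = np.meshgrid(np.arange(n) * dx, np.arange(n) * dx)
    c = n // 2 * dx
    r = 10 * dx
    return np.hypot(X - c, Y - c) < r, dx, c, r
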