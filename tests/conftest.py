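"""Shared fixtures and independent numerical oracles.

The oracles here deliberately avoid the package's own solution paths: the
boundary-value oracle uses scipy's collocation solver on the raw Pontryagin
ODEs, and the forward-integration oracle replays a returned control signal
with a classical RK4 stepper.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import solve_bvp

from richclub_control import Connectome


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_connectome(
    rng: np.random.Generator, n: int = 12, density: float = 0.4,
    ensure_connected: bool = True,
) -> Connectome:
    """A random symmetric weighted graph for property tests."""
    for _ in range(50):
        w = (rng.random((n, n)) < density) * rng.uniform(0.1, 1.0, (n, n))
        w = np.triu(w, 1)
        w = w + w.T
        c = Connectome(w)
        if not ensure_connected or c.is_connected():
            return c
    raise RuntimeError("failed to draw a connected random graph")


def scalar_maintenance_energy_bvp(
    s: float, x0: float, xt: float, T: float = 1.0, rho: float = 1.0,
    n_grid: int = 2001,
) -> float:
    """Collocation solution of the 1-node optimal control problem.

    Solves x' = s x - p/(2 rho), p' = 2(xt - x) - s p with x(0)=x0, x(T)=xt
    and returns the normalized energy integral of u = -p/(2 rho).
    """

    def rhs(t, y):
        return np.vstack(
            [s * y[0] - y[1] / (2 * rho), 2 * (xt - y[0]) - s * y[1]]
        )

    def bc(ya, yb):
        return np.array([ya[0] - x0, yb[0] - xt])

    t = np.linspace(0, T, 101)
    sol = solve_bvp(rhs, bc, t, np.zeros((2, len(t))), tol=1e-10, max_nodes=20000)
    assert sol.success
    tt = np.linspace(0, T, n_grid)
    u = -sol.sol(tt)[1] / (2 * rho)
    return float(np.trapezoid(u**2, tt) / (T / 1e-3))


def rk4_replay_endpoint_error(S, t_grid, u_traj, x0, xt) -> float:
    """Forward RK4 integration of dx/dt = S x + u(t) using the returned
    control, with linear interpolation of u between grid points."""
    x = np.array(x0, dtype=float)
    for k in range(len(t_grid) - 1):
        dt = t_grid[k + 1] - t_grid[k]
        u0, u1 = u_traj[k], u_traj[k + 1]
        um = (u0 + u1) / 2.0

        k1 = S @ x + u0
        k2 = S @ (x + dt / 2 * k1) + um
        k3 = S @ (x + dt / 2 * k2) + um
        k4 = S @ (x + dt * k3) + u1
        x = x + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    return float(np.linalg.norm(x - xt) / max(np.linalg.norm(xt), 1.0))
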