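"""Stabilized linear dynamics and the optimal-control energy solver.

The model treats regional activity x(t) as a linear dynamical system on the
weighted structural connectome,

    dx/dt = S x + B u,

where ``S = A / (1 + lambda_max(A)) - I`` is the stabilized (Hurwitz) system
matrix derived from the connectivity matrix A, and B selects the control set:
the regions permitted to inject input u. The optimal transition from x0 to a
target xT over horizon T minimizes

    J = \\int_0^T (xT - x)'(xT - x) + rho * u'u  dt

with both endpoints fixed. The Pontryagin conditions give a linear two-point
boundary-value problem in state and costate,

    d/dt [x; p] = [[S, -B B'/(2 rho)], [-2 I, -S']] [x; p] + [0; 2 xT],

solved here in closed form through the matrix exponential of the augmented
Hamiltonian block matrix and a single linear solve for the initial costate.

Per-node control energy is the time integral of u_i(t)^2, normalized by the
number of reference timesteps the horizon comprises (T / dt_ref with
dt_ref = 1e-3) so that energies are comparable across settings of T and
insensitive to grid refinement. *Stability* of a state is the inverse of the
energy needed to hold it (x0 = xT).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh, expm

from .graph_metrics import Connectome

__all__ = [
    "StabilizedSystem",
    "BrainState",
    "ControlSet",
    "ControlProblem",
    "ControlSolution",
    "UncontrollableSetError",
    "stabilize",
    "solve_optimal_control",
    "transition_energy",
    "state_stability",
    "regional_lesion_scan",
    "excluded_set_metrics",
]

#: reference timestep defining the energy normalization (timesteps per unit T)
DT_REF = 1e-3

STABILITY_INF = float("inf")


class UncontrollableSetError(RuntimeError):
    """The chosen control set leaves the boundary-value solve ill-conditioned."""


@dataclass
class StabilizedSystem:
    """Hurwitz-stable system matrix derived from a connectome."""

    S: np.ndarray
    lambda_max: float

    @property
    def n_nodes(self) -> int:
        return self.S.shape[0]


@dataclass
class BrainState:
    """Activation vector over regions (task-contrast beta-like units)."""

    x: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float).ravel()
        if not np.all(np.isfinite(self.x)):
            raise ValueError("brain state contains non-finite values")


@dataclass
class ControlSet:
    """Boolean mask of regions permitted to exert control."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool).ravel()
        if not self.mask.any():
            raise ValueError("control set must contain at least one node")

    @classmethod
    def full(cls, n: int) -> "ControlSet":
        return cls(np.ones(n, dtype=bool))

    @classmethod
    def excluding(cls, n: int, excluded) -> "ControlSet":
        mask = np.ones(n, dtype=bool)
        mask[np.asarray(list(excluded), dtype=int)] = False
        if not mask.any():
            raise ValueError("cannot exclude every node from the control set")
        return cls(mask)


@dataclass
class ControlProblem:
    x0: BrainState
    xT: BrainState
    control_set: ControlSet
    T: float = 1.0
    rho: float = 1.0
    n_steps: int = 1000

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("time horizon T must be positive")
        if self.rho <= 0:
            raise ValueError("penalization rho must be positive")
        if self.n_steps < 10:
            raise ValueError("n_steps must be at least 10")


@dataclass
class ControlSolution:
    t_grid: np.ndarray
    x_traj: np.ndarray  # (n_steps+1, N)
    u_traj: np.ndarray  # (n_steps+1, N), zero rows for non-control nodes
    nodal_energy: np.ndarray  # (N,)
    mean_energy: float
    endpoint_error: float


def stabilize(c: Connectome) -> StabilizedSystem:
    """Build ``S = A/(1 + lambda_max(A)) - I`` from the connectome weights.

    Dividing by one plus the spectral radius and subtracting the identity
    shifts every eigenvalue strictly below zero, so activity decays to the
    origin in the absence of input.
    """
    a = c.weights
    lam = float(eigh(a, eigvals_only=True, subset_by_index=(a.shape[0] - 1,) * 2)[0])
    s = a / (1.0 + lam) - np.eye(a.shape[0])
    # Hurwitz by construction: eig(S) = eig(A)/(1+lam) - 1 <= lam/(1+lam) - 1 < 0
    return StabilizedSystem(S=s, lambda_max=lam)


def _hamiltonian_blocks(
    sys: StabilizedSystem, prob: ControlProblem
) -> tuple[np.ndarray, np.ndarray]:
    n = sys.n_nodes
    mask = prob.control_set.mask
    if mask.shape[0] != n:
        raise ValueError("control mask length does not match system size")
    bbt = np.diag(mask.astype(float))  # B B' for a node-selection matrix B
    m = np.block(
        [[sys.S, -bbt / (2.0 * prob.rho)], [-2.0 * np.eye(n), -sys.S.T]]
    )
    forcing = np.concatenate([np.zeros(n), 2.0 * prob.xT.x])
    return m, forcing


def solve_optimal_control(
    sys: StabilizedSystem,
    prob: ControlProblem,
    endpoint_tol: float = 1e-4,
    rcond_min: float = 1e-12,
) -> ControlSolution:
    """Solve the fixed-endpoint optimal control problem in closed form.

    Raises
    ------
    UncontrollableSetError
        If the linear solve for the initial costate has reciprocal condition
        below ``rcond_min`` — the control set cannot steer the system — or if
        the achieved endpoint misses the target by more than ``endpoint_tol``
        (relative).
    """
    n = sys.n_nodes
    x0, xt = prob.x0.x, prob.xT.x
    if x0.shape[0] != n or xt.shape[0] != n:
        raise ValueError("state length does not match system size")
    m, forcing = _hamiltonian_blocks(sys, prob)

    # Augmented (2N+1) matrix folds the constant forcing into the exponential.
    aug = np.zeros((2 * n + 1, 2 * n + 1))
    aug[: 2 * n, : 2 * n] = m
    aug[: 2 * n, -1] = forcing

    e_t = expm(aug * prob.T)
    phi11 = e_t[:n, :n]
    phi12 = e_t[:n, n : 2 * n]
    d_x = e_t[:n, -1]

    rhs = xt - phi11 @ x0 - d_x
    sv = np.linalg.svd(phi12, compute_uv=False)
    rcond = sv[-1] / sv[0] if sv[0] > 0 else 0.0
    if rcond >= rcond_min:
        p0 = np.linalg.solve(phi12, rhs)
    else:
        # Singular map from initial costate to endpoint: the set cannot steer
        # every direction. If the required endpoint lies in the reachable
        # subspace (e.g. an uncontrolled coordinate already at equilibrium),
        # the minimum-norm solution still solves the problem; the endpoint
        # check below is the arbiter.
        p0 = np.linalg.lstsq(phi12, rhs, rcond=None)[0]
        resid = np.linalg.norm(phi12 @ p0 - rhs)
        if resid / max(np.linalg.norm(xt), 1.0) > endpoint_tol:
            raise UncontrollableSetError(
                f"control set of size {int(prob.control_set.mask.sum())} is "
                f"uncontrollable/ill-conditioned (rcond={rcond:.2e})"
            )

    # Exact propagation on the grid by iterating the one-step exponential.
    dt = prob.T / prob.n_steps
    e_dt = expm(aug * dt)
    z = np.empty((prob.n_steps + 1, 2 * n + 1))
    z[0] = np.concatenate([x0, p0, [1.0]])
    for k in range(prob.n_steps):
        z[k + 1] = e_dt @ z[k]
    t_grid = np.linspace(0.0, prob.T, prob.n_steps + 1)
    x_traj = z[:, :n]
    p_traj = z[:, n : 2 * n]
    mask = prob.control_set.mask
    u_traj = np.zeros_like(x_traj)
    u_traj[:, mask] = -p_traj[:, mask] / (2.0 * prob.rho)

    n_ref_steps = prob.T / DT_REF
    nodal_energy = np.trapezoid(u_traj**2, t_grid, axis=0) / n_ref_steps
    nodal_energy[~mask] = 0.0

    endpoint_error = float(
        np.linalg.norm(x_traj[-1] - xt) / max(np.linalg.norm(xt), 1.0)
    )
    if endpoint_error > endpoint_tol:
        raise UncontrollableSetError(
            f"endpoint error {endpoint_error:.2e} exceeds tolerance "
            f"{endpoint_tol:.2e} (control set size "
            f"{int(mask.sum())})"
        )
    return ControlSolution(
        t_grid=t_grid,
        x_traj=x_traj,
        u_traj=u_traj,
        nodal_energy=nodal_energy,
        mean_energy=float(nodal_energy.mean()),
        endpoint_error=endpoint_error,
    )


def transition_energy(
    sys: StabilizedSystem,
    x0: BrainState,
    xT: BrainState,
    control_set: ControlSet | None = None,
    T: float = 1.0,
    rho: float = 1.0,
    n_steps: int = 1000,
) -> float:
    """Mean optimal control energy for steering x0 to xT.

    The mean runs over all N regions, including non-controllers whose
    contribution is zero.
    """
    if control_set is None:
        control_set = ControlSet.full(sys.n_nodes)
    prob = ControlProblem(x0, xT, control_set, T=T, rho=rho, n_steps=n_steps)
    return solve_optimal_control(sys, prob).mean_energy


def state_stability(
    sys: StabilizedSystem,
    x: BrainState,
    control_set: ControlSet | None = None,
    T: float = 1.0,
    rho: float = 1.0,
    n_steps: int = 1000,
) -> float:
    """Inverse of the energy needed to hold state ``x`` over the horizon.

    A zero state (or a maintenance energy below 1e-12) sits at the stable
    equilibrium and needs no input; the documented sentinel ``inf`` is
    returned in that case.
    """
    if np.allclose(x.x, 0.0):
        return STABILITY_INF
    e = transition_energy(sys, x, x, control_set, T=T, rho=rho, n_steps=n_steps)
    if e < 1e-12:
        return STABILITY_INF
    return 1.0 / e


def regional_lesion_scan(
    sys: StabilizedSystem,
    x0: BrainState,
    xT: BrainState,
    T: float = 1.0,
    rho: float = 1.0,
    n_steps: int = 1000,
    stability_state: BrainState | None = None,
) -> dict[str, np.ndarray | float]:
    """Remove one region at a time from the control set.

    For each region r, ``energy_delta[r]`` is the extra transition energy when
    r may not control, and ``stability_delta[r]`` the change in stability of
    ``stability_state`` (default: the initial state x0). Regions whose removal
    leaves the solve ill-conditioned are recorded as NaN with a warning.
    """
    n = sys.n_nodes
    if n < 2:
        raise ValueError("lesion scan needs at least 2 regions")
    if stability_state is None:
        stability_state = x0
    full = ControlSet.full(n)
    e_full = transition_energy(sys, x0, xT, full, T=T, rho=rho, n_steps=n_steps)
    s_full = state_stability(
        sys, stability_state, full, T=T, rho=rho, n_steps=n_steps
    )
    e_delta = np.full(n, np.nan)
    s_delta = np.full(n, np.nan)
    for r in range(n):
        cs = ControlSet.excluding(n, [r])
        try:
            e_delta[r] = (
                transition_energy(sys, x0, xT, cs, T=T, rho=rho, n_steps=n_steps)
                - e_full
            )
            s_delta[r] = (
                state_stability(
                    sys, stability_state, cs, T=T, rho=rho, n_steps=n_steps
                )
                - s_full
            )
        except UncontrollableSetError:
            warnings.warn(
                f"lesion of region {r} left the control problem "
                "ill-conditioned; recorded as missing",
                stacklevel=2,
            )
    return {
        "energy_delta": e_delta,
        "stability_delta": s_delta,
        "energy_full": e_full,
        "stability_full": s_full,
    }


def excluded_set_metrics(
    sys: StabilizedSystem,
    x0: BrainState,
    xT: BrainState,
    excluded,
    T: float = 1.0,
    rho: float = 1.0,
    n_steps: int = 1000,
) -> tuple[float, float]:
    """Energy and stability when a node set may not exert control.

    The excluded nodes stay in the dynamics — they can still be driven by the
    remaining controllers — but receive no input channel. Returns
    ``(transition energy x0 -> xT, stability of x0)``.
    """
    excluded = _as_index_set(excluded)
    n = sys.n_nodes
    if len(excluded) >= n:
        raise ValueError("cannot exclude all nodes from the control set")
    cs = ControlSet.excluding(n, excluded)
    e = transition_energy(sys, x0, xT, cs, T=T, rho=rho, n_steps=n_steps)
    s = state_stability(sys, x0, cs, T=T, rho=rho, n_steps=n_steps)
    return e, s


def _as_index_set(excluded) -> list[int]:
    if hasattr(excluded, "member_flags"):  # RichClubAssignment
        return list(np.flatnonzero(excluded.member_flags))
    arr = np.asarray(list(excluded))
    if arr.dtype == bool:
        return list(np.flatnonzero(arr))
    return [int(i) for i in arr]
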