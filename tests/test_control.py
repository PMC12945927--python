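"""Optimal-control solver: closed forms, independent oracles, monotonicity."""

import numpy as np
import pytest

from richclub_control import (
    BrainState,
    Connectome,
    ControlProblem,
    ControlSet,
    UncontrollableSetError,
    excluded_set_metrics,
    regional_lesion_scan,
    solve_optimal_control,
    stabilize,
    state_stability,
    transition_energy,
)
from conftest import (
    random_connectome,
    rk4_replay_endpoint_error,
    scalar_maintenance_energy_bvp,
)


@pytest.fixture
def small_system(rng):
    c = random_connectome(rng, n=10)
    return stabilize(c)


class TestStabilize:
    def test_empty_graph_gives_minus_identity(self):
        s = stabilize(Connectome(np.zeros((4, 4))))
        np.testing.assert_allclose(s.S, -np.eye(4))

    def test_two_node_hand_eigenvalues(self):
        w = np.array([[0.0, 1.0], [1.0, 0.0]])
        s = stabilize(Connectome(w))
        assert s.lambda_max == pytest.approx(1.0)
        np.testing.assert_allclose(s.S, w / 2.0 - np.eye(2))
        ev = np.sort(np.linalg.eigvalsh(s.S))
        np.testing.assert_allclose(ev, [-1.5, -0.5], atol=1e-12)

    def test_hurwitz_on_random_connectomes(self, rng):
        for _ in range(50):
            c = random_connectome(rng, n=8, ensure_connected=False)
            s = stabilize(c)
            assert np.max(np.linalg.eigvalsh(s.S)) < 0


class TestSolver:
    def test_zero_states_zero_energy(self, small_system):
        prob = ControlProblem(
            BrainState(np.zeros(10)), BrainState(np.zeros(10)),
            ControlSet.full(10), n_steps=200,
        )
        sol = solve_optimal_control(small_system, prob)
        assert sol.mean_energy == pytest.approx(0.0, abs=1e-20)
        np.testing.assert_allclose(sol.u_traj, 0.0, atol=1e-12)

    def test_scalar_bvp_oracle(self):
        """1-node closed case vs an independent collocation solution."""
        c = Connectome(np.zeros((1, 1)))
        sys = stabilize(c)  # S = [[-1]]
        prob = ControlProblem(
            BrainState([1.0]), BrainState([0.0]), ControlSet.full(1)
        )
        sol = solve_optimal_control(sys, prob)
        oracle = scalar_maintenance_energy_bvp(-1.0, 1.0, 0.0)
        assert sol.mean_energy == pytest.approx(oracle, rel=1e-6)

    def test_forward_rk4_replay(self, rng):
        """Returned control steered through an RK4 stepper hits the target."""
        checked = 0
        while checked < 10:
            c = random_connectome(rng, n=10)
            sys = stabilize(c)
            x0 = BrainState(rng.normal(size=10))
            xt = BrainState(rng.normal(size=10))
            mask = rng.random(10) < 0.8
            mask[:6] = True
            sol = solve_optimal_control(
                sys, ControlProblem(x0, xt, ControlSet(mask), n_steps=1000)
            )
            if np.abs(sol.u_traj).max() > 200:
                continue  # near-singular draw
            err = rk4_replay_endpoint_error(
                sys.S, sol.t_grid, sol.u_traj, x0.x, xt.x
            )
            assert err < 1e-3
            checked += 1

    def test_nodal_energy_zero_pattern(self, small_system, rng):
        mask = np.zeros(10, dtype=bool)
        mask[[1, 4, 7]] = True
        sol = solve_optimal_control(
            small_system,
            ControlProblem(
                BrainState(rng.normal(size=10)), BrainState(rng.normal(size=10)),
                ControlSet(mask), n_steps=300,
            ),
        )
        assert np.all(sol.nodal_energy >= 0)
        np.testing.assert_array_equal(sol.nodal_energy[~mask], 0.0)
        assert sol.mean_energy == pytest.approx(sol.nodal_energy.mean())

    def test_grid_refinement_consistency(self, small_system, rng):
        """Normalized energy is a property of the horizon, not of the grid."""
        x0 = BrainState(rng.normal(size=10))
        xt = BrainState(rng.normal(size=10))
        e1 = transition_energy(small_system, x0, xt, n_steps=400)
        e2 = transition_energy(small_system, x0, xt, n_steps=800)
        assert e2 == pytest.approx(e1, rel=0.01)

    def test_uncontrollable_single_node_set(self, rng):
        # one controller on a 14-node graph cannot steer every direction
        c = random_connectome(rng, n=14)
        sys = stabilize(c)
        mask = np.zeros(14, dtype=bool)
        mask[0] = True
        with pytest.raises(UncontrollableSetError):
            solve_optimal_control(
                sys,
                ControlProblem(
                    BrainState(rng.normal(size=14)),
                    BrainState(rng.normal(size=14)),
                    ControlSet(mask), n_steps=200,
                ),
            )


class TestEnergyStability:
    def test_transition_energy_is_solution_mean(self, small_system, rng):
        x0 = BrainState(rng.normal(size=10))
        xt = BrainState(rng.normal(size=10))
        sol = solve_optimal_control(
            small_system, ControlProblem(x0, xt, ControlSet.full(10))
        )
        assert transition_energy(small_system, x0, xt) == pytest.approx(
            sol.mean_energy
        )

    def test_control_set_monotonicity(self, rng):
        """Restricting the control set never lowers the optimal energy."""
        for _ in range(20):
            c = random_connectome(rng, n=10)
            sys = stabilize(c)
            x0 = BrainState(rng.normal(size=10))
            xt = BrainState(rng.normal(size=10))
            mask = rng.random(10) < 0.6
            mask[:2] = True
            e_full = transition_energy(sys, x0, xt, n_steps=300)
            e_restr = transition_energy(
                sys, x0, xt, ControlSet(mask), n_steps=300
            )
            assert e_full <= e_restr + 1e-9

    def test_stability_sentinel_for_zero_state(self, small_system):
        assert state_stability(small_system, BrainState(np.zeros(10))) == np.inf

    def test_stability_decreases_with_state_scale(self, small_system, rng):
        for _ in range(20):
            x = rng.normal(size=10)
            s1 = state_stability(small_system, BrainState(x), n_steps=300)
            s2 = state_stability(small_system, BrainState(2 * x), n_steps=300)
            assert s2 < s1

    def test_stability_control_set_monotonicity(self, small_system, rng):
        x = BrainState(rng.normal(size=10))
        mask = np.ones(10, dtype=bool)
        mask[[2, 5]] = False
        s_full = state_stability(small_system, x, n_steps=300)
        s_restr = state_stability(
            small_system, x, ControlSet(mask), n_steps=300
        )
        assert s_full >= s_restr - 1e-9


class TestLesionScan:
    def test_deltas_nonnegative_and_isolated_node(self, rng):
        # network with an isolated node whose state entries are zero
        w = np.zeros((6, 6))
        sub = random_connectome(rng, n=5).weights
        w[:5, :5] = sub
        c = Connectome(w)
        sys = stabilize(c)
        x0 = np.append(rng.normal(size=5), 0.0)
        xt = np.append(rng.normal(size=5), 0.0)
        scan = regional_lesion_scan(
            sys, BrainState(x0), BrainState(xt), n_steps=300
        )
        assert np.all(scan["energy_delta"] >= -1e-9)
        # the isolated region holds no activation: removing its input channel
        # changes nothing
        assert scan["energy_delta"][5] == pytest.approx(0.0, abs=1e-9)

    def test_permutation_equivariance(self, rng):
        c = random_connectome(rng, n=7)
        x0 = rng.normal(size=7)
        xt = rng.normal(size=7)
        scan = regional_lesion_scan(
            stabilize(c), BrainState(x0), BrainState(xt), n_steps=300
        )
        perm = rng.permutation(7)
        c2 = Connectome(c.weights[np.ix_(perm, perm)])
        scan2 = regional_lesion_scan(
            stabilize(c2), BrainState(x0[perm]), BrainState(xt[perm]),
            n_steps=300,
        )
        np.testing.assert_allclose(
            scan2["energy_delta"], scan["energy_delta"][perm],
            rtol=1e-6, atol=1e-12,
        )


class TestExcludedSet:
    def test_empty_exclusion_equals_full(self, small_system, rng):
        x0 = BrainState(rng.normal(size=10))
        xt = BrainState(rng.normal(size=10))
        e, s = excluded_set_metrics(small_system, x0, xt, [])
        assert e == pytest.approx(transition_energy(small_system, x0, xt))
        assert s == pytest.approx(state_stability(small_system, x0))

    def test_exclusion_monotonicity_and_determinism(self, small_system, rng):
        x0 = BrainState(rng.normal(size=10))
        xt = BrainState(rng.normal(size=10))
        e_full = transition_energy(small_system, x0, xt, n_steps=300)
        e1, _ = excluded_set_metrics(
            small_system, x0, xt, [0, 3], n_steps=300
        )
        e2, s2 = excluded_set_metrics(
            small_system, x0, xt, [0, 3], n_steps=300
        )
        assert e1 >= e_full - 1e-9
        assert (e1, s2) == (e2, s2)  # no randomness anywhere in the solver

    def test_cannot_exclude_everything(self, small_system, rng):
        x = BrainState(rng.normal(size=10))
        with pytest.raises(ValueError, match="all nodes"):
            excluded_set_metrics(small_system, x, x, list(range(10)))
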