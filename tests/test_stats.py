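"""Inferential layer: oracles, calibration, rank machinery, spin inference."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from richclub_control import (
    PairedDesign,
    RegionalMap,
    activation_covariate,
    generate_coordinates,
    map_rank_correlation,
    network_mean_ranks,
    paired_effect_size,
    paired_t_one_tailed,
    rank_regions,
    rm_anova_covariate,
    set_mean_rank_test,
    spin_rotations,
)
from richclub_control.stats import RegionalRankTable


class TestActivationCovariate:
    def test_trivial_values(self):
        assert activation_covariate(np.zeros(4), np.zeros(4)) == 0.0
        assert activation_covariate(np.zeros(5), np.ones(5)) == 1.0

    def test_antisymmetry(self, rng):
        a, b = rng.normal(size=6), rng.normal(size=6)
        assert activation_covariate(a, b) == -activation_covariate(b, a)


class TestRmAnova:
    def test_equal_conditions(self, rng):
        a = rng.normal(size=10)
        res = rm_anova_covariate(PairedDesign(a, a.copy(), rng.normal(size=10)))
        assert res.F == 0.0 and res.p == 1.0 and res.direction == 0

    def test_manual_least_squares_oracle(self, rng):
        """F and p must match an explicit normal-equations computation."""
        a = rng.normal(size=15) + 0.5
        b = rng.normal(size=15)
        cv = rng.normal(size=15)
        res = rm_anova_covariate(PairedDesign(a, b, cv))
        d = a - b
        x = np.column_stack([np.ones(15), cv - cv.mean()])
        beta = np.linalg.solve(x.T @ x, x.T @ d)
        resid = d - x @ beta
        s2 = resid @ resid / 13
        se0 = np.sqrt(s2 * np.linalg.inv(x.T @ x)[0, 0])
        f_manual = (beta[0] / se0) ** 2
        p_manual = sps.f.sf(f_manual, 1, 13)
        assert res.F == pytest.approx(f_manual, rel=1e-10)
        assert res.p == pytest.approx(p_manual, rel=1e-10)

    def test_power_at_unit_effect(self):
        g = np.random.default_rng(10)
        rejections = 0
        for _ in range(200):
            subj = g.normal(size=50)
            a = subj + 1.0 + g.normal(size=50)
            b = subj + g.normal(size=50)
            rejections += rm_anova_covariate(
                PairedDesign(a, b, g.normal(size=50))
            ).p < 0.05
        assert rejections / 200 > 0.9

    def test_zero_variance_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            rm_anova_covariate(
                PairedDesign([1.0] * 5, [2.0] * 5, [0.0] * 5)
            )


class TestPairedT:
    def test_constant_shift_with_tiny_noise(self, rng):
        b = rng.normal(size=10)
        a = b + 1.0 + rng.normal(scale=1e-6, size=10)
        t, p = paired_t_one_tailed(a, b, "greater")
        assert p < 1e-10

    def test_direction_complement(self, rng):
        a, b = rng.normal(size=12), rng.normal(size=12)
        _, p_g = paired_t_one_tailed(a, b, "greater")
        _, p_l = paired_t_one_tailed(a, b, "less")
        assert p_g + p_l == pytest.approx(1.0)

    def test_textbook_fixture_independent_oracle(self):
        a = np.array([12.0, 14.5, 11.2, 13.3, 15.0, 12.8])
        b = np.array([11.0, 13.9, 11.5, 12.1, 14.2, 12.0])
        t, p = paired_t_one_tailed(a, b, "greater")
        d = a - b
        t_manual = d.mean() / (d.std(ddof=1) / np.sqrt(6))
        p_manual = sps.t.sf(t_manual, 5)
        assert t == pytest.approx(t_manual, abs=1e-10)
        assert p == pytest.approx(p_manual, abs=1e-10)

    def test_zero_variance_error(self):
        with pytest.raises(ValueError, match="zero-variance"):
            paired_t_one_tailed([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])


class TestRankRegions:
    def _table_from_deltas(self, e_delta, s_delta):
        return rank_regions(
            {"t0": {"energy_delta": e_delta, "stability_delta": s_delta}}
        )

    def test_strictly_ordered_deltas(self):
        e = np.array([0.1, 0.4, 0.2, 0.3])
        s = np.array([-0.1, -0.4, -0.2, -0.3])  # stability drops mirror
        table = self._table_from_deltas(e, s)
        energy_ranks = (
            table.ranks.query("measure == 'energy'")
            .sort_values("node")["rank"].to_numpy()
        )
        np.testing.assert_array_equal(energy_ranks, [4, 1, 3, 2])
        assert np.all((table.mean_rank >= 1) & (table.mean_rank <= 4))

    def test_permutation_equivariance(self, rng):
        e = rng.normal(size=6)
        s = rng.normal(size=6)
        t1 = self._table_from_deltas(e, s)
        perm = rng.permutation(6)
        t2 = self._table_from_deltas(e[perm], s[perm])
        np.testing.assert_array_equal(t2.mean_rank, t1.mean_rank[perm])

    def test_missing_regions_ranked_last(self):
        e = np.array([0.3, np.nan, 0.1])
        s = np.array([-0.3, np.nan, -0.1])
        with pytest.warns(UserWarning, match="missing"):
            table = self._table_from_deltas(e, s)
        assert table.mean_rank[1] == 3.0


def _toy_table(mean_rank):
    mean_rank = np.asarray(mean_rank, dtype=float)
    df = pd.DataFrame(
        {"node": range(len(mean_rank)), "task": "t0", "measure": "energy",
         "rank": mean_rank}
    )
    return RegionalRankTable(ranks=df, mean_rank=mean_rank,
                             n_nodes=len(mean_rank))


@pytest.fixture
def sphere_ens():
    coords, hemi = generate_coordinates(60, seed=12)
    return coords, hemi, spin_rotations(coords, hemi, 200, seed=12)


class TestSetMeanRank:
    def test_full_set_is_rotation_invariant(self, sphere_ens):
        _, _, ens = sphere_ens
        table = _toy_table(np.arange(1, 61))
        emp, p = set_mean_rank_test(table, np.arange(60), ens)
        assert emp == pytest.approx(np.mean(np.arange(1, 61)))
        assert p == 1.0

    def test_identity_only_ensemble(self, sphere_ens):
        coords, hemi, _ = sphere_ens
        ident = spin_rotations(coords, hemi, 1, seed=0, _identity=True)
        table = _toy_table(np.arange(1, 61))
        _, p = set_mean_rank_test(table, [55, 56, 57], ident)
        assert p in (0.0, 1.0)

    def test_planted_high_rank_set_detected(self, sphere_ens):
        """Ranks constructed to disfavor a set are flagged by the spin test."""
        _, _, ens = sphere_ens
        g = np.random.default_rng(1)
        mean_rank = g.permutation(np.arange(1.0, 61.0))
        target = np.argsort(mean_rank)[-6:]  # the six worst-ranked nodes
        table = _toy_table(mean_rank)
        emp, p = set_mean_rank_test(table, target, ens, alternative="greater")
        assert p < 0.05


class TestMapRankCorrelation:
    def test_self_and_negated_map(self, sphere_ens):
        _, _, ens = sphere_ens
        g = np.random.default_rng(2)
        mean_rank = g.permutation(np.arange(1.0, 61.0))
        table = _toy_table(mean_rank)
        r, _ = map_rank_correlation(table, RegionalMap(mean_rank), ens)
        assert r == pytest.approx(1.0)
        r2, _ = map_rank_correlation(table, RegionalMap(-mean_rank), ens)
        assert r2 == pytest.approx(-1.0)

    def test_zero_variance_map_error(self, sphere_ens):
        _, _, ens = sphere_ens
        table = _toy_table(np.arange(1.0, 61.0))
        with pytest.raises(ValueError, match="zero-variance"):
            map_rank_correlation(table, RegionalMap(np.ones(60)), ens)

    def test_planted_alignment_significant(self, sphere_ens):
        """A map tightly aligned with the ranks survives spin correction."""
        _, _, ens = sphere_ens
        g = np.random.default_rng(3)
        mean_rank = g.permutation(np.arange(1.0, 61.0))
        table = _toy_table(mean_rank)
        noisy_map = mean_rank + g.normal(scale=5.0, size=60)
        r, p = map_rank_correlation(table, RegionalMap(noisy_map), ens)
        assert r > 0.5
        assert p < 0.05


class TestNetworkMeanRanks:
    def test_single_network_grand_mean(self, sphere_ens):
        _, _, ens = sphere_ens
        table = _toy_table(np.arange(1.0, 61.0))
        out = network_mean_ranks(table, np.ones(60, dtype=int), ens)
        assert len(out) == 1
        assert out.loc[0, "mean_rank"] == pytest.approx(30.5)

    def test_planted_low_rank_network(self, sphere_ens):
        _, _, ens = sphere_ens
        g = np.random.default_rng(4)
        mean_rank = g.permutation(np.arange(1.0, 61.0))
        labels = np.ones(60, dtype=int)
        best = np.argsort(mean_rank)[:6]
        labels[best] = 2  # network 2 = the six most impactful regions
        table = _toy_table(mean_rank)
        out = network_mean_ranks(table, labels, ens).set_index("network")
        assert out.loc[2, "p_low"] < 0.05


class TestEffectSize:
    def test_constant_shift_sentinel(self):
        assert paired_effect_size([2.0, 3.0, 4.0], [1.0, 2.0, 3.0]) == np.inf

    def test_antisymmetry(self, rng):
        a, b = rng.normal(size=20), rng.normal(size=20)
        assert paired_effect_size(a, b) == pytest.approx(
            -paired_effect_size(b, a)
        )

    def test_unit_effect_simulation(self):
        g = np.random.default_rng(5)
        diff = g.normal(loc=1.0, scale=1.0, size=10_000)
        d = paired_effect_size(diff, np.zeros(10_000))
        assert d == pytest.approx(1.0, abs=0.05)
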