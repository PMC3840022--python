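"""Engine dynamics: determinism, diffusion, crowding, reactions, clamps."""

import numpy as np
import pytest

from npcabm.engine import (
    Clamp,
    EngineConfig,
    Lattice,
    PairRule,
    Simulation,
    Species,
)

DT = 2.5e-6


def make_walkers(n=2000, p=0.9, vol=0.0, shape=(32, 32, 32), seed=0):
    sim = Simulation(
        Lattice.box(shape, periodic=True),
        [Species("w", p_move=p, volume_nm3=vol)],
        config=EngineConfig(dt_s=DT),
        capacity=n + 64,
    )
    sim.add_agents("w", n=n, rng=seed)
    return sim


class TestDeterminism:
    def test_same_seed_identical_trajectory(self):
        runs = []
        for _ in range(2):
            sim = make_walkers(n=300, seed=5)
            sim.run(400, seed=42)
            runs.append(sim.positions("w"))
        assert np.array_equal(runs[0], runs[1])

    def test_different_seeds_differ(self):
        sim1 = make_walkers(n=300, seed=5)
        sim1.run(400, seed=42)
        sim2 = make_walkers(n=300, seed=5)
        sim2.run(400, seed=43)
        assert not np.array_equal(sim1.positions("w"), sim2.positions("w"))


class TestDiffusion:
    def test_msd_slope_and_isotropy(self):
        """Free-walker MSD grows as p * dx^2 per step (= 6 D t), with equal
        per-axis displacement variance."""
        sim = make_walkers(n=4000, p=0.9, seed=1)
        p0 = sim.positions("w").astype(float)
        checkpoints, msds = [], []
        total = 0
        for c in range(5):
            sim.run(150, seed=c + 10)
            total += 150
            disp = sim.positions("w").astype(float) - p0
            checkpoints.append(total)
            msds.append((disp**2).sum(axis=1).mean())
        slope = np.polyfit(checkpoints, msds, 1)[0]
        assert slope == pytest.approx(0.9, rel=0.03)
        var_axes = disp.var(axis=0)
        assert var_axes.max() / var_axes.min() < 1.15

    def test_forced_walker_moves_every_step(self):
        sim = make_walkers(n=1, p=1.0, seed=2)
        p0 = sim.positions("w").copy()
        for c in range(20):
            sim.run(1, seed=c)
            p1 = sim.positions("w")
            assert np.abs(p1 - p0).sum() == 1  # exactly one lattice hop
            p0 = p1.copy()

    def test_empty_lattice_step_is_identity(self):
        sim = Simulation(Lattice.box((4, 4, 4)), [Species("w", 0.5)])
        res = sim.run(10, seed=1)
        assert res.counts.sum() == 0
        sim.check_invariants()


class TestCrowding:
    def test_full_cell_is_never_entered(self):
        """Volume limit: a cell with zero free volume rejects all moves."""
        lat = Lattice.box((3, 1, 1), periodic=False)
        sim = Simulation(
            lat, [Species("big", 0.0, 125.0), Species("w", 1.0, 60.0)],
            config=EngineConfig(dt_s=DT), )
        sim.add_agents("big", cells=[1])
        sim.add_agents("w", cells=[0])
        sim.run(500, seed=3)
        assert sim.positions("w")[0, 0] == 0  # blocked by the full middle cell
        sim.check_invariants()

    def test_uniform_density_of_finite_volume_agents(self):
        """Non-interacting finite-volume agents equilibrate to uniform
        occupancy over accessible cells (RP acceptance is unbiased)."""
        sim = make_walkers(n=1500, p=0.9, vol=40.0, shape=(12, 12, 12), seed=4)
        sim.run(3000, seed=9)
        counts = np.zeros(12, dtype=float)
        for c in range(8):
            sim.run(250, seed=50 + c)
            z = sim.positions("w")[:, 2] % 12
            counts += np.bincount(z, minlength=12)
        frac = counts / counts.sum()
        assert np.all(np.abs(frac - 1 / 12) < 0.012)
        sim.check_invariants()

    def test_occupancy_ledger_fuzz(self):
        """Dense random initial conditions never overflow any cell."""
        for seed in range(3):
            sim = make_walkers(n=800, p=0.9, vol=55.0, shape=(8, 8, 8), seed=seed)
            sim.run(2000, seed=seed + 100)
            sim.check_invariants()  # includes occupancy <= cell volume


class TestReactions:
    def two_species_sim(self, p_bind=1.0, p_unbind=0.0, cells_a=(0,), cells_b=(1,)):
        lat = Lattice.box((3, 1, 1), periodic=False)
        sim = Simulation(
            lat,
            [Species("A", 0.0, 1.0), Species("B", 0.0, 1.0)],
            [PairRule("A", "B", p_bind, p_unbind, name="A+B")],
            config=EngineConfig(dt_s=DT),
        )
        sim.add_agents("A", cells=list(cells_a))
        sim.add_agents("B", cells=list(cells_b))
        return sim

    def test_adjacent_pair_binds_and_stays_bound(self):
        sim = self.two_species_sim()
        sim.run(1, seed=1)
        a = sim.agent_ids("A")[0]
        assert sim.apart[a] >= 0
        sim.run(100, seed=2)
        assert sim.apart[a] >= 0  # irreversible: absorbing state
        sim.check_invariants()

    def test_candidate_enumeration_one_a_two_adjacent_b(self):
        sim = self.two_species_sim(cells_a=(1,), cells_b=(0, 2))
        assert len(sim.reaction_candidates(0)) == 2

    def test_same_cell_pair_is_one_candidate(self):
        sim = self.two_species_sim(cells_a=(1,), cells_b=(1,))
        assert len(sim.reaction_candidates(0)) == 1

    def test_agent_binds_at_most_once_per_step(self):
        sim = self.two_species_sim(cells_a=(1,), cells_b=(0, 2))
        sim.run(1, seed=7)
        a = sim.agent_ids("A")[0]
        bs = sim.agent_ids("B")
        bound_bs = [b for b in bs if sim.apart[b] >= 0]
        assert len(bound_bs) == 1 and sim.apart[a] == bound_bs[0]

    def test_bound_pair_colocates_when_volume_allows(self):
        sim = self.two_species_sim()
        sim.run(1, seed=1)
        a = sim.agent_ids("A")[0]
        b = sim.apart[a]
        assert sim.acell[a] == sim.acell[b]

    def test_unbinding_decay_matches_first_order_kinetics(self):
        """An ensemble of bound pairs decays as exp(-k_off t)."""
        lat = Lattice.box((16, 16, 16), periodic=True)
        p_unbind = 2.5e-3  # k_off = 1000 /s at dt = 2.5e-6
        sim = Simulation(
            lat,
            [Species("A", 0.0, 0.0), Species("B", 0.0, 0.0)],
            [PairRule("A", "B", 1.0, p_unbind, name="A+B")],
            config=EngineConfig(dt_s=DT),
        )
        # isolated co-located pairs on the even sublattice: no two candidate
        # pairs are ever adjacent, so every A binds its own B at step one
        xs, ys, zs = np.meshgrid(*([np.arange(0, 16, 2)] * 3), indexing="ij")
        cells = ((xs * 16 + ys) * 16 + zs).ravel()
        n = len(cells)
        sim.add_agents("A", cells=cells)
        sim.add_agents("B", cells=cells)
        sim.run(1, seed=3)  # co-located pairs all bind
        assert sim.free_count("A") == 0
        # forbid rebinding so the survival curve is a pure decay
        sim.r_pbind[0] = 0.0
        steps = 400
        sim.run(steps, seed=4)
        survive = n - sim.free_count("A")
        expected = n * (1 - p_unbind) ** steps
        assert abs(survive - expected) < 4 * np.sqrt(n * 0.63 * 0.37)

    def test_conservation_without_clamps(self):
        sim = self.two_species_sim(p_bind=0.3, p_unbind=0.1)
        for c in range(20):
            sim.run(25, seed=c)
            assert len(sim.agent_ids("A")) == 1
            assert len(sim.agent_ids("B")) == 1


class TestClampsAndRestrictions:
    def clamped_sim(self, n0, target):
        lat = Lattice.box((8, 8, 8), periodic=True)
        sim = Simulation(
            lat,
            [Species("A", 0.5, 10.0)],
            clamps=[Clamp("A", 0, target)],
            config=EngineConfig(dt_s=DT),
        )
        if n0:
            sim.add_agents("A", n=n0, rng=1)
        return sim

    def test_clamp_at_target_is_a_no_op(self):
        sim = self.clamped_sim(5, 5)
        sim.run(200, seed=2)
        ledger = sim.clamp_ledger()
        assert ledger.inserted.iloc[0] == 0 and ledger.removed.iloc[0] == 0
        assert sim.free_count("A") == 5

    def test_clamp_restores_deficit_and_excess(self):
        sim = self.clamped_sim(2, 6)
        sim.run(1, seed=3)
        assert sim.free_count("A") == 6
        assert sim.clamp_ledger().inserted.iloc[0] == 4
        sim2 = self.clamped_sim(9, 6)
        sim2.run(1, seed=4)
        assert sim2.free_count("A") == 6
        assert sim2.clamp_ledger().removed.iloc[0] == 3

    def test_zero_target_empties_region(self):
        sim = self.clamped_sim(4, 0)
        sim.run(1, seed=5)
        assert sim.free_count("A") == 0

    def test_species_confined_to_allowed_region(self):
        region = np.zeros((6, 6, 6), dtype=np.int64)
        region[:, :, 3:] = 1
        lat = Lattice(shape=(6, 6, 6), region=region, periodic=False)
        sim = Simulation(lat, [Species("r", 0.9, 0.0, allowed_regions=(1,))],
                         config=EngineConfig(dt_s=DT))
        sim.add_agents("r", n=40, region=1, rng=2)
        sim.run(2000, seed=6)
        assert set(np.unique(sim.region[sim.acell[sim.agent_ids("r")]])) == {1}
        sim.check_invariants()
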