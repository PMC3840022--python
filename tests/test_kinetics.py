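"""Rate-constant -> probability mapping, including the Monte-Carlo
encounter oracle for the co-occupancy neighbour correction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from npcabm.engine import EngineConfig, Lattice, Simulation, Species
from npcabm.kinetics import (
    KineticPair,
    LatticeGeometry,
    TimestepOverflowError,
    bind_probability,
    move_probability,
    neighbor_correction,
    unbind_probability,
    unbind_probability_exact,
    validate_timestep,
)

GEOM = LatticeGeometry(cell_edge_nm=5.0)
DT = 2.5e-6


class TestMoveProbability:
    def test_immobile_species(self):
        assert move_probability(0.0, DT, GEOM) == 0.0

    def test_reference_value(self):
        # 6 * D * dt / dx^2 with D = 1 um^2/s, dt = 2.5e-6 s, dx = 5 nm
        assert move_probability(1.0, DT, GEOM) == pytest.approx(0.6)

    def test_overflow_is_error_with_max_dt(self):
        with pytest.raises(TimestepOverflowError) as exc:
            move_probability(2.0, DT, GEOM)  # would be 1.2
        assert exc.value.max_dt == pytest.approx(25.0 / (6 * 2.0e6))


class TestUnbindProbability:
    def test_irreversible_complex(self):
        assert unbind_probability(0.0, DT) == 0.0

    def test_linear_form(self):
        assert unbind_probability(1000.0, DT) == pytest.approx(2.5e-3)

    def test_probability_bound(self):
        with pytest.raises(TimestepOverflowError):
            unbind_probability(1000.0, 1.5e-3)

    def test_exponential_form_agrees_at_small_dt(self):
        assert unbind_probability_exact(1000.0, DT) == pytest.approx(
            unbind_probability(1000.0, DT), rel=2e-3)


class TestBindProbability:
    def test_non_interacting_pair(self):
        pair = KineticPair(0.0, 0.0)
        assert bind_probability(pair, DT, GEOM) == 0.0

    def test_same_species_exactly_halved(self):
        hetero = KineticPair(1e7, 0.0, same_species=False, correction_factor=0.5)
        homo = KineticPair(1e7, 0.0, same_species=True, correction_factor=0.5)
        assert bind_probability(homo, DT, GEOM) / bind_probability(hetero, DT, GEOM) == 0.5

    def test_overflow_reports_max_dt(self):
        pair = KineticPair(1e12, 0.0)
        with pytest.raises(TimestepOverflowError) as exc:
            bind_probability(pair, DT, GEOM)
        assert bind_probability(pair, exc.value.max_dt, GEOM) <= 1.0

    @settings(derandomize=True, max_examples=40)
    @given(kon=st.floats(1e3, 1e8), koff=st.floats(0.0, 1e4), halve=st.integers(1, 6))
    def test_linearity_in_dt(self, kon, koff, halve):
        """Halving dt halves p_bind and p_unbind exactly (small-dt mapping)."""
        pair = KineticPair(kon, koff)
        dt2 = DT / halve
        assert bind_probability(pair, dt2, GEOM) * halve == pytest.approx(
            bind_probability(pair, DT, GEOM), rel=1e-12)
        assert unbind_probability(koff, dt2) * halve == pytest.approx(
            unbind_probability(koff, DT), rel=1e-12)


class TestNeighborCorrection:
    def test_exclusion_when_pair_exceeds_cell(self):
        assert neighbor_correction((80.0, 60.0), 125.0) == 0.0

    def test_point_like_limit_is_maximal(self):
        nc0 = neighbor_correction((0.0, 0.0), 125.0)
        assert nc0 == pytest.approx(1.0)
        assert nc0 >= neighbor_correction((10.0, 10.0), 125.0)

    @settings(derandomize=True, max_examples=40)
    @given(v1=st.floats(0, 60), v2=st.floats(0, 60), dv=st.floats(0, 20))
    def test_monotone_non_increasing_in_summed_volume(self, v1, v2, dv):
        assert neighbor_correction((v1, v2), 125.0) >= neighbor_correction(
            (v1 + dv, v2), 125.0)

    def test_negative_volume_rejected(self):
        with pytest.raises(ValueError):
            neighbor_correction((-1.0, 10.0), 125.0)

    @pytest.mark.parametrize(
        "vols, expected_nc",
        [((0.0, 0.0), 1.0), ((40.0, 60.0), 1.0 - 100.0 / 250.0)],
    )
    def test_monte_carlo_encounter_oracle(self, vols, expected_nc):
        """Two hard molecules random-walking under RP+VL in a periodic box:
        the stationary in-cell encounter frequency, relative to a single
        neighbour channel, must match the closed form used for n_c."""
        lat = Lattice.box((4, 4, 4), periodic=True)
        sim = Simulation(
            lat,
            [Species("A", 0.9, vols[0]), Species("B", 0.9, vols[1])],
            config=EngineConfig(dt_s=DT),
        )
        sim.add_agents("A", cells=[0])
        sim.add_agents("B", cells=[32])
        n_same = n_adj = n_tot = 0
        for c in range(6000):
            sim.run(40, seed=c + 1)
            pa, pb = sim.positions("A")[0], sim.positions("B")[0]
            d = pa - pb
            d = (d + 2) % 4 - 2  # minimum-image on the periodic box
            dist = np.abs(d).sum()
            n_tot += 1
            if dist == 0:
                n_same += 1
            elif dist == 1 and np.count_nonzero(d) == 1:
                n_adj += 1
        nc_hat = 6.0 * n_same / max(n_adj, 1)
        # ~sqrt(n_same) counting noise; 6000 samples give a few-sigma test
        sigma = 6.0 * np.sqrt(max(n_same, 4)) / max(n_adj, 1)
        assert abs(nc_hat - expected_nc) < max(3 * sigma, 0.15)


class TestValidateTimestep:
    DIFF = {"impb": 1.5, "tracer": 1.5, "nup": 0.4}
    PAIRS = [KineticPair(1.66e7, 2000.0, name="impb:fg"),
             KineticPair(1.66e8, 0.0, name="impb:ran", correction_factor=0.5)]

    def test_reference_scenario_passes_at_default_dt(self):
        report = validate_timestep(self.DIFF, self.PAIRS, DT, GEOM)
        assert report.ok
        assert all(0 <= p <= 1 for p in report.move.values())

    def test_thousandfold_dt_fails_with_aggregated_report(self):
        report = validate_timestep(self.DIFF, self.PAIRS, DT * 1000, GEOM)
        assert not report.ok
        assert len(report.violations) >= 2  # every violating species/pair listed
        with pytest.raises(TimestepOverflowError):
            report.raise_if_invalid()
        assert report.max_admissible_dt < DT * 1000

    def test_half_dt_halves_all_linear_probabilities(self):
        full = validate_timestep(self.DIFF, self.PAIRS, DT, GEOM)
        half = validate_timestep(self.DIFF, self.PAIRS, DT / 2, GEOM)
        for key in full.move:
            assert half.move[key] == pytest.approx(full.move[key] / 2)
        for key in full.bind:
            assert half.bind[key] == pytest.approx(full.bind[key] / 2)
        for key in full.unbind:
            assert half.unbind[key] == pytest.approx(full.unbind[key] / 2)


class TestKineticPair:
    def test_inconsistent_kd_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            KineticPair.from_quantities(
                k_on="1e7 1/M/s", k_off="2000 1/s", K_D="100 uM")

    def test_kd_only_implies_koff(self):
        pair = KineticPair.from_quantities(k_on="1e7 1/M/s", K_D="200 uM")
        # k_off = K_D * k_on = 200e-6 * 1e7 = 2000 /s
        assert pair.k_off_s == pytest.approx(2000.0, rel=1e-9)

    def test_consistent_triple_accepted(self):
        KineticPair.from_quantities(
            k_on="1e7 1/M/s", k_off="2000 1/s", K_D="200 uM")
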