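"""NPC scenario: geometry, populations, clamps, transport semantics."""

import numpy as np
import pytest
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from npcabm.engine import EngineConfig, Lattice, PairRule, Simulation, Species
from npcabm.npc import (
    BASKET,
    CHANNEL,
    CYTOPLASM,
    MEMBRANE,
    NUCLEOPLASM,
    PERIPHERY,
    AffinityGradient,
    GRADIENT_PRESETS,
    NpcGeometrySpec,
    NpcScenario,
    build_geometry,
    build_simulation,
    microinject,
    validate_scenario,
)
from npcabm.config import scenario_to_config
from npcabm.units import PER_NM3_PER_MOLAR


@pytest.fixture(scope="module")
def geom():
    return build_geometry()


class TestGeometry:
    def test_total_element_count(self, geom):
        assert sum(v["cells"] for v in geom.audit.values()) == 42108

    def test_membrane_is_inaccessible(self, geom):
        lat = geom.lattice
        membrane = lat.flat_region() == MEMBRANE
        assert not lat.flat_accessible()[membrane].any()
        assert lat.flat_accessible()[~membrane].all()

    def test_region_map_is_deterministic(self, geom):
        again = build_geometry()
        assert np.array_equal(geom.lattice.region, again.lattice.region)

    def test_pore_is_the_only_passage(self, geom):
        """Removing the three pore regions disconnects cytoplasm from
        nucleoplasm: every lattice path between them crosses the pore."""
        lat = geom.lattice
        reg = lat.flat_region()
        keep = lat.flat_accessible() & np.isin(reg, [CYTOPLASM, NUCLEOPLASM])
        idx = -np.ones(lat.n_cells, dtype=np.int64)
        nodes = np.flatnonzero(keep)
        idx[nodes] = np.arange(len(nodes))
        nx, ny, nz = lat.shape
        rows, cols = [], []
        grid = keep.reshape(nx, ny, nz)
        ids = idx.reshape(nx, ny, nz)
        for axis in range(3):
            sl_a = [slice(None)] * 3
            sl_b = [slice(None)] * 3
            sl_a[axis] = slice(0, -1)
            sl_b[axis] = slice(1, None)
            both = grid[tuple(sl_a)] & grid[tuple(sl_b)]
            rows.append(ids[tuple(sl_a)][both])
            cols.append(ids[tuple(sl_b)][both])
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        adj = coo_matrix((np.ones(len(rows)), (rows, cols)),
                         shape=(len(nodes), len(nodes)))
        n_comp, labels = connected_components(adj, directed=False)
        cyt_label = labels[idx[lat.cells_in_region(CYTOPLASM)[0]]]
        nuc_label = labels[idx[lat.cells_in_region(NUCLEOPLASM)[0]]]
        assert cyt_label != nuc_label

    def test_pore_regions_connect_the_compartments(self, geom):
        lat = geom.lattice
        nx, ny, nz = lat.shape
        keep = lat.flat_accessible().copy()
        grid = keep.reshape(nx, ny, nz)
        idx = -np.ones(lat.n_cells, dtype=np.int64)
        nodes = np.flatnonzero(keep)
        idx[nodes] = np.arange(len(nodes))
        ids = idx.reshape(nx, ny, nz)
        rows, cols = [], []
        for axis in range(3):
            sl_a = [slice(None)] * 3
            sl_b = [slice(None)] * 3
            sl_a[axis] = slice(0, -1)
            sl_b[axis] = slice(1, None)
            both = grid[tuple(sl_a)] & grid[tuple(sl_b)]
            rows.append(ids[tuple(sl_a)][both])
            cols.append(ids[tuple(sl_b)][both])
        adj = coo_matrix(
            (np.ones(sum(len(r) for r in rows)),
             (np.concatenate(rows), np.concatenate(cols))),
            shape=(len(nodes), len(nodes)))
        n_comp, labels = connected_components(adj, directed=False)
        assert n_comp == 1  # with the pore open, everything is reachable

    def test_inconsistent_dimensions_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            build_geometry(NpcGeometrySpec(shape=(29, 33, 20)))


class TestPopulate:
    def test_clamp_targets_follow_closed_form_counts(self, geom):
        sc = NpcScenario()
        sim, meta = build_simulation(sc, seed=1)
        v_cyt = geom.audit[CYTOPLASM]["volume_nm3"]
        v_nuc = geom.audit[NUCLEOPLASM]["volume_nm3"]
        assert meta["impb_clamp_target"] == round(2.5e-6 * PER_NM3_PER_MOLAR * v_cyt)
        assert meta["rangtp_clamp_target"] == round(1.0e-6 * PER_NM3_PER_MOLAR * v_nuc)
        assert len(sim.agent_ids("impb")) == meta["impb_clamp_target"]

    def test_two_seeds_same_counts_different_placements(self):
        sc = NpcScenario()
        sim1, _ = build_simulation(sc, seed=1)
        sim2, _ = build_simulation(sc, seed=2)
        assert sim1.n_agents == sim2.n_agents
        assert not np.array_equal(sim1.positions("non_fg"), sim2.positions("non_fg"))

    def test_fg_counts_exact(self):
        sim, _ = build_simulation(NpcScenario(), seed=3)
        assert len(sim.agent_ids("fg_periphery")) == 24
        assert len(sim.agent_ids("fg_channel")) == 80
        assert len(sim.agent_ids("fg_basket")) == 32

    def test_zero_concentration_clamp_places_no_agents(self):
        sim, meta = build_simulation(NpcScenario(rangtp_conc_uM=0.0), seed=4)
        assert meta["rangtp_clamp_target"] == 0
        assert len(sim.agent_ids("rangtp")) == 0
        sim.run(500, seed=5)  # runs fine without RanGTP (ablation)
        sim.check_invariants()


class TestRunBehaviour:
    def test_membrane_never_occupied_and_nups_confined(self):
        sim, _ = build_simulation(NpcScenario(), seed=7)
        sim.run(20000, seed=8)
        sim.check_invariants()
        regs = sim.region[sim.acell[sim.agent_ids()]]
        assert MEMBRANE not in regs
        for name, home in (("fg_periphery", PERIPHERY), ("fg_channel", CHANNEL),
                           ("fg_basket", BASKET), ("non_fg", CHANNEL)):
            assert sim.counts_by_region(name) == {home: len(sim.agent_ids(name))}

    def test_clamp_fidelity_over_time(self):
        sim, meta = build_simulation(NpcScenario(), seed=9)
        target = meta["impb_clamp_target"]
        samples = []
        for c in range(20):
            sim.run(1000, seed=20 + c)
            samples.append(sim.free_count("impb", region=CYTOPLASM))
        # clamp restores after every step; sampled counts sit at the target
        # within the one-agent quantisation
        assert np.all(np.abs(np.asarray(samples) - target) <= 1)
        ledger = sim.clamp_ledger()
        assert (ledger.inserted >= 0).all()

    def test_gradient_reduction_to_uniform_is_bitwise(self):
        uni = NpcScenario(gradient=AffinityGradient.uniform(200.0))
        explicit = NpcScenario(gradient=AffinityGradient(200.0, 200.0, 200.0))
        assert scenario_to_config(uni) == scenario_to_config(explicit)

    def test_translocation_counts_telescope(self):
        """Oscillation across the basket/nucleoplasm boundary nets out."""
        sim, _ = build_simulation(NpcScenario(), seed=11)
        sim.run(50000, seed=12)
        tr = sim.translocation_totals("impb")
        net_in = tr["pore_to_nucleus"] - tr["nucleus_to_pore"]
        # conservation: net flow into nucleus + net flow into cytoplasm
        # + standing pore/compartment population changes = clamp net injections
        assert abs(net_in) <= tr["pore_to_nucleus"]


class TestTransportRules:
    def build_micro(self):
        """Minimal displacement fixture: Impβ-like A bound to Nup-like N,
        RanGTP-like R adjacent with a displacing irreversible rule."""
        lat = Lattice.box((3, 1, 1), periodic=False)
        sim = Simulation(
            lat,
            [Species("A", 0.0, 10.0), Species("N", 0.0, 10.0), Species("R", 0.0, 10.0)],
            [
                PairRule("A", "N", 1.0, 0.0, displaceable=True, name="A:N"),
                PairRule("R", "A", 1.0, 0.0, displaces=True, name="R:A"),
            ],
            config=EngineConfig(dt_s=2.5e-6),
        )
        return sim

    def test_rangtp_strips_nup_bond(self):
        sim = self.build_micro()
        sim.add_agents("A", cells=[1])
        sim.add_agents("N", cells=[1])
        sim.run(1, seed=1)
        a = sim.agent_ids("A")[0]
        n = sim.agent_ids("N")[0]
        assert sim.apart[a] == n  # Nup-bound first
        sim.add_agents("R", cells=[2])
        r = sim.agent_ids("R")[0]
        sim.run(1, seed=2)
        assert sim.apart[a] == r  # displaced into the A-R complex
        assert sim.apart[n] == -1  # Nup released
        sim.check_invariants()

    def test_complex_cannot_rebind_nups(self):
        sim = self.build_micro()
        sim.add_agents("A", cells=[1])
        sim.add_agents("R", cells=[1])
        sim.run(1, seed=3)
        a = sim.agent_ids("A")[0]
        assert sim.asp[sim.apart[a]] == sim.species_index("R")
        sim.add_agents("N", cells=[0])
        sim.run(50, seed=4)
        assert sim.asp[sim.apart[a]] == sim.species_index("R")  # still RanGTP-bound
        assert sim.apart[sim.agent_ids("N")[0]] == -1


class TestMicroinjection:
    def test_injected_count_follows_closed_form(self, geom):
        sc = NpcScenario(include_labeled_impb=True)
        sim, meta = build_simulation(sc, seed=13)
        v_cyt = geom.audit[CYTOPLASM]["volume_nm3"]
        n = microinject(sim, sc, "impb_labeled", 2.5, region=CYTOPLASM, rng=1)
        assert n == round(2.5e-6 * PER_NM3_PER_MOLAR * v_cyt)
        assert len(sim.agent_ids("impb_labeled")) == n
        # unlabeled clamp population is untouched
        assert len(sim.agent_ids("impb")) == meta["impb_clamp_target"]

    def test_zero_injection_is_noop_and_injections_are_additive(self):
        sc = NpcScenario(include_labeled_impb=True)
        sim, _ = build_simulation(sc, seed=14)
        assert microinject(sim, sc, "impb_labeled", 0.0) == 0
        n1 = microinject(sim, sc, "impb_labeled", 5.0, rng=2)
        n2 = microinject(sim, sc, "impb_labeled", 5.0, rng=3)
        assert len(sim.agent_ids("impb_labeled")) == n1 + n2


class TestTimestepValidation:
    def test_default_scenario_validates_at_reference_dt(self):
        report = validate_scenario(NpcScenario())
        assert report.ok
        assert all(p <= 1.0 for p in report.move.values())

    def test_micromolar_kon_reading_fails_validation(self):
        """The dimensionally suspicious on-rate reading (uM^-1 s^-1) is
        expressible but cannot run at the reference timestep."""
        from npcabm.kinetics import TimestepOverflowError
        sc = NpcScenario(impb_rangtp_kon=(9.6e4, "1/uM/s"))
        with pytest.raises(TimestepOverflowError):
            validate_scenario(sc)

    def test_thousandfold_timestep_fails(self):
        from npcabm.kinetics import TimestepOverflowError
        with pytest.raises(TimestepOverflowError):
            validate_scenario(NpcScenario(dt_s=2.5e-3))
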