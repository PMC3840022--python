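"""The nuclear pore complex world: geometry, species, kinetics, clamps.

The model is a 42,108-element lattice of 5 nm cells split into six regions:
bulk cytoplasm, bulk nucleoplasm, an impermeable 35 nm nuclear membrane, and
the three pore regions — a cytoplasmic-filament periphery (50 nm diameter
cylinder reaching 30 nm into the cytoplasm), an hourglass central channel
through the membrane (50 nm diameter at both faces, 30 nm at the midplane),
and a nuclear basket (truncated cone reaching 55 nm into the nucleoplasm,
widening from the channel exit to a 50 nm distal ring).

FG-nucleoporin agents (24 / 80 / 32 in periphery / channel / basket) bind
Impβ with a region-specific dissociation constant (the affinity gradient);
steric non-FG nucleoporin agents crowd the central channel and create the
passive permeability barrier.  Cytoplasmic Impβ and nuclear RanGTP are held
at fixed concentrations by clamps; RanGTP binding strips Impβ off FG-Nups,
blocks rebinding, and the resulting complex is recycled out of the bulk
nucleoplasm, terminating one import event.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .engine import (
    Clamp,
    ComplexSink,
    EngineConfig,
    Lattice,
    PairRule,
    Simulation,
    Species,
)
from .kinetics import (
    KineticPair,
    LatticeGeometry,
    bind_probability,
    move_probability,
    neighbor_correction,
    unbind_probability,
    validate_timestep,
)
from .units import PER_NM3_PER_MOLAR, parse_quantity

# region labels
CYTOPLASM, NUCLEOPLASM, MEMBRANE, PERIPHERY, CHANNEL, BASKET = range(6)
REGION_NAMES = {
    CYTOPLASM: "cytoplasm",
    NUCLEOPLASM: "nucleoplasm",
    MEMBRANE: "nuclear_membrane",
    PERIPHERY: "cytoplasmic_periphery",
    CHANNEL: "central_channel",
    BASKET: "nuclear_basket",
}
PORE_REGIONS = (PERIPHERY, CHANNEL, BASKET)
# region -> compartment (0 cytoplasm, 1 nucleus, 2 pore, 3 other)
COMPARTMENT_OF_REGION = np.array([0, 1, 3, 2, 2, 2], dtype=np.int64)


def radius_from_volume(volume_nm3: float) -> float:
    return (3.0 * volume_nm3 / (4.0 * math.pi)) ** (1.0 / 3.0)


def volume_from_radius(radius_nm: float) -> float:
    return 4.0 / 3.0 * math.pi * radius_nm**3


@dataclass(frozen=True)
class NpcGeometrySpec:
    """Lattice and pore dimensions (all lengths nm)."""

    cell_edge_nm: float = 5.0
    shape: tuple = (29, 33, 44)  # 42,108 elements; z is the transport axis
    membrane_z0: int = 15  # first membrane layer
    membrane_thickness_nm: float = 35.0
    pore_mid_diameter_nm: float = 30.0
    pore_peripheral_diameter_nm: float = 50.0
    periphery_depth_nm: float = 30.0
    basket_depth_nm: float = 55.0
    basket_proximal_diameter_nm: float = 30.0
    basket_distal_diameter_nm: float = 50.0

    @property
    def membrane_layers(self) -> int:
        return int(round(self.membrane_thickness_nm / self.cell_edge_nm))

    @property
    def axis_center(self) -> tuple:
        return ((self.shape[0] - 1) // 2, (self.shape[1] - 1) // 2)


@dataclass
class NpcGeometry:
    """Built lattice plus a per-region audit of cell counts and volumes."""

    spec: NpcGeometrySpec
    lattice: Lattice
    audit: dict  # region label -> {"cells": int, "volume_nm3": float}

    def region_volume_nm3(self, label) -> float:
        return self.audit[label]["volume_nm3"]

    def cells_far_from_pore(self, region, margin_layers=3) -> np.ndarray:
        """Clamp-insertion cells: bulk cells at least *margin_layers* beyond
        the pore-facing boundary of the compartment."""
        spec = self.spec
        z = np.arange(self.lattice.n_cells) % spec.shape[2]
        cells = self.lattice.cells_in_region(region)
        zc = cells % spec.shape[2]
        if region == CYTOPLASM:
            z_limit = spec.membrane_z0 - int(spec.periphery_depth_nm // spec.cell_edge_nm) - margin_layers
            return cells[zc < z_limit]
        if region == NUCLEOPLASM:
            z_limit = (
                spec.membrane_z0 + spec.membrane_layers
                + int(spec.basket_depth_nm // spec.cell_edge_nm) + margin_layers
            )
            return cells[zc >= z_limit]
        raise ValueError("clamp regions are bulk cytoplasm or nucleoplasm")


def build_geometry(spec: NpcGeometrySpec | None = None) -> NpcGeometry:
    """Deterministically label every lattice cell with its region."""
    spec = spec or NpcGeometrySpec()
    nx, ny, nz = spec.shape
    edge = spec.cell_edge_nm
    cx, cy = spec.axis_center
    mz0 = spec.membrane_z0
    mlayers = spec.membrane_layers
    mz1 = mz0 + mlayers
    per_layers = int(round(spec.periphery_depth_nm / edge))
    bas_layers = int(round(spec.basket_depth_nm / edge))
    if mz0 < per_layers or mz1 + bas_layers > nz:
        raise ValueError("inconsistent dimensions: pore structures exceed the lattice")

    x = np.arange(nx)[:, None, None]
    y = np.arange(ny)[None, :, None]
    z = np.arange(nz)[None, None, :]
    r_nm = np.sqrt((x - cx) ** 2 + (y - cy) ** 2) * edge + 0.0 * z

    r_per = spec.pore_peripheral_diameter_nm / 2.0
    r_mid = spec.pore_mid_diameter_nm / 2.0
    region = np.full(spec.shape, CYTOPLASM, dtype=np.int64)
    region[:, :, mz1:] = NUCLEOPLASM

    # membrane slab with the hourglass channel bored through it
    zmid = (mz0 + mz1 - 1) / 2.0
    for l in range(mz0, mz1):
        frac = abs(l - zmid) / (mlayers / 2.0 - 0.5) if mlayers > 1 else 0.0
        r_chan = r_mid + (r_per - r_mid) * frac
        layer = np.where(r_nm[:, :, 0] <= r_chan, CHANNEL, MEMBRANE)
        region[:, :, l] = layer

    # cytoplasmic filament periphery: cylinder reaching into the cytoplasm
    for l in range(mz0 - per_layers, mz0):
        mask = r_nm[:, :, 0] <= r_per
        region[:, :, l][mask] = PERIPHERY

    # nuclear basket: truncated cone widening away from the membrane
    r_bp = spec.basket_proximal_diameter_nm / 2.0
    r_bd = spec.basket_distal_diameter_nm / 2.0
    for i, l in enumerate(range(mz1, mz1 + bas_layers)):
        frac = i / max(bas_layers - 1, 1)
        r_bask = r_bp + (r_bd - r_bp) * frac
        mask = r_nm[:, :, 0] <= r_bask
        region[:, :, l][mask] = BASKET

    accessible = region != MEMBRANE
    lattice = Lattice(
        shape=spec.shape, region=region, accessible=accessible,
        cell_edge_nm=edge, periodic=False,
    )
    audit = {}
    for label in range(6):
        n = int((region == label).sum())
        audit[label] = {
            "name": REGION_NAMES[label],
            "cells": n,
            "volume_nm3": n * lattice.cell_volume_nm3,
        }
    return NpcGeometry(spec=spec, lattice=lattice, audit=audit)


@dataclass(frozen=True)
class AffinityGradient:
    """Nup-Impβ dissociation constants (µM) for the three pore regions."""

    periphery_uM: float
    channel_uM: float
    basket_uM: float

    @classmethod
    def uniform(cls, kd_uM: float) -> "AffinityGradient":
        return cls(kd_uM, kd_uM, kd_uM)

    def as_tuple(self):
        return (self.periphery_uM, self.channel_uM, self.basket_uM)


#: in vitro / optimised gradients (periphery, channel, basket) in µM
GRADIENT_PRESETS = {
    "yeast": AffinityGradient(1.5, 0.2, 0.01),
    "vertebrate": AffinityGradient(0.2, 0.1, 0.01),
    "optimum": AffinityGradient(2000.0, 200.0, 10.0),
    "uniform_200uM": AffinityGradient.uniform(200.0),
}


@dataclass(frozen=True)
class TracerSpec:
    """An inert (non-interacting) species used for passive-permeability assays."""

    name: str
    stokes_radius_nm: float

    @property
    def volume_nm3(self) -> float:
        return volume_from_radius(self.stokes_radius_nm)


#: Stokes radii (nm) spanning the passive-permeability panel
DEFAULT_TRACER_RADII = (0.531, 1.0, 1.5, 2.0, 2.5, 2.819)


@dataclass(frozen=True)
class NpcScenario:
    """Full parameterisation of one NPC simulation configuration.

    Defaults are the reference conditions; sweeps replace ``gradient`` and
    sensitivity analyses scale the concentration / timestep fields.
    """

    gradient: AffinityGradient = GRADIENT_PRESETS["uniform_200uM"]
    dt_s: float = 2.5e-6
    impb_conc_uM: float = 2.5
    rangtp_conc_uM: float = 1.0
    nup_impb_kon: tuple = (1.0e7, "1/M/s")
    impb_rangtp_kon: tuple = (1.0e8, "1/M/s")
    fg_counts: tuple = (24, 80, 32)  # periphery, channel, basket
    fg_volume_nm3: float = 35.0
    fg_diffusivity_um2_s: float = 0.4  # local jiggle of unstructured FG domains
    #: steric non-FG agents represent structured scaffold-anchored domains;
    #: they are immobile and their total volume sets the passive barrier
    non_fg_count: int = 650
    non_fg_volume_nm3: float = 40.0
    non_fg_diffusivity_um2_s: float = 0.1
    impb_volume_nm3: float = 90.0
    rangtp_volume_nm3: float = 34.0
    #: single effective diffusivity for freely diffusing species.  The
    #: timestep/lattice pair caps admissible D at dx^2/(6 dt) = 1.67 um^2/s,
    #: which compresses the narrow Stokes-Einstein range of this 0.5-3 nm
    #: panel against the ceiling; size selectivity is carried by excluded
    #: volume, not mobility.
    diffusivity_um2_s: float = 1.5
    bound_complex_mobile: bool = True
    tracer_radii_nm: tuple = ()
    #: register a "impb_labeled" species: identical physics to impb (binds
    #: FG-Nups and RanGTP) but unclamped and never recycled, so that a
    #: microinjected bolus is conserved and its nuclear accumulation can be
    #: fitted to first-order influx kinetics
    include_labeled_impb: bool = False
    geometry: NpcGeometrySpec = field(default_factory=NpcGeometrySpec)

    def diffusivity(self, radius_nm: float) -> float:  # noqa: ARG002
        return self.diffusivity_um2_s

    @property
    def impb_diffusivity_um2_s(self) -> float:
        return self.diffusivity_um2_s

    @property
    def rangtp_diffusivity_um2_s(self) -> float:
        return self.diffusivity_um2_s

    def with_gradient(self, gradient: AffinityGradient) -> "NpcScenario":
        return replace(self, gradient=gradient)


def _kinetic_pairs(scenario: NpcScenario, geometry: LatticeGeometry):
    """KineticPair per interaction, with co-occupancy corrections."""
    kon_nup = parse_quantity(
        {"value": scenario.nup_impb_kon[0], "unit": scenario.nup_impb_kon[1]}, "kon"
    ).internal
    kon_ran = parse_quantity(
        {"value": scenario.impb_rangtp_kon[0], "unit": scenario.impb_rangtp_kon[1]}, "kon"
    ).internal
    vcell = geometry.cell_volume_nm3
    nc_fg = neighbor_correction(
        (scenario.impb_volume_nm3, scenario.fg_volume_nm3), vcell
    )
    nc_ran = neighbor_correction(
        (scenario.impb_volume_nm3, scenario.rangtp_volume_nm3), vcell
    )
    pairs = {}
    for label, kd_uM in zip(
        ("fg_periphery", "fg_channel", "fg_basket"), scenario.gradient.as_tuple()
    ):
        kd_per_nm3 = kd_uM * PER_NM3_PER_MOLAR * 1e-6
        pairs[label] = KineticPair(
            k_on_nm3_s=kon_nup,
            k_off_s=kd_per_nm3 * kon_nup,
            correction_factor=nc_fg,
            name=f"impb:{label}",
        )
    pairs["rangtp"] = KineticPair(
        k_on_nm3_s=kon_ran, k_off_s=0.0, correction_factor=nc_ran, name="impb:rangtp"
    )
    return pairs


def validate_scenario(scenario: NpcScenario, raise_on_error=True):
    """Eager timestep validation over every species and interaction."""
    geom = LatticeGeometry(cell_edge_nm=scenario.geometry.cell_edge_nm)
    diffusivities = {
        "impb": scenario.impb_diffusivity_um2_s,
        "rangtp": scenario.rangtp_diffusivity_um2_s,
        "fg_nup": scenario.fg_diffusivity_um2_s,
        "non_fg_nup": scenario.non_fg_diffusivity_um2_s,
    }
    for r in scenario.tracer_radii_nm:
        diffusivities[f"tracer_{r:g}nm"] = scenario.diffusivity(r)
    pairs = _kinetic_pairs(scenario, geom).values()
    return validate_timestep(diffusivities, pairs, scenario.dt_s, geom,
                             raise_on_error=raise_on_error)


def tracer_name(radius_nm: float) -> str:
    return f"tracer_{radius_nm:g}nm"


def build_simulation(scenario: NpcScenario, seed: int) -> tuple:
    """Build and populate a ready-to-run Simulation.

    Returns ``(sim, meta)`` where *meta* records the geometry audit, clamp
    targets and event probabilities for the run manifest.
    """
    report = validate_scenario(scenario)
    npc_geom = build_geometry(scenario.geometry)
    lat = npc_geom.lattice
    geom = LatticeGeometry(cell_edge_nm=lat.cell_edge_nm, n_cells=lat.n_cells)
    dt = scenario.dt_s
    pairs = _kinetic_pairs(scenario, geom)

    species = [
        Species("impb", move_probability(scenario.impb_diffusivity_um2_s, dt, geom),
                scenario.impb_volume_nm3,
                diffusivity_um2_s=scenario.impb_diffusivity_um2_s),
        Species("rangtp", move_probability(scenario.rangtp_diffusivity_um2_s, dt, geom),
                scenario.rangtp_volume_nm3,
                diffusivity_um2_s=scenario.rangtp_diffusivity_um2_s),
        Species("fg_periphery", move_probability(scenario.fg_diffusivity_um2_s, dt, geom),
                scenario.fg_volume_nm3, allowed_regions=(PERIPHERY,)),
        Species("fg_channel", move_probability(scenario.fg_diffusivity_um2_s, dt, geom),
                scenario.fg_volume_nm3, allowed_regions=(CHANNEL,)),
        Species("fg_basket", move_probability(scenario.fg_diffusivity_um2_s, dt, geom),
                scenario.fg_volume_nm3, allowed_regions=(BASKET,)),
        Species("non_fg", move_probability(scenario.non_fg_diffusivity_um2_s, dt, geom),
                scenario.non_fg_volume_nm3, allowed_regions=(CHANNEL,)),
    ]
    for r in scenario.tracer_radii_nm:
        species.append(
            Species(tracer_name(r), move_probability(scenario.diffusivity(r), dt, geom),
                    volume_from_radius(r), diffusivity_um2_s=scenario.diffusivity(r))
        )
    if scenario.include_labeled_impb:
        species.append(
            Species("impb_labeled",
                    move_probability(scenario.impb_diffusivity_um2_s, dt, geom),
                    scenario.impb_volume_nm3,
                    diffusivity_um2_s=scenario.impb_diffusivity_um2_s)
        )

    rules = []
    for fg_sp, label in (
        ("fg_periphery", "fg_periphery"),
        ("fg_channel", "fg_channel"),
        ("fg_basket", "fg_basket"),
    ):
        pair = pairs[label]
        rules.append(PairRule(
            species_a="impb", species_b=fg_sp,
            p_bind=bind_probability(pair, dt, geom),
            p_unbind=unbind_probability(pair.k_off_s, dt),
            displaceable=True,
            complex_mobile=scenario.bound_complex_mobile,
            name=pair.name,
        ))
    ran_pair = pairs["rangtp"]
    rules.append(PairRule(
        species_a="rangtp", species_b="impb",
        p_bind=bind_probability(ran_pair, dt, geom),
        p_unbind=0.0,
        displaces=True,  # RanGTP strips Impβ off FG-Nups
        complex_mobile=True,
        name=ran_pair.name,
    ))
    if scenario.include_labeled_impb:
        for fg_sp, label in (
            ("fg_periphery", "fg_periphery"),
            ("fg_channel", "fg_channel"),
            ("fg_basket", "fg_basket"),
        ):
            pair = pairs[label]
            rules.append(PairRule(
                species_a="impb_labeled", species_b=fg_sp,
                p_bind=bind_probability(pair, dt, geom),
                p_unbind=unbind_probability(pair.k_off_s, dt),
                displaceable=True,
                complex_mobile=scenario.bound_complex_mobile,
                name=pair.name + ":labeled",
            ))
        rules.append(PairRule(
            species_a="rangtp", species_b="impb_labeled",
            p_bind=bind_probability(ran_pair, dt, geom),
            p_unbind=0.0,
            displaces=True,
            complex_mobile=True,
            name="impb_labeled:rangtp",
        ))

    v_cyt = npc_geom.region_volume_nm3(CYTOPLASM)
    v_nuc = npc_geom.region_volume_nm3(NUCLEOPLASM)
    impb_target = int(round(scenario.impb_conc_uM * 1e-6 * PER_NM3_PER_MOLAR * v_cyt))
    ran_target = int(round(scenario.rangtp_conc_uM * 1e-6 * PER_NM3_PER_MOLAR * v_nuc))
    clamps = [
        Clamp("impb", CYTOPLASM, impb_target,
              eligible_cells=npc_geom.cells_far_from_pore(CYTOPLASM)),
        Clamp("rangtp", NUCLEOPLASM, ran_target,
              eligible_cells=npc_geom.cells_far_from_pore(NUCLEOPLASM)),
    ]
    sinks = [ComplexSink("impb", "rangtp", NUCLEOPLASM)]

    sim = Simulation(
        lat, species, rules, clamps, sinks,
        config=EngineConfig(dt_s=dt, bound_complex_mobile=True),
        capacity=8192, pair_capacity=32768,
    )
    sim.set_compartments(COMPARTMENT_OF_REGION)

    rng = np.random.default_rng(seed)
    # steric non-FG Nups first (they need empty cells), then FG Nups
    sim.add_agents("non_fg", n=scenario.non_fg_count, region=CHANNEL, rng=rng)
    for name, region, count in (
        ("fg_periphery", PERIPHERY, scenario.fg_counts[0]),
        ("fg_channel", CHANNEL, scenario.fg_counts[1]),
        ("fg_basket", BASKET, scenario.fg_counts[2]),
    ):
        sim.add_agents(name, n=count, region=region, rng=rng)
    sim.add_agents("impb", n=impb_target, region=CYTOPLASM, rng=rng)
    sim.add_agents("rangtp", n=ran_target, region=NUCLEOPLASM, rng=rng)

    meta = {
        "geometry_audit": npc_geom.audit,
        "impb_clamp_target": impb_target,
        "rangtp_clamp_target": ran_target,
        "timestep_report": report,
        "probabilities": {
            "p_move": {s.name: s.p_move for s in species},
            "p_bind": {r.name: r.p_bind for r in rules},
            "p_unbind": {r.name: r.p_unbind for r in rules},
        },
    }
    return sim, meta


def microinject(sim: Simulation, scenario: NpcScenario, species_name: str,
                conc_uM: float, region: int = CYTOPLASM, rng=None) -> int:
    """Add a labelled species uniformly through a compartment at a target
    concentration, without disturbing existing agents.  Returns the count."""
    v = sim.lattice.region_volume_nm3(region)
    count = int(round(conc_uM * 1e-6 * PER_NM3_PER_MOLAR * v))
    if count > 0:
        sim.add_agents(species_name, n=count, region=region, rng=rng)
    return count


def nuclear_concentration_uM(result, sim: Simulation, species_name: str) -> np.ndarray:
    """Bulk-nucleoplasm concentration time course (µM) from a RunResult."""
    s = result.species.index(species_name)
    v_nuc = sim.lattice.region_volume_nm3(NUCLEOPLASM)
    counts = result.counts[:, s, 1].astype(float)  # compartment 1 = nucleus
    return counts / v_nuc / (PER_NM3_PER_MOLAR * 1e-6)
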