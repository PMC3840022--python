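"""Discrete-time stochastic lattice engine: agents, crowding, reactions.

The engine advances an explicit population of molecular agents on a 3D
cubic lattice with the von Neumann (face-adjacent) neighbourhood:

* movement: each mobile agent attempts a move with its per-step probability
  toward one of the six directions chosen uniformly; the move is rejected if
  the target cell is inaccessible or disallowed for the species, rejected
  outright when the target's free volume cannot hold the mover (volume
  limit, VL), and otherwise accepted with probability equal to the target
  cell's free-volume fraction (reduced probability, RP).
* reactions: unbound agents of an interacting pair type that share a cell or
  sit in adjacent cells are candidate pairs; candidates bind with ``p_bind``
  and bound pairs dissociate with ``p_unbind``.  Agent order, candidate
  order and the order of bind/unbind passes over rule types are all
  re-randomised every step.
* clamping: optional per-region boundary conditions restore the free count
  of a species after the reaction phase, logging insertions and removals so
  conservation can be audited.

A single integer seed fully determines a trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernel

COMPARTMENTS = ("cytoplasm", "nucleus", "pore", "other")
TRANS_COLUMNS = ("pore_to_nucleus", "nucleus_to_pore", "pore_to_cytoplasm", "cytoplasm_to_pore")


class EngineInvariantError(RuntimeError):
    """An internal invariant was violated - an engine bug, never user error."""


@dataclass
class Lattice:
    """Discretised space: shape, per-cell region label and accessibility."""

    shape: tuple
    region: np.ndarray  # int64 (nx, ny, nz)
    accessible: np.ndarray | None = None
    cell_edge_nm: float = 5.0
    periodic: bool = False

    def __post_init__(self):
        self.region = np.ascontiguousarray(self.region, dtype=np.int64)
        if self.region.shape != tuple(self.shape):
            raise ValueError("region array shape does not match lattice shape")
        if self.accessible is None:
            self.accessible = np.ones(self.shape, dtype=bool)
        self.accessible = np.ascontiguousarray(self.accessible, dtype=bool)

    @classmethod
    def box(cls, shape, cell_edge_nm=5.0, periodic=True):
        """Uniform single-region box (well-mixed scenarios, free diffusion)."""
        return cls(
            shape=tuple(shape),
            region=np.zeros(shape, dtype=np.int64),
            cell_edge_nm=cell_edge_nm,
            periodic=periodic,
        )

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.shape))

    @property
    def n_regions(self) -> int:
        return int(self.region.max()) + 1

    @property
    def cell_volume_nm3(self) -> float:
        return self.cell_edge_nm**3

    def flat_region(self):
        return self.region.reshape(-1)

    def flat_accessible(self):
        return self.accessible.reshape(-1)

    def cells_in_region(self, label) -> np.ndarray:
        """Flat indices of accessible cells carrying a region label."""
        mask = (self.flat_region() == label) & self.flat_accessible()
        return np.flatnonzero(mask).astype(np.int64)

    def region_volume_nm3(self, label) -> float:
        return len(self.cells_in_region(label)) * self.cell_volume_nm3


@dataclass(frozen=True)
class Species:
    """One molecular species: mobility, excluded volume, allowed regions."""

    name: str
    p_move: float
    volume_nm3: float = 0.0
    allowed_regions: tuple | None = None  # None = anywhere accessible
    diffusivity_um2_s: float | None = None  # bookkeeping only

    def __post_init__(self):
        if not (0.0 <= self.p_move <= 1.0):
            raise ValueError(f"species {self.name!r}: p_move outside [0, 1]")
        if self.volume_nm3 < 0:
            raise ValueError(f"species {self.name!r}: negative volume")


@dataclass(frozen=True)
class PairRule:
    """Interaction between two species in per-step probability form.

    ``displaceable`` marks bonds this rule forms as breakable by a competing
    ``displaces`` rule (used for RanGTP stripping Impb off FG-Nups).
    ``complex_mobile`` controls whether the bound pair may diffuse as a unit.
    """

    species_a: str
    species_b: str
    p_bind: float
    p_unbind: float
    displaceable: bool = False
    displaces: bool = False
    complex_mobile: bool = True
    name: str = ""

    def __post_init__(self):
        for label in ("p_bind", "p_unbind"):
            p = getattr(self, label)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"rule {self.name or self.species_a}: {label} outside [0, 1]")


@dataclass(frozen=True)
class Clamp:
    """Hold the free count of a species in a region at a target value."""

    species: str
    region: int
    target_count: int
    eligible_cells: np.ndarray = None  # flat cell indices for insertions


@dataclass(frozen=True)
class ComplexSink:
    """Remove bound A-B complexes found inside a region (recycling)."""

    species_a: str
    species_b: str
    region: int


@dataclass
class EngineConfig:
    dt_s: float = 2.5e-6
    bound_complex_mobile: bool = True
    neighborhood: str = "von_neumann"
    record_stride: int = 0

    def __post_init__(self):
        if self.neighborhood != "von_neumann":
            raise ValueError("only the von Neumann neighbourhood is supported")


@dataclass
class RunResult:
    """Observer output of one run: counts and translocations vs time."""

    times_s: np.ndarray
    species: tuple
    counts: np.ndarray  # (nrec, n_species, 4 compartments)
    translocations: np.ndarray  # (nrec, n_species, 4 directions), cumulative
    seed: int

    def counts_df(self) -> pd.DataFrame:
        rows = []
        for r, t in enumerate(self.times_s):
            for s, name in enumerate(self.species):
                for c, comp in enumerate(COMPARTMENTS):
                    rows.append((r, t, name, comp, int(self.counts[r, s, c])))
        return pd.DataFrame(rows, columns=["record", "time_s", "species", "compartment", "count"])

    def net_import(self, species_index: int) -> np.ndarray:
        """Cumulative net entries into bulk nucleoplasm for one species."""
        tr = self.translocations[:, species_index, :]
        return tr[:, 0] - tr[:, 1]

    def net_export(self, species_index: int) -> np.ndarray:
        tr = self.translocations[:, species_index, :]
        return tr[:, 2] - tr[:, 3]


class Simulation:
    """Owns the lattice state and drives the numba kernels."""

    def __init__(
        self,
        lattice: Lattice,
        species,
        rules=(),
        clamps=(),
        sinks=(),
        config: EngineConfig | None = None,
        capacity: int = 16384,
        pair_capacity: int = 65536,
    ):
        self.lattice = lattice
        self.species = tuple(species)
        self.rules = tuple(rules)
        self.clamps = tuple(clamps)
        self.sinks = tuple(sinks)
        self.config = config or EngineConfig()
        self.capacity = int(capacity)
        self.pair_capacity = int(pair_capacity)
        self._sp_index = {s.name: i for i, s in enumerate(self.species)}
        if len(self._sp_index) != len(self.species):
            raise ValueError("duplicate species names")
        self._alloc()

    # ------------------------------------------------------------------ setup
    def _alloc(self):
        lat = self.lattice
        N = lat.n_cells
        S = len(self.species)
        R = lat.n_regions
        cap = self.capacity
        self.nx, self.ny, self.nz = (int(v) for v in lat.shape)
        self.region = lat.flat_region().copy()
        self.accessible = lat.flat_accessible().copy()
        self.occ = np.zeros(N, dtype=np.float64)
        self.comp_of_region = np.full(R, 3, dtype=np.int64)

        self.s_pmove = np.array([s.p_move for s in self.species], dtype=np.float64)
        self.s_vol = np.array([s.volume_nm3 for s in self.species], dtype=np.float64)
        self.s_allowed = np.zeros((S, R), dtype=bool)
        for i, s in enumerate(self.species):
            if s.allowed_regions is None:
                self.s_allowed[i, :] = True
            else:
                for r in s.allowed_regions:
                    self.s_allowed[i, int(r)] = True

        P = max(len(self.rules), 1)
        self.r_a = np.zeros(P, dtype=np.int64)
        self.r_b = np.zeros(P, dtype=np.int64)
        self.r_pbind = np.zeros(P, dtype=np.float64)
        self.r_punbind = np.zeros(P, dtype=np.float64)
        self.r_same = np.zeros(P, dtype=bool)
        self.r_disp = np.zeros(P, dtype=bool)
        self.r_displaceable = np.zeros(P, dtype=bool)
        self.r_cmob = np.zeros(P, dtype=bool)
        for p, rule in enumerate(self.rules):
            self.r_a[p] = self._sp_index[rule.species_a]
            self.r_b[p] = self._sp_index[rule.species_b]
            self.r_pbind[p] = rule.p_bind
            self.r_punbind[p] = rule.p_unbind
            self.r_same[p] = rule.species_a == rule.species_b
            self.r_disp[p] = rule.displaces
            self.r_displaceable[p] = rule.displaceable
            self.r_cmob[p] = rule.complex_mobile

        C = max(len(self.clamps), 1)
        self.c_sp = np.zeros(C, dtype=np.int64)
        self.c_reg = np.zeros(C, dtype=np.int64)
        self.c_target = np.zeros(C, dtype=np.int64)
        cells_list = []
        offs = [0]
        for c, clamp in enumerate(self.clamps):
            self.c_sp[c] = self._sp_index[clamp.species]
            self.c_reg[c] = int(clamp.region)
            self.c_target[c] = int(clamp.target_count)
            elig = clamp.eligible_cells
            if elig is None:
                elig = self.lattice.cells_in_region(clamp.region)
            cells_list.append(np.asarray(elig, dtype=np.int64))
            offs.append(offs[-1] + len(cells_list[-1]))
        self.c_cells = (
            np.concatenate(cells_list) if cells_list else np.zeros(0, dtype=np.int64)
        )
        self.c_off = np.array(offs + [offs[-1]] * (C + 1 - len(offs)), dtype=np.int64)[: C + 1]
        self.c_ins = np.zeros(C, dtype=np.int64)
        self.c_rem = np.zeros(C, dtype=np.int64)

        K = max(len(self.sinks), 1)
        self.snk_a = np.zeros(K, dtype=np.int64)
        self.snk_b = np.zeros(K, dtype=np.int64)
        self.snk_reg = np.zeros(K, dtype=np.int64)
        self.snk_rem = np.zeros(K, dtype=np.int64)
        for k, sink in enumerate(self.sinks):
            self.snk_a[k] = self._sp_index[sink.species_a]
            self.snk_b[k] = self._sp_index[sink.species_b]
            self.snk_reg[k] = int(sink.region)

        self.apos = np.zeros((cap, 3), dtype=np.int64)
        self.acell = np.zeros(cap, dtype=np.int64)
        self.asp = np.zeros(cap, dtype=np.int64)
        self.apart = np.full(cap, -1, dtype=np.int64)
        self.abrule = np.full(cap, -1, dtype=np.int64)
        self.acomp = np.zeros(cap, dtype=np.int64)
        self.aalive = np.zeros(cap, dtype=bool)

        self.cell_head = np.full(N, -1, dtype=np.int64)
        self.cnext = np.full(cap, -1, dtype=np.int64)
        self.cprev = np.full(cap, -1, dtype=np.int64)
        self.sp_head = np.full(S, -1, dtype=np.int64)
        self.snext = np.full(cap, -1, dtype=np.int64)
        self.sprev = np.full(cap, -1, dtype=np.int64)

        # counters[0] = free-stack top, counters[1] = n_alive
        self.free_stack = np.arange(cap - 1, -1, -1, dtype=np.int64)
        self.counters = np.array([cap, 0], dtype=np.int64)
        self.alive_list = np.zeros(cap, dtype=np.int64)
        self.alive_pos = np.zeros(cap, dtype=np.int64)
        self.trans = np.zeros((S, 4), dtype=np.int64)

        self._order = np.zeros(cap, dtype=np.int64)
        self._moved = np.zeros(cap, dtype=bool)
        self._pair_a = np.zeros(self.pair_capacity, dtype=np.int64)
        self._pair_b = np.zeros(self.pair_capacity, dtype=np.int64)
        self._evorder = np.zeros(max(2 * P, 1), dtype=np.int64)
        self._scratch = np.zeros(cap, dtype=np.int64)
        self._steps_done = 0

    # -------------------------------------------------------------- utilities
    def species_index(self, name: str) -> int:
        return self._sp_index[name]

    def set_compartments(self, comp_of_region):
        """Map region label -> compartment id (0 cyt, 1 nuc, 2 pore, 3 other)."""
        arr = np.asarray(comp_of_region, dtype=np.int64)
        if arr.shape != self.comp_of_region.shape:
            raise ValueError("compartment map length must equal n_regions")
        self.comp_of_region = arr.copy()
        # refresh cached compartments of live agents
        alive = np.flatnonzero(self.aalive)
        self.acomp[alive] = self.comp_of_region[self.region[self.acell[alive]]]

    @property
    def n_agents(self) -> int:
        return int(self.counters[1])

    def add_agents(self, species_name, n=None, cells=None, region=None, rng=None):
        """Place agents at given flat cells, or uniformly at random in a region
        (or anywhere accessible), honouring the volume limit."""
        sp = self._sp_index[species_name]
        vol = self.s_vol[sp]
        cell_vol = self.lattice.cell_volume_nm3
        if rng is None or isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(rng)
        ids = []
        if cells is not None:
            for c in np.asarray(cells, dtype=np.int64):
                if not self.accessible[c]:
                    raise ValueError(f"cell {c} is inaccessible")
                if vol > cell_vol - self.occ[c] + 1e-9:
                    raise EngineInvariantError(
                        f"overcrowding: cell {c} cannot hold {species_name}"
                    )
                ids.append(self._spawn_py(sp, int(c)))
        else:
            if n is None:
                raise ValueError("give either explicit cells or a count n")
            if region is not None:
                candidates = self.lattice.cells_in_region(region)
            else:
                candidates = np.flatnonzero(self.accessible).astype(np.int64)
            if self.species[sp].allowed_regions is not None:
                ok = np.isin(self.region[candidates], np.array(self.species[sp].allowed_regions))
                candidates = candidates[ok]
            if len(candidates) == 0 and n > 0:
                raise EngineInvariantError(f"no accessible cells for {species_name}")
            for i in range(n):
                for _ in range(10000):
                    c = int(candidates[rng.integers(len(candidates))])
                    if vol <= cell_vol - self.occ[c] + 1e-9:
                        ids.append(self._spawn_py(sp, c))
                        break
                else:
                    raise EngineInvariantError(
                        f"overcrowding: cannot place {species_name} agent "
                        f"{i + 1}/{n}; region volume exhausted"
                    )
        return np.array(ids, dtype=np.int64)

    def _spawn_py(self, sp, cell):
        if self.counters[0] <= 0:
            raise EngineInvariantError("agent capacity exhausted")
        self.counters[0] -= 1
        i = int(self.free_stack[self.counters[0]])
        x, rem = divmod(cell, self.ny * self.nz)
        y, z = divmod(rem, self.nz)
        self.apos[i] = (x, y, z)
        self.acell[i] = cell
        self.asp[i] = sp
        self.apart[i] = -1
        self.abrule[i] = -1
        self.acomp[i] = self.comp_of_region[self.region[cell]]
        self.aalive[i] = True
        self.occ[cell] += self.s_vol[sp]
        _kernel._ll_insert.py_func(i, cell, self.cell_head, self.cnext, self.cprev)
        _kernel._sp_insert.py_func(i, sp, self.sp_head, self.snext, self.sprev)
        self.alive_list[self.counters[1]] = i
        self.alive_pos[i] = self.counters[1]
        self.counters[1] += 1
        return i

    # ------------------------------------------------------------------- runs
    def run(self, n_steps, seed, record_stride=None) -> RunResult:
        """Advance *n_steps*; identical seed and state give identical output."""
        if n_steps < 0:
            raise ValueError("n_steps must be non-negative")
        stride = record_stride if record_stride is not None else self.config.record_stride
        if stride is None or stride <= 0:
            stride = max(n_steps, 1)
        nrec = (n_steps // stride) + 1
        S = len(self.species)
        rec_counts = np.zeros((nrec, S, 4), dtype=np.int64)
        rec_trans = np.zeros((nrec, S, 4), dtype=np.int64)
        _kernel._record.py_func(0, self.capacity, S, self.asp, self.acomp,
                                self.aalive, self.trans, rec_counts, rec_trans)
        rng_state = _kernel.make_rng_state(int(seed))
        if n_steps > 0:
            err, _ = _kernel.run_kernel(
                rng_state, n_steps, stride, 1,
                self.capacity, self.pair_capacity, S, len(self.rules),
                len(self.clamps), len(self.sinks),
                self.nx, self.ny, self.nz, self.lattice.periodic,
                self.lattice.cell_volume_nm3, self.config.bound_complex_mobile,
                self.apos, self.acell, self.asp, self.apart, self.abrule,
                self.acomp, self.aalive,
                self.occ, self.region, self.accessible, self.comp_of_region,
                self.s_pmove, self.s_vol, self.s_allowed,
                self.r_a, self.r_b, self.r_pbind, self.r_punbind, self.r_same,
                self.r_disp, self.r_displaceable, self.r_cmob,
                self.cell_head, self.cnext, self.cprev,
                self.sp_head, self.snext, self.sprev,
                self.free_stack, self.counters, self.alive_list,
                self.alive_pos, self.trans,
                self.c_sp, self.c_reg, self.c_target, self.c_off, self.c_cells,
                self.c_ins, self.c_rem,
                self.snk_a, self.snk_b, self.snk_reg, self.snk_rem,
                self._order, self._moved, self._pair_a, self._pair_b,
                self._evorder, self._scratch,
                rec_counts, rec_trans,
            )
            if err == _kernel.ERR_PAIR_OVERFLOW:
                raise EngineInvariantError("reaction candidate buffer overflow; raise pair_capacity")
            if err == _kernel.ERR_CAPACITY:
                raise EngineInvariantError("agent capacity exhausted during clamping")
        times = np.arange(nrec, dtype=np.float64) * stride * self.config.dt_s
        times += self._steps_done * self.config.dt_s
        self._steps_done += n_steps
        return RunResult(
            times_s=times,
            species=tuple(s.name for s in self.species),
            counts=rec_counts,
            translocations=rec_trans,
            seed=int(seed),
        )

    def step(self, seed=None):
        """Advance exactly one timestep (seeds the stream first if given)."""
        if seed is not None:
            return self.run(1, seed)
        return self.run(1, np.random.randint(2**31))

    # -------------------------------------------------------------- observers
    def positions(self, species_name=None) -> np.ndarray:
        """Unwrapped (x, y, z) integer coordinates of live agents."""
        alive = np.flatnonzero(self.aalive)
        if species_name is not None:
            alive = alive[self.asp[alive] == self._sp_index[species_name]]
        return self.apos[alive].copy()

    def agent_ids(self, species_name=None) -> np.ndarray:
        alive = np.flatnonzero(self.aalive)
        if species_name is not None:
            alive = alive[self.asp[alive] == self._sp_index[species_name]]
        return alive

    def counts_by_region(self, species_name) -> dict:
        sp = self._sp_index[species_name]
        alive = self.agent_ids(species_name)
        regs = self.region[self.acell[alive]]
        return {int(r): int(n) for r, n in zip(*np.unique(regs, return_counts=True))}

    def free_count(self, species_name, region=None) -> int:
        alive = self.agent_ids(species_name)
        free = alive[self.apart[alive] < 0]
        if region is not None:
            free = free[self.region[self.acell[free]] == int(region)]
        return len(free)

    def translocation_totals(self, species_name) -> dict:
        sp = self._sp_index[species_name]
        return {k: int(v) for k, v in zip(TRANS_COLUMNS, self.trans[sp])}

    def clamp_ledger(self) -> pd.DataFrame:
        rows = []
        for c, clamp in enumerate(self.clamps):
            rows.append(
                (clamp.species, clamp.region, int(self.c_target[c]),
                 int(self.c_ins[c]), int(self.c_rem[c]))
            )
        return pd.DataFrame(rows, columns=["species", "region", "target", "inserted", "removed"])

    def reaction_candidates(self, rule_index: int):
        """Enumerate current candidate pairs for one rule (unshuffled).

        Mirrors the kernel's enumeration: unbound partners in the same or
        von-Neumann-adjacent cells, each unordered pair exactly once."""
        rule = self.rules[rule_index]
        a_sp = self._sp_index[rule.species_a]
        b_sp = self._sp_index[rule.species_b]
        same = a_sp == b_sp
        out = []
        for a in self.agent_ids():
            if self.asp[a] != a_sp or self.apart[a] >= 0:
                continue
            x, y, z = self.apos[a]
            neigh_cells = [int(self.acell[a])]
            for k in range(6):
                ok, _, _, _, c = _kernel._neighbor_coords.py_func(
                    int(x), int(y), int(z), k, self.nx, self.ny, self.nz,
                    self.lattice.periodic)
                if ok:
                    neigh_cells.append(int(c))
            for c in neigh_cells:
                b = int(self.cell_head[c])
                while b >= 0:
                    if b != a and self.asp[b] == b_sp:
                        free_b = self.apart[b] < 0
                        displaceable = (
                            rule.displaces and self.apart[b] >= 0
                            and self.rules[self.abrule[b]].displaceable
                        )
                        if (free_b or displaceable) and ((not same) or b > a):
                            out.append((int(a), int(b)))
                    b = int(self.cnext[b])
        return out

    # --------------------------------------------------------------- auditing
    def check_invariants(self):
        """Panic if internal state is inconsistent (occupancy, bonds, regions)."""
        cell_vol = self.lattice.cell_volume_nm3
        alive = np.flatnonzero(self.aalive)
        occ = np.zeros_like(self.occ)
        np.add.at(occ, self.acell[alive], self.s_vol[self.asp[alive]])
        if not np.allclose(occ, self.occ, atol=1e-6):
            raise EngineInvariantError("occupancy ledger out of sync with agents")
        if np.any(occ > cell_vol + 1e-6):
            raise EngineInvariantError("cell volume exceeded")
        for i in alive:
            j = self.apart[i]
            if j >= 0:
                if not self.aalive[j] or self.apart[j] != i:
                    raise EngineInvariantError("asymmetric bond")
                d = np.abs(self.apos[i] - self.apos[j]).sum()
                if d > 1:
                    raise EngineInvariantError("bound pair neither co-located nor adjacent")
            if not self.accessible[self.acell[i]]:
                raise EngineInvariantError("agent in inaccessible cell")
            if not self.s_allowed[self.asp[i], self.region[self.acell[i]]]:
                raise EngineInvariantError("agent outside its allowed regions")
        return True
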