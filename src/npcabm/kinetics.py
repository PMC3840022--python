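"""Mapping physical parameters to per-timestep event probabilities.

The lattice engine is driven entirely by three probabilities per timestep:

* ``p_move``  — probability that a free agent attempts a lattice move,
  chosen so that an unbiased random walk on a cubic lattice reproduces the
  species' diffusion coefficient: ``p_move = 2 d D dt / dx^2`` with ``d = 3``
  spatial dimensions (the attempted direction is then uniform over the
  ``q = 2d`` von Neumann neighbours).
* ``p_unbind`` — probability that a bound pair dissociates, the small-dt
  limit of first-order decay: ``p_unbind = k_off * dt``.
* ``p_bind``  — probability that a *candidate* pair (two unbound partners in
  the same or face-adjacent cells) associates.  Equating the expected number
  of binding events per step, ``P_bind * N_A N_B (q + n_c) / N_cells``, with
  the mass-action increment ``k_on N_A N_B dt / V_system`` gives
  ``p_bind = k_on dt / ((q + n_c) V_cell)`` with ``k_on`` in nm^3/s per
  molecule pair.  ``n_c`` is the effective extra neighbour contributed by
  in-cell co-occupancy of two molecules small enough to share a cell.

Any probability that exceeds one is a hard error naming the largest
admissible timestep — never a silent clamp, which would quietly change the
kinetics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .units import Quantity, parse_quantity

__all__ = [
    "LatticeGeometry",
    "KineticPair",
    "EventProbabilities",
    "TimestepOverflowError",
    "TimestepReport",
    "move_probability",
    "unbind_probability",
    "bind_probability",
    "neighbor_correction",
    "validate_timestep",
]


class TimestepOverflowError(ValueError):
    """An event probability formula yielded a value above one.

    Carries ``max_dt``, the largest timestep for which the offending
    probability stays at or below one.
    """

    def __init__(self, message: str, max_dt: float | None = None):
        super().__init__(message)
        self.max_dt = max_dt


@dataclass(frozen=True)
class LatticeGeometry:
    """Cubic-lattice discretisation: cell edge, cell count, coordination."""

    cell_edge_nm: float
    n_cells: int = 1
    n_neighbors: int = 6

    def __post_init__(self):
        if self.cell_edge_nm <= 0:
            raise ValueError("cell_edge_nm must be positive")
        if self.n_neighbors != 6:
            raise ValueError("only the 3D von Neumann neighbourhood (q=6) is supported")

    @property
    def cell_volume_nm3(self) -> float:
        return self.cell_edge_nm**3

    @property
    def dimensions(self) -> int:
        return self.n_neighbors // 2


@dataclass(frozen=True)
class KineticPair:
    """Pairwise kinetics between two species, in internal units.

    ``k_on`` is stored as nm^3 s^-1 per molecule pair; build instances from
    tagged laboratory units with :meth:`from_quantities`.
    """

    k_on_nm3_s: float
    k_off_s: float
    same_species: bool = False
    correction_factor: float = 0.0
    name: str = ""

    def __post_init__(self):
        if self.k_on_nm3_s < 0 or self.k_off_s < 0:
            raise ValueError("rate constants must be non-negative")
        if self.correction_factor < 0:
            raise ValueError("neighbour correction must be non-negative")

    @property
    def K_D_per_nm3(self) -> float:
        """Dissociation constant in molecules/nm^3 (k_off / k_on)."""
        if self.k_on_nm3_s == 0:
            return math.inf
        return self.k_off_s / self.k_on_nm3_s

    @classmethod
    def from_quantities(
        cls,
        k_on,
        k_off=None,
        K_D=None,
        same_species: bool = False,
        correction_factor: float = 0.0,
        name: str = "",
        rtol: float = 1e-9,
    ) -> "KineticPair":
        """Build from unit-tagged k_on plus k_off and/or K_D.

        If all three are supplied they must satisfy K_D = k_off/k_on to
        relative tolerance *rtol*.
        """
        kon = parse_quantity(k_on, "kon").internal
        koff = None if k_off is None else parse_quantity(k_off, "rate").internal
        kd = None if K_D is None else parse_quantity(K_D, "concentration").internal
        if koff is None and kd is None:
            raise ValueError(f"pair {name!r}: need k_off or K_D alongside k_on")
        if koff is None:
            koff = kd * kon
        elif kd is not None:
            implied = koff / kon if kon > 0 else math.inf
            if not math.isclose(implied, kd, rel_tol=rtol):
                raise ValueError(
                    f"pair {name!r}: K_D inconsistent with k_off/k_on "
                    f"(given {kd:.6g}, implied {implied:.6g} molecules/nm^3)"
                )
        return cls(kon, koff, same_species, correction_factor, name)


@dataclass(frozen=True)
class EventProbabilities:
    """Per-timestep probabilities; construction rejects values outside [0, 1]."""

    p_move: float = 0.0
    p_bind: float = 0.0
    p_unbind: float = 0.0

    def __post_init__(self):
        for label in ("p_move", "p_bind", "p_unbind"):
            p = getattr(self, label)
            if not (0.0 <= p <= 1.0):
                raise TimestepOverflowError(f"{label} = {p:.6g} outside [0, 1]")


def move_probability(D_um2_s: float, dt_s: float, geometry: LatticeGeometry) -> float:
    """Per-step move-attempt probability for diffusivity *D* (µm²/s).

    ``p = 2 d D dt / dx^2`` with d the spatial dimension; the ensemble MSD of
    free walkers then equals ``6 D t`` on a cubic lattice.
    """
    if D_um2_s < 0:
        raise ValueError("diffusion coefficient must be non-negative")
    if dt_s <= 0:
        raise ValueError("timestep must be positive")
    D_nm2 = D_um2_s * 1e6
    d = geometry.dimensions
    p = 2.0 * d * D_nm2 * dt_s / geometry.cell_edge_nm**2
    if p > 1.0:
        max_dt = geometry.cell_edge_nm**2 / (2.0 * d * D_nm2)
        raise TimestepOverflowError(
            f"p_move = {p:.4g} > 1 for D = {D_um2_s} um^2/s; "
            f"largest admissible dt is {max_dt:.4g} s",
            max_dt=max_dt,
        )
    return p


def unbind_probability(k_off_s: float, dt_s: float) -> float:
    """Per-step dissociation probability, ``k_off * dt`` (small-dt limit)."""
    if k_off_s < 0:
        raise ValueError("k_off must be non-negative")
    if dt_s <= 0:
        raise ValueError("timestep must be positive")
    p = k_off_s * dt_s
    if p > 1.0:
        raise TimestepOverflowError(
            f"p_unbind = k_off*dt = {p:.4g} > 1; "
            f"largest admissible dt is {1.0 / k_off_s:.4g} s",
            max_dt=1.0 / k_off_s,
        )
    return p


def unbind_probability_exact(k_off_s: float, dt_s: float) -> float:
    """Exponential-form alternative ``1 - exp(-k_off dt)``, robust at large dt."""
    if k_off_s < 0:
        raise ValueError("k_off must be non-negative")
    return -math.expm1(-k_off_s * dt_s)


def neighbor_correction(volumes_of_pair, cell_volume_nm3: float) -> float:
    """Effective extra neighbour count n_c from in-cell co-occupancy.

    Two molecules that fit in one cell together can also bind from the same
    lattice element, adding to the q face-adjacent channels.  Under the
    RP+VL move rule the stationary in-cell encounter frequency, relative to a
    single neighbour-cell channel, is the mean free-volume acceptance of the
    two partners:

        n_c = (f_A + f_B) / 2 = 1 - (V_A + V_B) / (2 V_cell),   f_i = 1 - V_i/V_cell

    and zero when the pair cannot co-occupy a cell (sum of volumes above the
    cell volume).  Point-like molecules give the maximal value n_c = 1.  The
    Monte-Carlo encounter oracle in the test suite is the source of truth for
    this form.
    """
    vols = list(volumes_of_pair)
    if len(vols) != 2:
        raise ValueError("neighbor_correction expects exactly two molecular volumes")
    if any(v < 0 for v in vols):
        raise ValueError("molecular volumes must be non-negative")
    if cell_volume_nm3 <= 0:
        raise ValueError("cell volume must be positive")
    total = sum(vols)
    if total > cell_volume_nm3:
        return 0.0
    return max(0.0, 1.0 - total / (2.0 * cell_volume_nm3))


def bind_probability(
    pair: KineticPair, dt_s: float, geometry: LatticeGeometry
) -> float:
    """Per-candidate-pair association probability.

    ``p_bind = k_on dt / ((q + n_c) V_cell)``, halved for two molecules of
    the same species (each unordered pair is a single candidate, and the
    factor of two in the same-species mass-action rate is carried by the
    pair count N(N-1)/2).
    """
    if dt_s <= 0:
        raise ValueError("timestep must be positive")
    q = geometry.n_neighbors
    denom = (q + pair.correction_factor) * geometry.cell_volume_nm3
    p = pair.k_on_nm3_s * dt_s / denom
    if pair.same_species:
        p *= 0.5
    if p > 1.0:
        max_dt = dt_s / p
        raise TimestepOverflowError(
            f"p_bind = {p:.4g} > 1 for pair {pair.name!r}; "
            f"largest admissible dt is {max_dt:.4g} s",
            max_dt=max_dt,
        )
    return p


@dataclass
class TimestepReport:
    """Outcome of validating one timestep against a full parameter set."""

    dt_s: float
    move: dict = field(default_factory=dict)  # species -> p_move
    bind: dict = field(default_factory=dict)  # pair name -> p_bind
    unbind: dict = field(default_factory=dict)  # pair name -> p_unbind
    violations: list = field(default_factory=list)  # (event, name, message, max_dt)

    @property
    def ok(self) -> bool:
        return not self.violations

    @property
    def max_admissible_dt(self) -> float:
        dts = [v[3] for v in self.violations if v[3] is not None]
        return min(dts) if dts else self.dt_s

    def raise_if_invalid(self):
        if self.violations:
            lines = [f"timestep dt = {self.dt_s:g} s is too large:"]
            lines += [f"  {ev} ({name}): {msg}" for ev, name, msg, _ in self.violations]
            lines.append(f"largest admissible dt = {self.max_admissible_dt:.4g} s")
            raise TimestepOverflowError("\n".join(lines), max_dt=self.max_admissible_dt)


def validate_timestep(
    diffusivities_um2_s: dict,
    pairs,
    dt_s: float,
    geometry: LatticeGeometry,
    raise_on_error: bool = False,
) -> TimestepReport:
    """Check every move/bind/unbind probability of a scenario against one dt.

    *diffusivities_um2_s* maps species name -> D; *pairs* is an iterable of
    :class:`KineticPair`.  Returns a report listing each probability and every
    violation (with the per-event maximum admissible dt).
    """
    report = TimestepReport(dt_s=dt_s)
    for name, D in diffusivities_um2_s.items():
        try:
            report.move[name] = move_probability(D, dt_s, geometry)
        except TimestepOverflowError as exc:
            report.violations.append(("move", name, str(exc), exc.max_dt))
    for pair in pairs:
        label = pair.name or f"{pair.k_on_nm3_s:g}nm3/s"
        try:
            report.bind[label] = bind_probability(pair, dt_s, geometry)
        except TimestepOverflowError as exc:
            report.violations.append(("bind", label, str(exc), exc.max_dt))
        try:
            report.unbind[label] = unbind_probability(pair.k_off_s, dt_s)
        except TimestepOverflowError as exc:
            report.violations.append(("unbind", label, str(exc), exc.max_dt))
    if raise_on_error:
        report.raise_if_invalid()
    return report
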