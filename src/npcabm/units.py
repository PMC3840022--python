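"""Unit-tagged quantities and conversion to the internal unit system.

Everything inside the package is expressed in nanometres, seconds and
molecule counts.  Concentrations are molecules/nm^3, diffusivities nm^2/s,
second-order on-rates nm^3/s (per molecule pair).  Configuration files carry
explicit unit tags; an unknown or dimensionally wrong tag is a hard error,
never a silent default.
"""

from __future__ import annotations

from dataclasses import dataclass

AVOGADRO = 6.02214076e23

#: molecules/nm^3 per mol/L
PER_NM3_PER_MOLAR = AVOGADRO / 1e24


class UnitError(ValueError):
    """Raised for unknown units or a unit of the wrong dimension."""


def _aliases(*names):
    return tuple(names)


# unit tag -> (kind, factor to internal units)
_UNIT_TABLE: dict[str, tuple[str, float]] = {}


def _register(kind: str, factor: float, *tags: str) -> None:
    for t in tags:
        _UNIT_TABLE[t] = (kind, factor)


_register("length", 1.0, "nm")
_register("length", 1e3, "um", "µm")
_register("time", 1.0, "s", "sec")
_register("time", 1e-3, "ms")
_register("time", 1e-6, "us", "µs")
_register("volume", 1.0, "nm3", "nm^3")
_register("concentration", PER_NM3_PER_MOLAR, "M", "mol/L")
_register("concentration", PER_NM3_PER_MOLAR * 1e-3, "mM")
_register("concentration", PER_NM3_PER_MOLAR * 1e-6, "uM", "µM")
_register("concentration", PER_NM3_PER_MOLAR * 1e-9, "nM")
_register("diffusivity", 1e6, "um2/s", "µm2/s", "um^2/s", "µm^2/s")
_register("diffusivity", 1.0, "nm2/s", "nm^2/s")
# second-order on-rate: 1 M^-1 s^-1 == 1e24/N_A nm^3/s
_register("kon", 1e24 / AVOGADRO, "1/M/s", "M-1s-1", "/M/s")
_register("kon", 1e30 / AVOGADRO, "1/uM/s", "uM-1s-1", "1/µM/s", "µM-1s-1")
_register("kon", 1.0, "nm3/s", "nm^3/s")
_register("rate", 1.0, "1/s", "s-1", "/s")


@dataclass(frozen=True)
class Quantity:
    """A magnitude with an explicit unit tag."""

    magnitude: float
    unit: str

    @property
    def kind(self) -> str:
        try:
            return _UNIT_TABLE[self.unit][0]
        except KeyError:
            raise UnitError(f"unknown unit {self.unit!r}") from None

    @property
    def internal(self) -> float:
        """Value in internal units (nm / s / molecules)."""
        return self.magnitude * _UNIT_TABLE[self.unit][1]

    def to_internal(self, kind: str) -> float:
        if self.kind != kind:
            raise UnitError(
                f"expected a {kind} but got {self.magnitude} {self.unit!r} "
                f"({self.kind})"
            )
        return self.internal

    def to(self, unit: str) -> "Quantity":
        """Convert to another unit of the same dimension.

        The factor is the exact ratio of table entries, so converting a
        quantity to its own unit is the identity (bit-exact round trips)."""
        try:
            kind_t, factor_t = _UNIT_TABLE[unit]
        except KeyError:
            raise UnitError(f"unknown unit {unit!r}") from None
        if self.kind != kind_t:
            raise UnitError(f"cannot convert {self.unit} ({self.kind}) to {unit}")
        return Quantity(self.magnitude * (_UNIT_TABLE[self.unit][1] / factor_t), unit)


def parse_quantity(value, kind: str | None = None) -> Quantity:
    """Parse ``"2.5 uM"``, ``{"value": 2.5, "unit": "uM"}`` or a Quantity.

    If *kind* is given the quantity's dimension is checked against it.
    """
    if isinstance(value, Quantity):
        q = value
    elif isinstance(value, str):
        parts = value.split()
        if len(parts) != 2:
            raise UnitError(f"cannot parse quantity {value!r}; expected 'MAGNITUDE UNIT'")
        try:
            mag = float(parts[0])
        except ValueError:
            raise UnitError(f"bad magnitude in {value!r}") from None
        q = Quantity(mag, parts[1])
    elif isinstance(value, dict):
        try:
            q = Quantity(float(value["value"]), str(value["unit"]))
        except KeyError as exc:
            raise UnitError(f"quantity mapping {value!r} missing {exc}") from None
    else:
        raise UnitError(
            f"bare number {value!r} has no unit tag; write e.g. '2.5 uM'"
        )
    if q.unit not in _UNIT_TABLE:
        raise UnitError(f"unknown unit {q.unit!r}")
    if kind is not None:
        q.to_internal(kind)  # raises on dimension mismatch
    return q


def concentration_to_count(conc_per_nm3: float, volume_nm3: float) -> int:
    """Integer molecule count for a concentration in a given volume."""
    return int(round(conc_per_nm3 * volume_nm3))


def count_to_concentration_uM(count: float, volume_nm3: float) -> float:
    """Convert a molecule count in a volume to micromolar."""
    return count / volume_nm3 / (PER_NM3_PER_MOLAR * 1e-6)
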