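"""Configuration files, canonical fixtures and run manifests.

Configs are YAML with explicit unit tags on every dimensioned quantity
(mapping form ``{value: 2.5, unit: uM}`` or string form ``"2.5 uM"``).
Loading normalises everything to internal units (nm, s, molecules), checks
K_D / k_off / k_on consistency where redundant values are supplied, and runs
eager timestep validation so a configuration that cannot be simulated at its
stated dt fails at load time with the offending key named.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .kinetics import KineticPair
from .npc import (
    GRADIENT_PRESETS,
    AffinityGradient,
    DEFAULT_TRACER_RADII,
    NpcScenario,
    validate_scenario,
)
from .units import PER_NM3_PER_MOLAR, UnitError, parse_quantity

FIXTURE_NAMES = ("uniform_KD", "yeast", "vertebrate", "optimum", "ode_box", "tracer_panel")


class ConfigError(ValueError):
    pass


def _q(value, unit):
    return {"value": float(value), "unit": unit}


def _get_quantity(mapping, key, kind):
    try:
        raw = mapping[key]
    except KeyError:
        raise ConfigError(f"missing config key {key!r}") from None
    try:
        return parse_quantity(raw, kind).to_internal(kind)
    except UnitError as exc:
        raise ConfigError(f"config key {key!r}: {exc}") from exc


def scenario_to_config(scenario: NpcScenario, label: str = "npc") -> dict:
    """Serialise an NpcScenario into the unit-tagged mapping form."""
    g = scenario.gradient
    return {
        "kind": "npc",
        "label": label,
        "engine": {
            "dt": _q(scenario.dt_s, "s"),
            "bound_complex_mobile": bool(scenario.bound_complex_mobile),
        },
        "gradient": {
            "cytoplasmic_periphery": _q(g.periphery_uM, "uM"),
            "central_channel": _q(g.channel_uM, "uM"),
            "nuclear_basket": _q(g.basket_uM, "uM"),
        },
        "kinetics": {
            "nup_impb_kon": _q(scenario.nup_impb_kon[0], scenario.nup_impb_kon[1]),
            "impb_rangtp_kon": _q(scenario.impb_rangtp_kon[0], scenario.impb_rangtp_kon[1]),
        },
        "concentrations": {
            "impb_cytoplasm": _q(scenario.impb_conc_uM, "uM"),
            "rangtp_nucleoplasm": _q(scenario.rangtp_conc_uM, "uM"),
        },
        "species": {
            "impb": {"volume": _q(scenario.impb_volume_nm3, "nm3"),
                     "diffusivity": _q(scenario.impb_diffusivity_um2_s, "um2/s")},
            "rangtp": {"volume": _q(scenario.rangtp_volume_nm3, "nm3"),
                       "diffusivity": _q(scenario.rangtp_diffusivity_um2_s, "um2/s")},
            "fg_nup": {"volume": _q(scenario.fg_volume_nm3, "nm3"),
                       "diffusivity": _q(scenario.fg_diffusivity_um2_s, "um2/s"),
                       "counts": list(scenario.fg_counts)},
            "non_fg_nup": {"volume": _q(scenario.non_fg_volume_nm3, "nm3"),
                           "diffusivity": _q(scenario.non_fg_diffusivity_um2_s, "um2/s"),
                           "count": int(scenario.non_fg_count)},
        },
        "tracers": {"stokes_radii": [_q(r, "nm") for r in scenario.tracer_radii_nm]},
        "include_labeled_impb": bool(scenario.include_labeled_impb),
    }


def config_to_scenario(cfg: dict) -> NpcScenario:
    """Parse and validate a unit-tagged NPC configuration mapping."""
    if cfg.get("kind") != "npc":
        raise ConfigError(f"expected kind 'npc', got {cfg.get('kind')!r}")
    eng = cfg.get("engine", {})
    dt = _get_quantity(eng, "dt", "time")
    grad_cfg = cfg.get("gradient", {})
    kd = {}
    for key in ("cytoplasmic_periphery", "central_channel", "nuclear_basket"):
        if key not in grad_cfg:
            raise ConfigError(f"missing config key {key!r}")
        kd[key] = parse_quantity(grad_cfg[key], "concentration").to("uM").magnitude
    kin = cfg.get("kinetics", {})
    kon_nup = parse_quantity(kin["nup_impb_kon"], "kon")
    kon_ran = parse_quantity(kin["impb_rangtp_kon"], "kon")
    # optional redundant k_off triple: must be consistent with K_D and k_on
    if "nup_impb_koff" in kin:
        for key, kd_uM in zip(
            ("cytoplasmic_periphery", "central_channel", "nuclear_basket"), kd.values()
        ):
            KineticPair.from_quantities(
                k_on=kon_nup,
                k_off=kin["nup_impb_koff"][key],
                K_D=_q(kd_uM, "uM"),
                name=f"nup_impb:{key}",
                rtol=1e-9,
            )
    conc = cfg.get("concentrations", {})
    sp = cfg.get("species", {})

    def _missing(key):
        raise ConfigError(f"missing config key {key!r}")

    def species_field(name, field, kind, default, unit=None):
        block = sp.get(name, {})
        if field in block:
            q = parse_quantity(block[field], kind)
            return q.to(unit).magnitude if unit else q.internal
        return default

    base = NpcScenario()
    tracers = tuple(
        parse_quantity(r, "length").internal
        for r in cfg.get("tracers", {}).get("stokes_radii", [])
    )
    scenario = replace(
        base,
        dt_s=dt,
        bound_complex_mobile=bool(eng.get("bound_complex_mobile", True)),
        gradient=AffinityGradient(
            kd["cytoplasmic_periphery"], kd["central_channel"], kd["nuclear_basket"]
        ),
        nup_impb_kon=(kon_nup.magnitude, kon_nup.unit),
        impb_rangtp_kon=(kon_ran.magnitude, kon_ran.unit),
        impb_conc_uM=parse_quantity(conc["impb_cytoplasm"], "concentration").to("uM").magnitude
        if "impb_cytoplasm" in conc else _missing("impb_cytoplasm"),
        rangtp_conc_uM=parse_quantity(conc["rangtp_nucleoplasm"], "concentration").to("uM").magnitude
        if "rangtp_nucleoplasm" in conc else _missing("rangtp_nucleoplasm"),
        impb_volume_nm3=species_field("impb", "volume", "volume", base.impb_volume_nm3),
        diffusivity_um2_s=species_field("impb", "diffusivity", "diffusivity", base.diffusivity_um2_s, unit="um2/s"),
        rangtp_volume_nm3=species_field("rangtp", "volume", "volume", base.rangtp_volume_nm3),
        fg_volume_nm3=species_field("fg_nup", "volume", "volume", base.fg_volume_nm3),
        fg_diffusivity_um2_s=species_field("fg_nup", "diffusivity", "diffusivity", base.fg_diffusivity_um2_s, unit="um2/s"),
        fg_counts=tuple(sp.get("fg_nup", {}).get("counts", base.fg_counts)),
        non_fg_volume_nm3=species_field("non_fg_nup", "volume", "volume", base.non_fg_volume_nm3),
        non_fg_diffusivity_um2_s=species_field("non_fg_nup", "diffusivity", "diffusivity", base.non_fg_diffusivity_um2_s, unit="um2/s"),
        non_fg_count=int(sp.get("non_fg_nup", {}).get("count", base.non_fg_count)),
        tracer_radii_nm=tracers,
        include_labeled_impb=bool(cfg.get("include_labeled_impb", False)),
    )
    validate_scenario(scenario)  # eager timestep validation
    return scenario


def generate_fixture(name: str, seed: int = 0) -> tuple:
    """Emit a canonical ready-to-run config plus its expected-property sheet.

    Returns ``(config_dict, properties)`` where *properties* is a
    machine-readable list of the checks the fixture should satisfy."""
    if name not in FIXTURE_NAMES:
        raise ConfigError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    if name == "ode_box":
        cfg = {
            "kind": "ode_box",
            "label": "ode_box",
            "n0": 2000,
            "c0": _q(3.0, "mM"),
            "k_on": [_q(5e4, "1/M/s"), _q(2e5, "1/M/s")],
            "engine": {"dt": _q(2.5e-6, "s")},
            "seed": int(seed),
        }
        props = [
            {"check": "box_volume_nm3", "target": 2000 / (3e-3 * PER_NM3_PER_MOLAR), "rtol": 0.01},
            {"check": "abm_vs_ode_max_abs_z", "max": 3.0},
        ]
        return cfg, props
    if name == "tracer_panel":
        sc = NpcScenario(tracer_radii_nm=DEFAULT_TRACER_RADII)
        cfg = scenario_to_config(sc, label="tracer_panel")
        cfg["seed"] = int(seed)
        props = [
            {"check": "influx_large_tracer_below_per_s", "radius_nm": 2.819, "max": 0.001},
            {"check": "influx_small_vs_large_ratio_min", "min": 30.0},
        ]
        return cfg, props
    grad = {
        "uniform_KD": GRADIENT_PRESETS["uniform_200uM"],
        "yeast": GRADIENT_PRESETS["yeast"],
        "vertebrate": GRADIENT_PRESETS["vertebrate"],
        "optimum": GRADIENT_PRESETS["optimum"],
    }[name]
    sc = NpcScenario(gradient=grad)
    cfg = scenario_to_config(sc, label=name)
    cfg["seed"] = int(seed)
    props = [
        {"check": "gradient_uM", "target": list(grad.as_tuple())},
        {"check": "timestep_valid", "dt_s": sc.dt_s},
        {"check": "net_import_non_negative"},
    ]
    return cfg, props


def write_fixture(name: str, directory, seed: int = 0) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg, props = generate_fixture(name, seed)
    path = directory / f"{name}.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    with open(directory / f"{name}.properties.yaml", "w") as fh:
        yaml.safe_dump(props, fh, sort_keys=True)
    return path


def load_config(path):
    """Load and validate a config file; returns ``(kind, payload)``.

    For ``kind: npc`` the payload is a validated :class:`NpcScenario`; for
    ``kind: ode_box`` it is the parsed parameter mapping."""
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "kind" not in cfg:
        raise ConfigError(f"{path}: not a scenario config (missing 'kind')")
    if cfg["kind"] == "npc":
        return "npc", config_to_scenario(cfg)
    if cfg["kind"] == "ode_box":
        _get_quantity(cfg.get("engine", {}), "dt", "time")
        _get_quantity(cfg, "c0", "concentration")
        for k in cfg.get("k_on", []):
            parse_quantity(k, "kon")
        return "ode_box", cfg
    raise ConfigError(f"{path}: unknown config kind {cfg['kind']!r}")


def config_hash(cfg: dict) -> str:
    blob = yaml.safe_dump(cfg, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def make_manifest(cfg: dict, seed, outputs=(), extra=None) -> dict:
    """Run manifest sufficient to re-run bit-identically."""
    man = {
        "config_hash": config_hash(cfg),
        "config": cfg,
        "seed": int(seed),
        "package": {"name": "npcabm", "version": __version__},
        "environment": {
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
        "outputs": [str(o) for o in outputs],
    }
    if extra:
        man["extra"] = extra
    return man


def write_manifest(man: dict, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(man, fh, indent=2, sort_keys=True)
    return path
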