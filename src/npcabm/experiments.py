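"""Experiment drivers: ODE validation, influx fits, transport rates, sweeps.

These reduce raw trajectories to the quantities of interest:

* ``ode_validation`` — ensemble of well-mixed irreversible 2A -> C runs
  compared per-checkpoint against the numerically integrated rate law.
* ``equilibrium_check`` — reversible A + B <-> AB in a well-mixed box versus
  the mass-action quadratic for the configured K_D.
* ``fit_influx`` / ``measure_influx`` — first-order nuclear-entry kinetics
  c(t) = c_inf (1 - exp(-k t)) after an in-silico microinjection.
* ``measure_transport_rate`` — replicate-averaged OLS slope of cumulative
  net Impβ entries into bulk nucleoplasm after a burn-in, with the standard
  error taken across replicates.
* ``sweep_gradients`` / ``sensitivity_suite`` — affinity-gradient grids and
  the timestep / concentration perturbation battery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit

from .engine import EngineConfig, Lattice, PairRule, Simulation, Species
from .kinetics import (
    KineticPair,
    LatticeGeometry,
    bind_probability,
    move_probability,
    neighbor_correction,
    unbind_probability,
)
from .npc import (
    CYTOPLASM,
    NUCLEOPLASM,
    NpcScenario,
    build_simulation,
    microinject,
    nuclear_concentration_uM,
    tracer_name,
)
from .units import PER_NM3_PER_MOLAR

MAX_SEED = 2**31 - 1


def _spawn_seeds(seed, n):
    """Independent sub-seeds below 2^31 derived from one master seed."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) & MAX_SEED]


# --------------------------------------------------------------------- boxes
def box_dims_for_volume(volume_nm3: float, cell_edge_nm: float = 5.0) -> tuple:
    """Near-cubic lattice dimensions whose cell count best matches a volume."""
    n_cells = max(1, int(round(volume_nm3 / cell_edge_nm**3)))
    a = int(round(n_cells ** (1 / 3)))
    best = None
    for dx in range(max(1, a - 6), a + 7):
        for dy in range(max(1, a - 6), a + 7):
            dz = int(round(n_cells / (dx * dy)))
            if dz < 1:
                continue
            err = abs(dx * dy * dz - n_cells)
            if best is None or err < best[0]:
                best = (err, (dx, dy, dz))
    return best[1]


@dataclass
class OdeComparison:
    """Per-checkpoint comparison of the ABM ensemble mean with the rate law."""

    k_on_M_s: float
    times_s: np.ndarray
    abm_mean: np.ndarray
    abm_se: np.ndarray
    ode: np.ndarray
    n_replicates: int

    @property
    def z_scores(self) -> np.ndarray:
        se = np.where(self.abm_se > 0, self.abm_se, np.inf)
        return (self.abm_mean - self.ode) / se

    @property
    def max_abs_z(self) -> float:
        return float(np.max(np.abs(self.z_scores)))


def ode_validation(
    k_on_list_M_s=(5e4, 2e5),
    n0: int = 2000,
    c0_mM: float = 3.0,
    dt_s: float = 2.5e-6,
    horizon_s: float = 0.01,
    n_checkpoints: int = 10,
    n_replicates: int = 16,
    molecule_volume_nm3: float = 5.0,
    diffusivity_um2_s: float = 1.5,
    seed: int = 0,
):
    """Irreversible 2A -> C in a well-mixed periodic box vs the ODE solution.

    The box volume is set so that *n0* molecules correspond to *c0_mM*
    (2000 molecules at 3 mM is about 1.107e6 nm^3, i.e. 8856 cells of
    125 nm^3).  Returns one :class:`OdeComparison` per rate constant.
    """
    c0 = c0_mM * 1e-3 * PER_NM3_PER_MOLAR  # molecules / nm^3
    volume = n0 / c0
    dims = box_dims_for_volume(volume)
    lat = Lattice.box(dims, periodic=True)
    geom = LatticeGeometry(cell_edge_nm=lat.cell_edge_nm, n_cells=lat.n_cells)
    v_sys = lat.n_cells * lat.cell_volume_nm3
    n_c = neighbor_correction((molecule_volume_nm3, molecule_volume_nm3),
                              lat.cell_volume_nm3)
    p_move = move_probability(diffusivity_um2_s, dt_s, geom)
    steps_total = int(round(horizon_s / dt_s))
    chunk = max(1, steps_total // n_checkpoints)
    times = np.arange(1, n_checkpoints + 1) * chunk * dt_s

    out = []
    seeds = _spawn_seeds(seed, len(k_on_list_M_s) * n_replicates * 2)
    si = 0
    for k_on in k_on_list_M_s:
        pair = KineticPair(
            k_on_nm3_s=k_on * 1e24 / (PER_NM3_PER_MOLAR * 1e24),
            k_off_s=0.0, same_species=True, correction_factor=n_c, name="A+A",
        )
        p_bind = bind_probability(pair, dt_s, geom)
        traj = np.zeros((n_replicates, n_checkpoints))
        for r in range(n_replicates):
            sim = Simulation(
                lat,
                [Species("A", p_move, molecule_volume_nm3)],
                [PairRule("A", "A", p_bind, 0.0, name="A+A")],
                config=EngineConfig(dt_s=dt_s),
                capacity=n0 + 64,
            )
            sim.add_agents("A", n=n0, rng=seeds[si]); si += 1
            for c in range(n_checkpoints):
                sim.run(chunk, seed=(seeds[si - 1] + 7919 * (c + 1)) % MAX_SEED)
                traj[r, c] = sim.free_count("A")
        # deterministic rate law for 2A -> C with the ordered-collision
        # rate-constant convention (the same-species probability is halved
        # and each unordered pair is a single candidate): the event rate is
        # k N(N-1)/(4V) and each event consumes two A, so
        # dN/dt = -k N(N-1)/(2V).
        k_vol = pair.k_on_nm3_s
        sol = solve_ivp(
            lambda t, y: -k_vol * y * (y - 1.0) / (2.0 * v_sys),
            (0.0, times[-1]), [float(n0)],
            t_eval=times, rtol=1e-10, atol=1e-8,
        )
        mean = traj.mean(axis=0)
        se = traj.std(axis=0, ddof=1) / math.sqrt(n_replicates)
        out.append(OdeComparison(k_on, times, mean, se, sol.y[0], n_replicates))
    return out


@dataclass
class EquilibriumResult:
    kd_uM: float
    bound_mean: float
    bound_se: float
    bound_theory: float
    n_replicates: int

    @property
    def z_score(self) -> float:
        se = self.bound_se if self.bound_se > 0 else np.inf
        return (self.bound_mean - self.bound_theory) / se


def mass_action_bound_count(n_a: int, n_b: int, kd_per_nm3: float, volume_nm3: float) -> float:
    """Equilibrium bound count from the mass-action quadratic (large-N limit)."""
    kd_count = kd_per_nm3 * volume_nm3
    s = n_a + n_b + kd_count
    return (s - math.sqrt(s * s - 4.0 * n_a * n_b)) / 2.0


def exact_equilibrium_bound_mean(n_a: int, n_b: int, kd_per_nm3: float,
                                 volume_nm3: float) -> float:
    """Mean bound count of the exact A+B<->AB birth-death stationary law.

    At single- to hundreds-of-molecule copy numbers the stationary mean
    differs from the mass-action quadratic root by O(1) molecules; this is
    the correct oracle for a finite stochastic system."""
    kd_count = kd_per_nm3 * volume_nm3
    nmax = min(n_a, n_b)
    logw = np.zeros(nmax + 1)
    for n in range(1, nmax + 1):
        logw[n] = logw[n - 1] + math.log(
            (n_a - n + 1) * (n_b - n + 1) / (kd_count * n))
    w = np.exp(logw - logw.max())
    n = np.arange(nmax + 1)
    return float((n * w).sum() / w.sum())


def equilibrium_check(
    kd_uM: float = 200.0,
    k_on_M_s: float = 1e7,
    n_a: int = 300,
    n_b: int = 300,
    box_cells: tuple = (20, 20, 20),
    molecule_volume_nm3: float = 5.0,
    diffusivity_um2_s: float = 1.5,
    dt_s: float = 2.5e-6,
    burn_in_steps: int = 8000,
    n_samples: int = 40,
    sample_stride: int = 500,
    n_replicates: int = 5,
    seed: int = 0,
) -> EquilibriumResult:
    """Reversible A + B <-> AB: measured bound fraction vs mass action."""
    lat = Lattice.box(box_cells, periodic=True)
    geom = LatticeGeometry(cell_edge_nm=lat.cell_edge_nm, n_cells=lat.n_cells)
    kd_per_nm3 = kd_uM * 1e-6 * PER_NM3_PER_MOLAR
    n_c = neighbor_correction((molecule_volume_nm3, molecule_volume_nm3),
                              lat.cell_volume_nm3)
    pair = KineticPair(
        k_on_nm3_s=k_on_M_s * 1e24 / (PER_NM3_PER_MOLAR * 1e24),
        k_off_s=kd_per_nm3 * k_on_M_s * 1e24 / (PER_NM3_PER_MOLAR * 1e24),
        correction_factor=n_c, name="A+B",
    )
    p_move = move_probability(diffusivity_um2_s, dt_s, geom)
    p_bind = bind_probability(pair, dt_s, geom)
    p_unbind = unbind_probability(pair.k_off_s, dt_s)
    seeds = _spawn_seeds(seed, n_replicates)
    means = []
    for r in range(n_replicates):
        sim = Simulation(
            lat,
            [Species("A", p_move, molecule_volume_nm3),
             Species("B", p_move, molecule_volume_nm3)],
            [PairRule("A", "B", p_bind, p_unbind, name="A+B")],
            config=EngineConfig(dt_s=dt_s),
            capacity=n_a + n_b + 64,
        )
        sim.add_agents("A", n=n_a, rng=seeds[r])
        sim.add_agents("B", n=n_b, rng=seeds[r] + 1)
        sim.run(burn_in_steps, seed=seeds[r])
        samples = []
        for c in range(n_samples):
            sim.run(sample_stride, seed=(seeds[r] + 104729 * (c + 1)) % MAX_SEED)
            samples.append(n_a - sim.free_count("A"))
        means.append(float(np.mean(samples)))
    theory = exact_equilibrium_bound_mean(n_a, n_b, kd_per_nm3,
                                          lat.n_cells * lat.cell_volume_nm3)
    means = np.asarray(means)
    return EquilibriumResult(
        kd_uM=kd_uM,
        bound_mean=float(means.mean()),
        bound_se=float(means.std(ddof=1) / math.sqrt(n_replicates)),
        bound_theory=theory,
        n_replicates=n_replicates,
    )


# -------------------------------------------------------------- influx fits
@dataclass
class InfluxFit:
    """First-order influx fit c(t) = c_inf (1 - exp(-k t))."""

    k_per_s: float
    c_inf_uM: float
    k_stderr: float
    residual_norm: float
    n_replicates: int


class InfluxFitError(RuntimeError):
    pass


def fit_influx(times_s, conc_uM, c_inf_uM=None, n_replicates=1) -> InfluxFit:
    """Least-squares fit of the first-order nuclear-entry law.

    With *c_inf_uM* given only the rate is fitted (robust for nearly
    impermeable species); otherwise both parameters are free.  The curve is
    pinned at c(0) = 0 (post-injection origin).
    """
    t = np.asarray(times_s, dtype=float)
    c = np.asarray(conc_uM, dtype=float)
    if len(t) < 3 or np.all(c <= 0):
        raise InfluxFitError(
            f"influx indeterminate: {len(t)} points, max c = {c.max() if len(c) else 0:.3g} uM"
        )
    try:
        if c_inf_uM is None:
            def f(t, k, cinf):
                return cinf * -np.expm1(-k * t)
            k0 = 1.0 / max(t[-1] / 3.0, 1e-9)
            popt, pcov = curve_fit(f, t, c, p0=(k0, max(c.max(), 1e-6)),
                                   maxfev=20000, bounds=(0, np.inf))
            k, cinf = popt
            kerr = float(np.sqrt(pcov[0, 0]))
        else:
            cinf = float(c_inf_uM)

            def f(t, k):
                return cinf * -np.expm1(-k * t)
            popt, pcov = curve_fit(f, t, c, p0=(0.1,), maxfev=20000,
                                   bounds=(0, np.inf))
            k = popt[0]
            kerr = float(np.sqrt(pcov[0, 0]))
    except RuntimeError as exc:
        raise InfluxFitError(f"influx fit did not converge: {exc}") from exc
    resid = c - cinf * -np.expm1(-k * t)
    return InfluxFit(float(k), float(cinf), kerr, float(np.linalg.norm(resid)),
                     n_replicates)


def measure_influx(
    scenario: NpcScenario,
    species: str,
    inject_conc_uM: float = 10.0,
    pre_equilibrate_s: float = 0.1,
    horizon_s: float = 2.0,
    record_stride_s: float = 0.02,
    n_replicates: int = 4,
    seed: int = 0,
    fixed_plateau: bool = True,
):
    """Microinjection influx assay: replicate-averaged nuclear concentration
    fitted to first-order kinetics.  *species* is either ``"impb_labeled"``
    or a tracer name already present in ``scenario.tracer_radii_nm``."""
    dt = scenario.dt_s
    burn = int(round(pre_equilibrate_s / dt))
    steps = int(round(horizon_s / dt))
    stride = max(1, int(round(record_stride_s / dt)))
    seeds = _spawn_seeds(seed, 2 * n_replicates)
    curves = []
    v_cyt = v_nuc = v_total = None
    for r in range(n_replicates):
        sim, meta = build_simulation(scenario, seed=seeds[2 * r])
        if v_cyt is None:
            v_cyt = meta["geometry_audit"][CYTOPLASM]["volume_nm3"]
            v_nuc = meta["geometry_audit"][NUCLEOPLASM]["volume_nm3"]
            acc = sum(meta["geometry_audit"][k]["volume_nm3"]
                      for k in meta["geometry_audit"]
                      if meta["geometry_audit"][k]["name"] != "nuclear_membrane")
            v_total = acc
        if burn > 0:
            sim.run(burn, seed=seeds[2 * r + 1])
        microinject(sim, scenario, species, inject_conc_uM, region=CYTOPLASM,
                    rng=seeds[2 * r] + 13)
        res = sim.run(steps, seed=(seeds[2 * r + 1] + 1) % MAX_SEED,
                      record_stride=stride)
        curves.append(nuclear_concentration_uM(res, sim, species))
        times = res.times_s - res.times_s[0]
    mean_curve = np.mean(curves, axis=0)
    n_injected = inject_conc_uM * 1e-6 * PER_NM3_PER_MOLAR * v_cyt
    c_inf = None
    if fixed_plateau:
        # plateau = injected amount spread over all accessible volume
        c_inf = n_injected / v_total / (PER_NM3_PER_MOLAR * 1e-6)
    fit = fit_influx(times[1:], mean_curve[1:], c_inf_uM=c_inf,
                     n_replicates=n_replicates)
    return fit, times, mean_curve


# ---------------------------------------------------------- transport rates
@dataclass
class TransportResult:
    """Replicate-averaged Impβ transport rate (net entries / s)."""

    rate_per_s: float
    se_per_s: float
    rates: np.ndarray
    gross_rate_per_s: float
    gross_se_per_s: float
    gross_rates: np.ndarray
    burn_in_s: float
    window_s: float
    n_replicates: int


def measure_transport_rate(
    scenario: NpcScenario,
    n_replicates: int = 100,
    total_s: float = 2.5,
    burn_in_s: float = 1.0,
    record_stride_s: float = 0.01,
    seed: int = 0,
) -> TransportResult:
    """Steady-state Impβ transport rate through the pore.

    Per replicate the cumulative net count of Impβ agents entering bulk
    nucleoplasm is regressed on time over (burn_in, total]; the reported
    rate is the replicate mean, with the standard error computed across
    replicate slopes."""
    dt = scenario.dt_s
    steps = int(round(total_s / dt))
    stride = max(1, int(round(record_stride_s / dt)))
    seeds = _spawn_seeds(seed, 2 * n_replicates)
    slopes = []
    gross = []
    for r in range(n_replicates):
        sim, _ = build_simulation(scenario, seed=seeds[2 * r])
        res = sim.run(steps, seed=seeds[2 * r + 1], record_stride=stride)
        t = res.times_s
        sel = t > burn_in_s
        if sel.sum() < 2:
            raise ValueError("window after burn-in holds fewer than 2 records")
        net = res.net_import(res.species.index("impb"))
        slopes.append(float(np.polyfit(t[sel], net[sel], 1)[0]))
        g = res.translocations[:, res.species.index("impb"), 0]
        gross.append(float(np.polyfit(t[sel], g[sel], 1)[0]))
    slopes = np.asarray(slopes)
    gross = np.asarray(gross)
    se = float(slopes.std(ddof=1) / math.sqrt(n_replicates)) if n_replicates > 1 else 0.0
    gse = float(gross.std(ddof=1) / math.sqrt(n_replicates)) if n_replicates > 1 else 0.0
    return TransportResult(
        rate_per_s=float(slopes.mean()),
        se_per_s=se,
        rates=slopes,
        gross_rate_per_s=float(gross.mean()),
        gross_se_per_s=gse,
        gross_rates=gross,
        burn_in_s=burn_in_s,
        window_s=total_s - burn_in_s,
        n_replicates=n_replicates,
    )


def paired_relative_change(a: TransportResult, b: TransportResult,
                           gross: bool = True):
    """Relative rate change a vs b with the SE of the paired difference.

    Valid when both results were measured with the same master seed, so
    replicate i of each condition shares its random channel packing
    (common random numbers); the quenched-disorder variance then cancels
    in the per-replicate differences."""
    ra = a.gross_rates if gross else a.rates
    rb = b.gross_rates if gross else b.rates
    n = min(len(ra), len(rb))
    d = np.asarray(ra[:n]) - np.asarray(rb[:n])
    base = float(np.mean(rb[:n]))
    if base == 0.0:
        return math.inf, math.inf
    rel = float(np.mean(d)) / base
    se = float(np.std(d, ddof=1)) / math.sqrt(n) / abs(base) if n > 1 else math.inf
    return rel, se


def sweep_gradients(
    scenario: NpcScenario,
    gradients: dict,
    n_replicates: int = 10,
    total_s: float = 2.5,
    burn_in_s: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Transport rate over a set of affinity gradients.

    *gradients* maps label -> AffinityGradient.  Per-cell failures are
    recorded (rate = NaN) and the sweep continues.  Returns a tidy table."""
    rows = []
    seeds = _spawn_seeds(seed, len(gradients))
    for i, (label, grad) in enumerate(gradients.items()):
        sc = scenario.with_gradient(grad)
        try:
            res = measure_transport_rate(
                sc, n_replicates=n_replicates, total_s=total_s,
                burn_in_s=burn_in_s, seed=seeds[i],
            )
            rows.append((label, *grad.as_tuple(), res.rate_per_s, res.se_per_s,
                         res.gross_rate_per_s, n_replicates, None))
        except Exception as exc:  # noqa: BLE001 - sweep must continue
            rows.append((label, *grad.as_tuple(), np.nan, np.nan, np.nan,
                         n_replicates, str(exc)))
    return pd.DataFrame(
        rows,
        columns=["label", "kd_periphery_uM", "kd_channel_uM", "kd_basket_uM",
                 "rate_per_s", "se_per_s", "gross_rate_per_s", "n_replicates",
                 "error"],
    )


def sensitivity_suite(
    scenario: NpcScenario,
    n_replicates: int = 10,
    total_s: float = 1.5,
    burn_in_s: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """The perturbation battery: dt/2, Impβ x2, RanGTP x10 and /10.

    Reports each condition's rate with SE and the relative change versus
    baseline."""
    conditions = {
        "baseline": scenario,
        "dt_half": replace(scenario, dt_s=scenario.dt_s / 2.0),
        "impb_x2": replace(scenario, impb_conc_uM=2.0 * scenario.impb_conc_uM),
        "rangtp_x10": replace(scenario, rangtp_conc_uM=10.0 * scenario.rangtp_conc_uM),
        "rangtp_div10": replace(scenario, rangtp_conc_uM=scenario.rangtp_conc_uM / 10.0),
    }
    seeds = _spawn_seeds(seed, len(conditions))
    rows = []
    base_rate = None
    for i, (label, sc) in enumerate(conditions.items()):
        res = measure_transport_rate(
            sc, n_replicates=n_replicates, total_s=total_s,
            burn_in_s=burn_in_s, seed=seeds[i],
        )
        if label == "baseline":
            base_rate = res.rate_per_s
        rel = (res.rate_per_s - base_rate) / base_rate if base_rate else np.nan
        rows.append((label, res.rate_per_s, res.se_per_s, rel, n_replicates))
    return pd.DataFrame(
        rows, columns=["condition", "rate_per_s", "se_per_s",
                       "relative_change", "n_replicates"],
    )
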