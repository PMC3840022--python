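# Methods

## The model

`npcabm` simulates nucleocytoplasmic import as an on-lattice agent-based
model (ABM).  Space is a cubic lattice of 5 nm cells; time advances in
discrete steps of `dt = 2.5e-6 s`.  Each molecule is an explicit agent that
diffuses by hopping between face-adjacent (von Neumann) cells and reacts
with partners in its own or adjacent cells.  The model's purpose is to
measure how the regional affinity of FG-nucleoporins (FG-Nups) for the
import receptor Importinβ (Impβ) — an *affinity gradient* across the pore —
shapes the steady-state import rate.

### From physical constants to per-step probabilities

The engine is driven by three probabilities, derived so that the stochastic
dynamics reproduce the macroscopic laws:

* **Movement.** `p_move = 2 d D dt / Δx²` with `d = 3` dimensions.  An agent
  attempts a hop with probability `p_move`, toward one of the `q = 2d = 6`
  neighbours chosen uniformly.  The ensemble mean-squared displacement is
  then `6 D t` exactly; the test suite recovers `D` from free walkers to
  within 2 %.
* **Unbinding.** `p_unbind = k_off · dt`, the small-`dt` limit of
  `1 − exp(−k_off dt)` (the exponential form is available as
  `unbind_probability_exact` for large-`dt` robustness).  A bound ensemble
  decays as `(1 − p_unbind)^n`, i.e. first-order kinetics.
* **Binding.** Candidate pairs are unbound partners in the same or adjacent
  cells.  When the lattice is much larger than the population, a given pair
  is a candidate with probability `(q + n_c)/N_cells`, where `n_c` corrects
  for in-cell co-occupancy (below).  Equating the expected event count
  `p_bind · N_A N_B (q + n_c)/N_cells` per step with the mass-action
  increment `k_on N_A N_B dt / V` gives

      p_bind = k_on · dt / ((q + n_c) · V_cell)

  with `k_on` in nm³/s per molecule pair.  For two molecules of the same
  species the probability is halved and each unordered pair is enumerated
  once; the deterministic law this encodes for `2A → C` is
  `dN/dt = −k_on N(N−1)/(2V)` (the ordered-collision rate-constant
  convention), which is the law the ODE-equivalence test integrates.

Any probability above one is a construction-time error carrying the largest
admissible `dt` — never a silent clamp, which would quietly rescale the
kinetics.  `validate_timestep` applies this check to a whole scenario at
once and is run eagerly when configurations are loaded.

### The co-occupancy neighbour correction `n_c`

Cells can hold several molecules as long as their summed volume fits, so
two partners may also meet *inside* one cell.  Under the crowding rule
below, the stationary frequency of in-cell encounters relative to a single
neighbour-cell channel works out to the mean free-volume acceptance of the
two partners:

    n_c = 1 − (V_A + V_B) / (2 V_cell)    for V_A + V_B ≤ V_cell, else 0.

The point-like limit is `n_c = 1`; the constant in front is fixed by that
limit, not fitted.  A Monte-Carlo oracle in the test suite (two hard
molecules random-walking in a periodic box) confirms the form at both
point-like and intermediate volumes.

### Crowding: reduced probability + volume limit (RP+VL)

A move into a cell whose free volume cannot hold the mover is rejected
outright (VL); otherwise it is accepted with probability equal to the
target cell's free-volume fraction (RP).  Moves are attempted toward a
uniformly drawn neighbour regardless of accessibility ("blind ant"), which
is the variant that preserves the MSD↔D identity near obstacles.
Non-interacting finite-volume agents equilibrate to uniform density over
accessible cells (tested).

### Reaction execution order

Each step: (1) every agent, in an order reshuffled each step, attempts one
move; (2) for every interaction rule, a bind pass and an unbind pass are
executed, with the order of all passes reshuffled each step and candidate
pairs processed in shuffled order; a binding claims both partners, so an
agent binds at most once per step.  (3) concentration clamps and the
complex-recycling sink run last.  On binding, the pair co-locates in one
cell when the volume limit allows (otherwise the bond spans the two
adjacent cells and the complex is held in place until it can co-locate or
unbinds).  Mobile bound pairs move as a unit with the slower partner's
probability, restricted to regions allowed for both partners.

## The NPC scenario

A 42,108-element lattice (29 × 33 × 44 cells of 5 nm) holds six regions:
cytoplasm, nucleoplasm, an impermeable 35 nm membrane, and three pore
regions — the cytoplasmic-filament periphery (50 nm diameter × 30 nm deep),
an hourglass central channel (50 nm diameter at the faces, 30 nm at the
midplane) and a nuclear basket modelled as a solid truncated cone
(55 nm deep, widening from the 30 nm channel exit to a 50 nm distal ring).
The pore is the only passage between the compartments (verified by graph
search).

**Populations.**  FG-Nup agents number 24 / 80 / 32 in periphery / channel /
basket and are confined to their home regions (tethered, locally diffusive,
`D = 0.4 µm²/s`, 35 nm³ each).  Steric non-FG Nup agents represent
scaffold-anchored domains crowding the central channel: 650 agents of
40 nm³ (≈ 58 % channel volume occupancy including FG agents), slowly
rearranging at `D = 0.1 µm²/s`.  Cytoplasmic Impβ (90 nm³) is clamped at
2.5 µM (3 agents in the bulk-cytoplasm volume) and nuclear RanGTP (34 nm³)
at 1 µM (2 agents); clamps insert or remove free agents far from the pore
mouth after every step and log every action so conservation can be audited.

**Interactions.**  Impβ binds FG-Nups with `k_on = 1e7 M⁻¹s⁻¹` and a
region-specific `K_D` (the affinity gradient; sweeps vary `k_off` only).
RanGTP binds Impβ irreversibly (`k_on = 1e8 M⁻¹s⁻¹`), may displace an
existing Impβ–Nup bond, and blocks FG rebinding; Impβ–RanGTP complexes in
bulk nucleoplasm are removed by a recycling sink, terminating one import
event.  Labeled Impβ (for influx assays) shares all Impβ physics but is
neither clamped nor recycled, so an injected bolus is conserved.

### Parameter choices where the physics underdetermines the model

* **Diffusivities.**  The `dt = 2.5e-6 s`, `Δx = 5 nm` pair admits at most
  `D = Δx²/(6 dt) = 1.67 µm²/s`.  The species in play (0.5–2.8 nm Stokes
  radii) span only a ~5× Stokes–Einstein range, which this ceiling
  compresses; and the import machinery (RanGTP capture fast relative to a
  transport cycle, transport rates of tens of events per second from ~3
  receptor agents) requires near-ceiling mobility.  All freely diffusing
  species therefore share `D = 1.5 µm²/s` (`p_move = 0.9`); size
  selectivity is carried entirely by excluded volume.  Consequence: passive
  influx rates for *small* tracers are faster than they would be under a
  size-resolved mobility law; the exclusion *contrast* across the panel is
  the robust observable.
* **Molecular volumes.**  Impβ 90 nm³ (the largest single-molecule agent;
  the 5 nm cell was chosen to accommodate it), RanGTP 34 nm³, FG domain
  35 nm³, non-FG domain 40 nm³.  These make the discrimination mechanism
  concrete: a cell holding one FG domain has exactly 90 nm³ free — it
  admits Impβ but excludes a 2.82 nm (94 nm³) inert tracer.
* **The passive permeability barrier** is calibrated through the non-FG
  crowder count, the one deliberately fitted constant: 650 crowders is the
  knee at which an inert 2.82 nm tracer is blocked a few-hundred-fold
  relative to Impβ while receptor transport remains measurable.  Pushing
  the barrier tighter (≥ 750 crowders, or freezing them) silences *both*
  the tracer leak and all Impβ transport: with a hard volume cap there is
  no static packing that passes a 90 nm³ receptor and stops a 94 nm³
  tracer.  Selectivity is kinetic: crowders rearrange slowly, transiently
  opening corridors; Nup-bound Impβ waits in place and exploits every
  opening, while an inert molecule has drifted away between openings.
* **RanGTP association.**  Set near the diffusion limit at `1e8 M⁻¹s⁻¹`
  (configurable).  Nuclear capture of Impβ is then encounter-limited, which
  is what makes the basket affinity matter: holding Impβ at the basket
  raises its chance of meeting RanGTP before diffusing back into the pore.

### Transport accounting

`count_translocations` maintains four cumulative per-species counters
(pore→nucleus, nucleus→pore, pore→cytoplasm, cytoplasm→pore).  The
transport experiment regresses the cumulative count of pore→nucleus entry
events on time over the post-burn-in window (replicate mean ± SE across
replicates) and reports the net rate (entries − exits) alongside.  The
event rate is the headline: with ~3 clamped receptor agents, tens of
translocation events per second correspond to fractions of a second per
receptor crossing, while the *net* rate is bounded by the RanGTP capture
rate and is an order of magnitude smaller.

## What the scaled experiments do and do not show

Default experiment scales (replicates × window) are reduced from the
reference protocol (100 × 2.5 s with a 1 s burn-in) to 6–10 replicates and
~1 s windows so that the whole battery runs in minutes on one CPU; the CLI
exposes the full protocol.  At this scale, per-replicate variance is
dominated by the random channel packing (quenched disorder that relaxes
only slowly at the crowders' `D = 0.1 µm²/s`), so standard errors on
transport rates are large; qualitative orderings (biphasic affinity
dependence, basket-affinity benefit, receptor-limited scaling) are the
reliable readouts, while ±10 %-level contrasts need the full protocol.

The synthetic scenarios emulate: a single pore (no pore crowding by
neighbouring pores), a two-compartment geometry of ~5×10⁶ nm³ (far smaller
than a cell, hence single-digit copy numbers at physiological
concentrations), one receptor species with no cargo, no NTF2/Ran-recycling
pathway, and an effective single-probability macroscopic affinity in place
of multivalent microscopic FG binding sites.  Passing tests therefore
establishes internal consistency of the stochastic kinetics with the
mass-action and diffusion laws and reproduction of the qualitative
transport phenomenology — not quantitative agreement with in-vivo fluxes.

## Numerical choices

* Probabilities above 1 are construction-time errors; `validate_timestep`
  aggregates every violating species/pair with its maximum admissible dt.
* The engine's randomness is a single seeded xorshift64* stream; a seed
  fully determines a trajectory, bit-identically across platforms.
  Replicates use sub-seeds spawned from a master seed.
* Volume comparisons use a 1e-9 nm³ tolerance so that exactly-fitting
  co-occupancies (e.g. Impβ into an FG cell, 90 ≤ 90) are accepted.
* Influx fits pin `c(0) = 0`; for nearly-impermeable species the plateau is
  fixed to the injected amount spread over the accessible volume and only
  the rate is fitted.  A curve with no entries at all is reported as an
  error, not a zero fit.
* Clamp counts are integer-rounded from concentration × audited region
  volume; the clamp restores the free count after every step, so the
  time-averaged concentration is exact to one-agent quantisation.
* Region boundaries are half-open along the pore axis; cell indices are
  0-based; the basket cone and channel hourglass radii are interpolated
  per 5 nm layer.

## Known limitations

* Absolute rates inherit the unresolvable ambiguities of the reference
  parameterisation (diffusivities, Nup volumes, and an Impβ–RanGTP on-rate
  whose printed unit is dimensionally inconsistent); relative and
  qualitative results are the trustworthy layer.
* Bound pairs that cannot co-locate are held in place rather than moving as
  a two-cell dimer; at channel crowding levels this makes high-affinity
  (sub-µM) pores somewhat stickier than a mobile-dimer treatment would.
* The clamp inserts agents at uniformly drawn cells far from the pore; it
  does not reproduce a physical bulk reservoir's spatial correlations.
* One pore, one receptor, no export pathway, no competing transportins.
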