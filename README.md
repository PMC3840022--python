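# npcabm

An on-lattice agent-based simulator of nucleocytoplasmic import through the
nuclear pore complex (NPC), built to ask a focused biophysical question:
**does a gradient of FG-nucleoporin affinity for the import receptor
Importinβ, rising from the cytoplasmic filaments to the nuclear basket,
increase the steady-state import rate — and is there an optimal gradient?**

It is aimed at computational biophysicists studying coarse-grained
nucleocytoplasmic transport, and at anyone who needs a small, fast,
well-tested reaction–diffusion ABM with molecular crowding on a lattice.

## The model in brief

Molecules are explicit agents on a cubic lattice of 5 nm cells advancing in
2.5 µs timesteps.  Physical constants map onto per-step event
probabilities:

    p_move   = 2 d D Δt / Δx²                    (d = 3; MSD = 6 D t)
    p_unbind = k_off Δt
    p_bind   = k_on Δt / ((q + n_c) V_cell)      (q = 6 von Neumann neighbours)

where `n_c = 1 − (V_A+V_B)/(2 V_cell)` corrects for pairs meeting inside a
shared cell, and any probability above 1 is a hard error naming the largest
admissible timestep.  Crowding uses the combined reduced-probability /
volume-limit (RP+VL) rule: a move into a cell that cannot hold the mover is
rejected; otherwise it is accepted with the target's free-volume fraction.

The NPC scenario is a 42,108-element lattice with six regions (cytoplasm,
nucleoplasm, impermeable membrane, cytoplasmic periphery, central channel,
nuclear basket), 24/80/32 FG-Nup agents per pore region, steric non-FG
crowders in the channel, cytoplasmic Impβ clamped at 2.5 µM, nuclear RanGTP
clamped at 1 µM, and an affinity gradient given as a K_D triple
(periphery, channel, basket).  RanGTP binding strips Impβ off the Nups and
terminates one import event.

## Worked example

Measure the Impβ transport rate for a pore with uniform 200 µM affinity
versus the optimal gradient (2000 / 200 / 10 µM), at reduced scale:

```python
from npcabm.npc import NpcScenario, GRADIENT_PRESETS
from npcabm.experiments import measure_transport_rate

base = NpcScenario()  # uniform 200 uM affinity
for label, sc in {
    "uniform 200 uM": base,
    "optimum gradient": base.with_gradient(GRADIENT_PRESETS["optimum"]),
}.items():
    r = measure_transport_rate(sc, n_replicates=10, total_s=1.25,
                               burn_in_s=0.5, seed=1)
    print(f"{label}: {r.gross_rate_per_s:.1f} ± {r.gross_se_per_s:.1f} "
          f"translocations/s (net {r.rate_per_s:.1f} ± {r.se_per_s:.1f}/s)")
```

Output from this exact snippet (seed 1, ~4 min):

```
uniform 200 uM: 11.9 ± 9.6 translocations/s (net 0.4 ± 0.2/s)
optimum gradient: 4.4 ± 3.1 translocations/s (net 0.5 ± 0.2/s)
```

The gross rate counts cumulative Impβ entries into bulk nucleoplasm
(regressed on time after the burn-in); the net rate subtracts re-exits and
is bounded by how fast nuclear RanGTP captures incoming receptors.  At
this replicate count the standard errors are dominated by the random
channel packing — the two conditions here are not statistically
distinguishable — so condition contrasts should be run with a shared seed
(paired replicates, `npcabm.experiments.paired_relative_change`) or with
the full 100-replicate protocol exposed by the CLI.

The same experiments are scriptable from the shell:

```sh
npcabm fixture optimum --out fixtures       # canonical scenario configs
npcabm transport --config fixtures/optimum.yaml --replicates 10 \
    --total 1.25 --burn-in 0.5 --seed 1 --out out/
npcabm sweep --channel-kds 2,20,200,2000 --replicates 10 --out out/
npcabm validate-ode --replicates 8 --out out/
```

Every run writes a JSON manifest (config hash, seed, versions) sufficient
to reproduce it bit-identically.

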