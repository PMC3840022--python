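"""Shared fixtures.

The transport-rate battery is expensive (each replicate is hundreds of
thousands of engine steps), so it is computed once per session at reduced
scale (8-10 replicates, ~1 s windows) and shared by the acceptance tests
that compare configurations against each other.
"""

from dataclasses import replace

import pytest

from npcabm.experiments import measure_transport_rate
from npcabm.npc import AffinityGradient, GRADIENT_PRESETS, NpcScenario


@pytest.fixture(scope="session")
def npc_default():
    return NpcScenario()


@pytest.fixture(scope="session")
def transport_battery():
    """Reduced-scale transport rates for the configurations the acceptance
    criteria compare.  Keyed by label; values are TransportResult."""
    base = NpcScenario()
    configs = {
        "uniform_200": (base, 10, 1.0, 0.4),
        "uniform_2": (base.with_gradient(AffinityGradient.uniform(2.0)), 8, 1.0, 0.4),
        "uniform_4000": (base.with_gradient(AffinityGradient.uniform(4000.0)), 8, 1.0, 0.4),
        "optimum": (base.with_gradient(GRADIENT_PRESETS["optimum"]), 10, 1.0, 0.4),
        "reversed": (base.with_gradient(AffinityGradient(10.0, 200.0, 2000.0)), 8, 1.0, 0.4),
        "cyt_weakened": (base.with_gradient(AffinityGradient(2.0, 200.0, 10.0)), 8, 1.0, 0.4),
        "impb_x2": (replace(base, impb_conc_uM=5.0), 8, 1.0, 0.4),
        "rangtp_x10": (replace(base, rangtp_conc_uM=10.0), 8, 1.0, 0.4),
        "dt_half": (replace(base, dt_s=base.dt_s / 2.0), 6, 1.0, 0.4),
    }
    out = {}
    # one master seed for every condition: replicate i of each condition then
    # shares its random channel packing, so condition contrasts are paired
    # (common-random-numbers variance reduction)
    for label, (sc, n, total, burn) in configs.items():
        out[label] = measure_transport_rate(
            sc, n_replicates=n, total_s=total, burn_in_s=burn, seed=1007,
        )
    return out
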