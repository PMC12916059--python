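"""Dopamine depletion in the full network: rates, beta power, loop synchrony.

Builds the full six-population network twice with identical wiring — once
with healthy dopamine (Dd = 0.166) and once dopamine-depleted (Dd = 0.5) —
and compares population firing rates, corrected beta-band power of the STN
and D2 population rates, and the phase locking (PLV) between the
subthalamo-pallidal and striato-pallidal beta loops.

One realization of 4 s per condition: expect a couple of minutes runtime.
"""

import numpy as np

from bgdbs.engine import SimulationSpec, simulate
from bgdbs.network import NetworkConfig, build_network
from bgdbs.analysis import beta_phase, corrected_band_power, plv, population_rate

spec = SimulationSpec(duration=4000, discard=2000, n_realizations=1)
rng = np.random.default_rng(0)

for label, dd in [("healthy", 0.166), ("parkinsonian", 0.5)]:
    net = build_network(NetworkConfig(Dd=dd, seed_network=1, seed_noise=101))
    spikes = simulate(net, spec=spec)
    print(f"== {label} (Dd = {dd}) ==")
    for pop in ("D1", "D2", "FSN", "GPe_TA", "GPe_TI", "STN"):
        print(f"  {pop:7s} {spikes.mean_rate(pop, spec.analysis_window):6.2f} Hz")
    rs = {p: population_rate(spikes, p, spec.analysis_window)
          for p in ("STN", "D2")}
    beta = corrected_band_power(rs["STN"], rng=rng)
    sync = plv(beta_phase(rs["STN"]), beta_phase(rs["D2"]))
    print(f"  STN corrected beta power: {beta.corrected:.4f}")
    print(f"  STN-D2 beta phase locking (PLV): {sync:.2f}")
    print()

print("Depletion raises D2 drive: the D2/D1 rate balance flips above 1,")
print("STN beta power rises severalfold, and the two beta-generating loops")
print("synchronize (PLV from ~0.3 to ~0.7) — the Parkinsonian signature.")
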