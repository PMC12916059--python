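"""The analysis stack on synthetic population activity (fast, no network).

Builds binomial spike-count series — a constant-activity population and one
with a 20 Hz rate modulation — and walks through the statistics the
simulator reports: Welch PSD, mean band power, the binomial baseline
correction, the beta-band spectral centroid, and the phase-locking value.
"""

import numpy as np

from bgdbs.analysis import (
    FS_HZ, RateSeries, beta_phase, corrected_band_power,
    mean_band_frequency, plv, psd_welch,
)

rng = np.random.default_rng(42)
n_neurons, length = 400, 8000
t = np.arange(length) / FS_HZ

flat = RateSeries(rng.binomial(n_neurons, 0.015, length), 0.0, n_neurons)
p_mod = 0.015 * (1 + 0.4 * np.sin(2 * np.pi * 20 * t))
osc = RateSeries(rng.binomial(n_neurons, p_mod), 0.0, n_neurons)

for label, rs in [("constant-activity", flat), ("20 Hz modulated", osc)]:
    bp = corrected_band_power(rs, rng=rng)
    print(f"{label:18s} raw beta {bp.mean_power:8.4f}  "
          f"baseline Q {bp.baseline:8.4f}  corrected {bp.corrected:+8.4f}")

print()
print("The baseline Q is the band power a same-size, same-rate population")
print("would show with no oscillation at all: the corrected value isolates")
print("genuine rhythmicity (near 0 for the constant population).")

print(f"\nbeta centroid of the modulated series: "
      f"{mean_band_frequency(psd_welch(osc)):.1f} Hz (injected: 20 Hz)")

lagged = RateSeries(np.roll(osc.counts, 10), 0.0, n_neurons)
print(f"PLV, series vs itself:       {plv(beta_phase(osc), beta_phase(osc)):.3f}")
print(f"PLV, series vs 10-ms-lagged: "
      f"{plv(beta_phase(osc), beta_phase(lagged)):.3f}")
print(f"PLV, series vs independent:  "
      f"{plv(beta_phase(osc), beta_phase(flat)):.3f}")
print("\nPLV measures phase consistency, not simultaneity: a fixed lag")
print("still locks perfectly, while independent noise decorrelates.")
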