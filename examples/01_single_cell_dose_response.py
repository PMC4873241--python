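"""Single-cell agonist dose response.

Simulates one endothelial cell under the agonist step protocol at each of
the four registered (K, V_m3) presets (rising histamine weakens PMCA
extrusion and strengthens CICR), scores the calcium trace with the
spike-calling pipeline, and prints spike count, first interspike interval
and fluorescence amplitude per preset.  Low presets produce repetitive
calcium spikes; the highest preset produces one prolonged transient.
"""

from calnet import build_topology, integrate, step_protocol, result_metrics
from calnet.model import AGONIST_PRESETS

topo = build_topology("single")
for level, (K, V_m3) in sorted(AGONIST_PRESETS.items()):
    res = integrate(topo, step_protocol(level, onset_s=200.0),
                    duration_s=500.0, seed=1, init_jitter=0.05)
    m = result_metrics(res)[0]
    interval = "-" if m.first_interval_s is None else f"{m.first_interval_s:6.1f} s"
    amp = "-" if not m.spike_amplitudes else f"{m.spike_amplitudes[0]:4.2f}"
    print(f"preset {level} (K={K:<4} V_m3={V_m3:3.0f} s^-1): "
          f"{m.n_spikes:2d} spikes, oscillating={m.oscillating!s:5}, "
          f"first interval {interval}, F/F0 amplitude {amp}")
print("\nIsolated cells never classify as oscillating; only the highest dose "
      "drives a single detectable transient -- repetitive spiking needs "
      "gap-junction-coupled neighbors (see example 02).")
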