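# calnet — collective calcium signaling in coupled cell networks

`calnet` simulates histamine-induced calcium dynamics in networks of
endothelial cells coupled by gap junctions, and quantifies the resulting
traces the way calcium-imaging recordings are scored.  It is built for the
question of *cellular architecture*: why do cells arranged in capillary-like
strands fire repetitive calcium spikes under an agonist while the very same
cells, isolated or packed into a monolayer, produce only a single transient?

## The model

Each cell carries five states — cytosolic calcium `c` (μM), store calcium
`s` (μM), membrane potential `v` (mV), the open probability `w` of
Ca²⁺-activated K⁺ channels, and IP₃ concentration `I` (μM) — with the
classic flux set of coupled vascular-cell models:

```
dc/dt = J_IP3R − J_SERCA + J_CICR − K·c + L·s − J_VOCC + J_NaCa + J_coupling
ds/dt = J_SERCA − J_CICR − L·s
dv/dt = γ·(−J_NaK − J_Cl − 2·J_VOCC − J_NaCa − J_K) + V_coupling
dw/dt = λ·(K_act(c, v) − w)
dI/dt = J_PLC − k_deg·I
```

with Hill-type IP₃-receptor release `F·I²/(K_r²+I²)`, SERCA uptake
`B·c²/(c_b²+c²)`, calcium-induced calcium release
`V_m3 · s²/(s_c²+s²) · c⁴/(c_c⁴+c⁴)`, linear plasma-membrane extrusion
`K·c`, and sigmoidal voltage-gated Ca²⁺ entry.  The agonist (histamine)
level maps onto the pair `(K, V_m3)` through four registered presets —
rising dose weakens extrusion and strengthens CICR — plus a step in the
PLC-driven IP₃ production `J_PLC` at agonist addition.

Cells are coupled along the edges of an explicit topology (pair, periodic
chain, clique, periodic Moore-lattice monolayer, honeycomb, strip, or a
custom edge list) by an electrical coupling current
`−(g/C_m)·Σ(v_i−v_j)` and gap-junctional calcium diffusion
`−D·Σ(c_i−c_j)`.  Strong electrical coupling removes the
membrane-potential feedback that stabilizes each cell's CICR autocatalysis
— a network mode grows and ignites sustained, cell-offset calcium spikes —
while calcium diffusion re-stabilizes the network in proportion to the
number of neighbors.  Oscillations therefore live in sparsely connected
architectures and die in densely connected ones; with the default coupling
they vanish when seven or more cells are fully coupled.

Trace quantification follows the standard imaging conventions: F/F₀
normalization against a pre-stimulus median, spike calling at a strict
peak-to-baseline ratio of 3 with a re-arm de-bounce, oscillation defined as
≥ 2 spikes, the half-decay time of the initial transient and its
reciprocal decay rate, and the first interspike interval.  A synthetic
generator renders 5-minute, 1–2 Hz fluorescence recordings with exactly
known ground truth (spike times, amplitudes, half-decays, planted
oscillating fraction) for validating every stage.

## Worked example

```
$ python examples/02_architecture_dependence.py
condition  n_cells  occurrence_pct  sync_index
   single        2             0.0         NaN
    ring9       18           100.0    0.579194
 torus3x3       18             0.0    1.000000
```

Eighteen cells pooled over two seeded replicates per architecture, all at
the highest agonist preset: isolated cells never oscillate (0 %), every
cell of the 9-cell periodic chain oscillates (100 %), and the 9-cell
periodic Moore monolayer — eight neighbors per cell — is fully quenched
(0 %).  The chain's synchronization index of 0.58 shows neighbors spiking
at offset times rather than in lockstep.  The gap-junction-blocker control
(`examples/03_coupling_knockout.py`) zeroes both coupling strengths and
collapses a 100 %-oscillating ring to 0 %, with every cell's trajectory
matching an isolated run to ~10⁻⁸ μM.

The other examples cover the single-cell dose response
(`01_single_cell_dose_response.py`) and synthetic-trace round-tripping
(`04_synthetic_trace_analysis.py`).  A thin CLI mirrors the library:
`calnet simulate`, `calnet sweep {dose|architecture|clique|coupling|strip}`,
`calnet analyze`, `calnet synth`.

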