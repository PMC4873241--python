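# Methods

## Model

Each cell is a single well-mixed compartment with five states: cytosolic
free calcium `c` (μM), store (ER/SR) calcium `s` (μM), membrane potential
`v` (mV), the open probability `w` of Ca²⁺-activated K⁺ channels
(dimensionless), and IP₃ concentration `I` (μM).  The flux set is the
classic coupled vascular-cell formulation: Hill-type IP₃-receptor release
`F·I²/(K_r²+I²)`; SERCA uptake `B·c²/(c_b²+c²)`; calcium-induced calcium
release (CICR) `V_m3 · s²/(s_c²+s²) · c⁴/(c_c⁴+c⁴)`; linear PMCA extrusion
`K·c` (no voltage dependence); store leak `L·s`; sigmoidal voltage-gated
Ca²⁺ entry; Na⁺/Ca²⁺ exchange `G_NaCa · c/(c+c_NaCa) · (v−v_NaCa)`; a
constant Na⁺-K⁺-ATPase flux; Cl⁻ and Ca²⁺-activated K⁺ currents.  Membrane
currents are written as equivalent calcium fluxes (μM·mV⁻¹·s⁻¹
conductances) and scaled into mV/s by the factor `γ`.

The agonist enters in two ways: the preset pair `(K, V_m3)` — (1, 300),
(0.75, 400), (0.5, 500), (0.1, 600) in s⁻¹ for ordinal levels 1–4, rising
histamine weakening extrusion and strengthening CICR — and a step of the
PLC-driven IP₃ production `J_PLC` from a resting 0.05 μM/s to a stimulated
0.3347 μM/s at agonist addition.  The resting parameter set is the level-1
machinery with resting `J_PLC`; protocols switch parameters at exact event
times (integration restarts at each switch), because pipette agonist
addition is effectively a step.

### Intercellular coupling

Cells are coupled along explicit graph edges by two gap-junctional terms:
an electrical coupling current `−(g/C_m)·Σ_j (v_i − v_j)` and calcium
diffusion `−D·Σ_j (c_i − c_j)`.  `g` is stated in μS/cm² and converted to a
rate with a membrane specific capacitance of 1 μF/cm², so the coupled value
of 1000 μS/cm² acts as 1000 s⁻¹; uncoupled is 0.  IP₃ is not exchanged
through gap junctions.  Both terms are pairwise antisymmetric, so diffusion
conserves total network calcium exactly and the voltage inputs sum to zero.

### Why architecture matters (mechanism)

At the high-agonist preset the isolated cell is excitable but stable: its
CICR autocatalysis (`∂ċ/∂c > 0` near the operating point) is held in check
by a membrane feedback loop — elevated calcium opens Ca²⁺-activated K⁺
channels, the membrane hyperpolarizes, and voltage-gated entry and
exchanger fluxes pull calcium back down.  Strong electrical coupling clamps
neighboring membrane potentials together, which *removes exactly this
stabilizing loop* from every desynchronizing network mode (a mode with
graph-Laplacian eigenvalue μ sees the single-cell Jacobian minus
`diag(μD, 0, μg/C_m, 0, 0)`).  Modes with large `μ·g` but small `μ·D` are
therefore unstable: seeded cell-to-cell variability grows into sustained,
large-amplitude, cell-offset calcium spikes.  Calcium diffusion acts the
opposite way — `μ·D` re-stabilizes the mode — and on a clique of n cells
every desynchronizing mode has μ = n, so the instability window closes at a
sharp clique size.  With the defaults the critical `μ·D` is ≈ 0.68, putting
the extinction threshold between n = 6 (6·D = 0.63, unstable) and n = 7
(7·D = 0.735, stable).  Sparse architectures (chains: μ ≤ 4) stay unstable
and oscillate; dense ones (9-cell Moore monolayer: μ = 9) are quenched.

## Parameters

Printed, externally fixed values: the four `(K, V_m3)` preset pairs and the
electrical coupling strengths 0 / 1000 μS/cm².  Everything else is a
package default recorded in `src/calnet/data/parameters.json` (every key
carries its unit).  The default set descends from the published
coupled-cell lineage but was re-fit once, because the lineage constants
combined with the preset-scale `V_m3` of 300–600 s⁻¹ do not reproduce the
architecture dependence that defines this system.  The calibration targets
were the printed qualitative behaviors: a single agonist transient with no
oscillation in isolated cells at the high preset; sustained irregular
oscillations in electrically coupled pairs at g = 1000 μS/cm²; extinction
of the oscillations when seven or more cells are fully coupled; silence
under the gap-junction-blocker transform.  The notable departures from the
lineage values are a near-saturated SERCA (`B` = 0.67 μM/s, `c_b` = 0.25
μM — a small slope at the operating point), a stronger Na⁺/Ca²⁺ exchanger
(`G_NaCa` = 0.049) and Ca²⁺-activated K⁺ conductance (`G_K` = 0.018), and a
more sensitive K-channel activation (`β` = 0.017 μM²); these place the
high-agonist operating point just below the CICR knee with the membrane
loop as the decisive stabilizer.

The calcium-diffusion default `D` = 0.105 s⁻¹ is the one coupling constant
the printed material does not pin down; it is set so that diffusive
stabilization closes the instability window between 6 and 7 fully coupled
cells, and it is an explicit config value everywhere (the coupling sweep
exposes the full (g, D) plane).

## Simulation protocol

Runs draw initial states as the resting steady state (found by damped
root-finding seeded from a long relaxation; residual tolerance 10⁻⁸)
perturbed by seeded multiplicative jitter, 5 % by default — the minimal
stand-in for natural cell-to-cell variability, and the symmetry-breaking
seed the network instability amplifies.  A 60-s pre-stimulus window
precedes agonist onset: long enough for the 20-s baseline used by the trace
pipeline, short enough that the seeded variability has not been damped away
by coupling before the stimulus arrives.  Recording then spans 300 s (the
5-minute imaging window) sampled at 0.5 s.  Integration uses LSODA with
relative tolerance 10⁻⁶ and per-state absolute tolerances; runs are
bit-reproducible for a fixed seed.

Numerical caveat: on architectures inside the instability window the
desynchronizing mode amplifies *any* perturbation, including integrator
rounding noise.  Zero-jitter symmetry checks are therefore run at tight
tolerance (rtol 10⁻¹⁰) and on windows short enough that amplified rounding
stays below 10⁻⁶ μM; the same applies to the decoupled-equivalence
comparison, where adaptive step-size differences between a network run and
an isolated rerun play the role of the perturbation.

## Trace quantification

Signals (simulated calcium rendered through a saturating indicator
transform `F ∝ c/(c+K_d)`, K_d = 1 μM, or synthetic/imported fluorescence)
are normalized to the median of the 20 s before onset.  A spike is a local
maximum of the 3-sample running-median-smoothed signal whose
peak-to-baseline ratio strictly exceeds 3; consecutive spikes must be
separated by a return below baseline + 50 % of the threshold excess
(the de-bounce that separates spikes from small rapid fluctuations).  Spike
times are localized on the rising edge (interpolated 90 %-of-peak crossing)
— far more noise-robust than the flat decay top.  The half-decay time runs
from the post-rise peak to the interpolated crossing of baseline + half the
peak excess, with a second pass that re-estimates the amplitude from
droop-corrected early-decay samples (one sample's noise otherwise leaks
into the half level); the decay rate is its reciprocal.  Oscillation is ≥ 2
spikes; occurrence is the percentage of oscillating cells; undefined
metrics propagate as explicit absences, never zeros.  A synchronization
index (fraction of spikes with a partner within 2 s in a neighboring cell)
quantifies coordination.

The indicator saturation matters for amplitudes: concentration excursions
spanning an order of magnitude compress into near-uniform F/F₀ peak ratios,
which is why measured spike amplitudes are insensitive to the agonist dose.

## Synthetic recordings

The generator plants transients with a 2-s linear rise and an exponential
fall calibrated so the measured half-decay equals the planted value,
multiplies by `(1 + σ·N(0,1))` noise (default σ = 2 %) and a slow
sinusoidal drift (2 % amplitude, 200 s period, a stand-in for
photobleaching/focus drift), at 2 Hz for 300 s.  Oscillating cells get an
onset pulse plus ≥ 2 irregular follow-up spikes; non-oscillating cells one
prolonged transient.  The planted oscillating fraction is exact-count (a
seeded shuffle of a fixed number of labels), which makes occurrence
recovery a deterministic check.  What passing recovery tests show is that
the pipeline is faithful on data whose ground truth is known and whose
noise is well-behaved multiplicative Gaussian; they do not certify
performance on motion artifacts, focus jumps, or saturating-camera
nonlinearities, which the generator deliberately does not model.

Measured recovery at σ = 2 % (n = 200 cells): planted occurrence exact,
spike times within one sample, mean half-decay error ≈ 4–5 % (the
first-crossing rule is noise-biased; at σ = 5 % the mean error grows to
≈ 9 %), zero false-positive spikes on spike-free traces.

## Design choices and limitations

* **Dose response.**  Under this calibration isolated cells do not
  oscillate at *any* preset; the lower presets produce only subthreshold
  responses.  The lineage's low-dose single-cell oscillation regime and the
  coupling-driven architecture dependence could not be realized with a
  single constant set in this formulation; the calibration deliberately
  favors the architecture dependence, which is the phenomenon this package
  exists to reproduce.  The dose sweep still exposes the high-dose
  contract (single prolonged transient, 0 % occurrence) and near-uniform
  response amplitudes.
* **Decay-time scale.**  The simulated initial transient clears within
  seconds, much faster than the tens-of-seconds half-decays of recorded
  fluorescence (which fold in dye kinetics and cellular buffering not
  modeled here).  Half-decay statistics on simulated traces are therefore
  internally consistent but not comparable in absolute scale to recordings;
  the synthetic generator, which plants realistic half-decays directly, is
  the validation path for the decay metrics.
* **Coordination.**  Coupled-cell spikes are offset but more temporally
  coordinated (synchronization index ≈ 0.5–0.9) than the visually
  unsynchronized recordings; the index is reported, not asserted against.
* Heterogeneity is initial-condition jitter only by default; an optional
  per-cell parameter-jitter switch additionally scales each cell's
  agonist-sensitive gains (F, V_m3) by a seeded factor.
* **Strips.**  Linear patterns of growing width do not extinguish in the
  model the way wide patterned lines do in experiments: an extended lattice
  always retains long-wavelength (small-μ) desynchronizing modes below the
  diffusive stabilization threshold, so occurrence stays high at every
  width.  The extinction mechanism is specific to compact, densely coupled
  clusters (cliques / the periodic Moore monolayer), suggesting the real
  wide-pattern decline involves additional damping not captured here.
* Single-compartment cytosol, deterministic channel gating, no
  receptor-level agonist binding, no dynamic gap-junction gating by calcium
  or phosphorylation, no mechanical coupling.
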