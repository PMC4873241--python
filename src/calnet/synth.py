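"""Synthetic fluorescence recordings with known ground truth.

Emulates 5-minute Fluo-3 time-lapse data sampled at ~1–2 frames/s: a flat
pre-stimulus baseline, an abrupt agonist-addition transient, optional
subsequent spikes of near-uniform amplitude, multiplicative Gaussian noise
and a slow sinusoidal baseline drift (a stand-in for photobleaching/focus
drift).  Each planted transient has a fast linear rise (~2 s) and an
exponential fall whose rate is calibrated so the measured half-decay time
equals the planted value exactly, making the generator a round-trip oracle
for the trace-metrics pipeline.

Populations are planted with an exact-count oscillating fraction: an
"oscillating" cell receives an initial pulse plus ≥ 2 irregular subsequent
spikes; a "non-oscillating" cell receives one prolonged transient.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .metrics import Trace

__all__ = [
    "TransientSpec",
    "CellSpec",
    "SyntheticSpec",
    "generate_trace",
    "generate_population",
    "population_to_csv",
    "ground_truth_frame",
]

RISE_S = 2.0  #: linear rise time of a planted transient (s)


class SpecError(ValueError):
    """Invalid synthetic-data specification."""


@dataclass(frozen=True)
class TransientSpec:
    """One planted calcium transient.

    ``peak_ratio`` is the peak-to-baseline ratio (dimensionless, > 1);
    ``half_decay_s`` the time for the excess over baseline to halve.
    """

    time_s: float
    peak_ratio: float
    half_decay_s: float

    def __post_init__(self):
        if self.peak_ratio <= 1.0:
            raise SpecError("peak_ratio must exceed 1 (baseline)")
        if self.half_decay_s <= 0:
            raise SpecError("half_decay_s must be positive")


@dataclass(frozen=True)
class CellSpec:
    """Ground truth for one cell: archetype plus its planted transients."""

    archetype: str                     # "oscillating" | "single_transient" | "flat"
    transients: tuple[TransientSpec, ...] = ()


@dataclass(frozen=True)
class SyntheticSpec:
    """Recording geometry and noise model for a synthetic population.

    Defaults mirror the imaging protocol the generator emulates: 300 s
    recording at 2 Hz with stimulus onset at 30 s; multiplicative Gaussian
    noise of fractional σ ``noise_sigma``; sinusoidal drift of fractional
    amplitude ``drift_amplitude`` and period ``drift_period_s``.
    """

    duration_s: float = 300.0
    sampling_hz: float = 2.0
    onset_s: float = 30.0
    noise_sigma: float = 0.02
    drift_amplitude: float = 0.02
    drift_period_s: float = 200.0
    seed: int = 0

    def __post_init__(self):
        n = self.duration_s * self.sampling_hz
        if abs(n - round(n)) > 1e-9:
            raise SpecError("sampling_hz * duration_s must be an integer")
        if not (0 <= self.onset_s < self.duration_s):
            raise SpecError("onset_s must lie inside the recording")
        if self.noise_sigma < 0 or self.drift_amplitude < 0:
            raise SpecError("noise and drift amplitudes must be >= 0")

    @property
    def time(self) -> np.ndarray:
        n = int(round(self.duration_s * self.sampling_hz))
        return np.arange(n) / self.sampling_hz

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "SyntheticSpec":
        return cls(**json.loads(s))


def _clean_signal(spec: SyntheticSpec, cell: CellSpec) -> np.ndarray:
    """Noise-free baseline-1 signal with the planted transients."""
    t = spec.time
    y = np.ones_like(t)
    last_end = -np.inf
    for tr in sorted(cell.transients, key=lambda x: x.time_s):
        if tr.time_s < spec.onset_s:
            raise SpecError("planted transients must come after the onset")
        if tr.time_s - last_end < RISE_S:
            raise SpecError(
                f"transients at {last_end:.1f}s and {tr.time_s:.1f}s overlap "
                f"within the {RISE_S}s rise time"
            )
        last_end = tr.time_s
        amp = tr.peak_ratio - 1.0
        k = np.log(2.0) / tr.half_decay_s
        rise = (t >= tr.time_s - RISE_S) & (t < tr.time_s)
        fall = t >= tr.time_s
        y[rise] += amp * (1.0 - (tr.time_s - t[rise]) / RISE_S)
        y[fall] += amp * np.exp(-k * (t[fall] - tr.time_s))
    return y


def generate_trace(spec: SyntheticSpec, cell: CellSpec,
                   rng: np.random.Generator | None = None) -> Trace:
    """Render one cell: clean signal × (1 + noise) × (1 + drift).

    Deterministic for a given ``spec.seed`` (or a supplied generator).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    t = spec.time
    y = _clean_signal(spec, cell)
    if spec.drift_amplitude > 0:
        y = y * (1.0 + spec.drift_amplitude
                 * np.sin(2 * np.pi * t / spec.drift_period_s))
    if spec.noise_sigma > 0:
        y = y * (1.0 + spec.noise_sigma * rng.standard_normal(t.shape))
    return Trace(t, y, onset=spec.onset_s, source="synthetic")


def _oscillating_cell(spec: SyntheticSpec, rng: np.random.Generator,
                      *, peak_ratio: float, half_decay_s: float,
                      n_extra: int, base_interval_s: float,
                      interval_jitter: float) -> CellSpec:
    """Initial pulse + ≥ 2 irregular subsequent spikes."""
    times = [spec.onset_s + RISE_S]
    for _ in range(n_extra):
        gap = base_interval_s * (1.0 + interval_jitter * (rng.random() - 0.5))
        times.append(times[-1] + gap)
    trs = tuple(
        TransientSpec(tt, peak_ratio * (1.0 + 0.05 * (rng.random() - 0.5)),
                      half_decay_s)
        for tt in times if tt < spec.duration_s - RISE_S
    )
    if len(trs) < 3:
        raise SpecError("oscillating archetype needs >= 3 transients inside "
                        "the recording; lengthen the recording or shorten the "
                        "interval")
    return CellSpec("oscillating", trs)


def generate_population(
    n_cells: int,
    occurrence: float,
    spec: SyntheticSpec | None = None,
    *,
    peak_ratio: float = 5.0,
    half_decay_osc_s: float = 12.0,
    half_decay_single_s: float = 80.0,
    n_extra_spikes: int = 3,
    base_interval_s: float = 45.0,
    interval_jitter: float = 0.4,
) -> tuple[list[Trace], list[CellSpec]]:
    """Seeded population with an exact-count planted oscillating fraction.

    ``round(occurrence * n_cells)`` cells get the oscillating archetype
    (short initial pulse, ``n_extra_spikes`` irregular follow-ups with
    half-decay ``half_decay_osc_s``); the rest get a single prolonged
    transient (half-decay ``half_decay_single_s``).  Assignment order is a
    seeded shuffle; the planted count is deterministic, not Bernoulli.
    """
    if not (0.0 <= occurrence <= 1.0):
        raise SpecError("occurrence must lie in [0, 1]")
    if spec is None:
        spec = SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    n_osc = int(round(occurrence * n_cells))
    flags = np.zeros(n_cells, dtype=bool)
    flags[:n_osc] = True
    rng.shuffle(flags)
    traces, cells = [], []
    for i in range(n_cells):
        if flags[i]:
            cell = _oscillating_cell(
                spec, rng, peak_ratio=peak_ratio,
                half_decay_s=half_decay_osc_s, n_extra=n_extra_spikes,
                base_interval_s=base_interval_s,
                interval_jitter=interval_jitter)
        else:
            cell = CellSpec("single_transient", (
                TransientSpec(spec.onset_s + RISE_S, peak_ratio,
                              half_decay_single_s),))
        traces.append(generate_trace(spec, cell, rng))
        cells.append(cell)
    return traces, cells


def population_to_csv(traces: list[Trace], path_or_buffer) -> None:
    """Write the trace-CSV format consumed by :mod:`calnet.metrics`."""
    df = pd.DataFrame({"time_s": traces[0].time})
    for i, tr in enumerate(traces):
        df[f"cell{i}"] = tr.signal
    df.to_csv(path_or_buffer, index=False)


def ground_truth_frame(cells: list[CellSpec]) -> pd.DataFrame:
    """Ground-truth table: cell, archetype, spike times, ratios, half-decay."""
    rows = []
    for i, c in enumerate(cells):
        rows.append({
            "cell": i,
            "archetype": c.archetype,
            "n_transients": len(c.transients),
            "spike_times_s": " ".join(f"{t.time_s:g}" for t in c.transients),
            "peak_ratios": " ".join(f"{t.peak_ratio:g}" for t in c.transients),
            "half_decays_s": " ".join(f"{t.half_decay_s:g}" for t in c.transients),
        })
    return pd.DataFrame(rows)
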