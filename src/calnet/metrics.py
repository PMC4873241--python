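"""Quantification of calcium traces: normalization, spike calling,
oscillation classification, decay and interval statistics.

The procedures mirror how Fluo-3 time-lapse recordings are scored:

* the raw signal is normalized to the median of a pre-stimulus window
  (F/F₀, so the baseline sits at 1);
* a local maximum counts as a calcium spike when its peak-to-baseline ratio
  strictly exceeds 3 (small repetitive fluctuations are excluded by a re-arm
  rule: after a spike the signal must first fall back below
  ``baseline + 0.5*(threshold-1)*baseline`` before a new spike can be
  called);
* a cell is classified as oscillating when it fires two or more spikes;
* the half-decay time of the initial spike is the time for the signal to
  fall to baseline plus half the peak excess, and the decay rate is its
  reciprocal;
* the first interspike interval estimates the oscillation period.

Undefined quantities (no spikes, plateau above the half level) are carried
as ``None`` and excluded from population summaries, never coerced to zero.

The same functions apply unchanged to simulated cytosolic-calcium
trajectories and to (synthetic or imported) fluorescence recordings, because
every statistic is a ratio to the trace's own baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "Trace",
    "TraceMetrics",
    "normalize",
    "detect_spikes",
    "classify_oscillation",
    "half_decay",
    "first_interval",
    "occurrence_rate",
    "synchronization_index",
    "analyze_trace",
    "analyze_population",
    "read_trace_csv",
    "population_summary",
    "RATIO_THRESHOLD",
    "BASELINE_WINDOW_S",
]

#: Spike threshold: peak-to-baseline ratio must strictly exceed this.
RATIO_THRESHOLD = 3.0
#: Default pre-onset window used for the baseline estimate (s).
BASELINE_WINDOW_S = 20.0


class TraceError(ValueError):
    """Invalid trace input (non-increasing time, missing baseline window...)."""


@dataclass(frozen=True)
class Trace:
    """A single-cell intensity or concentration time series.

    ``signal`` may be raw fluorescence (a.u.), normalized F/F₀, or cytosolic
    calcium (μM); ``onset`` is the stimulus-addition time on the same clock
    as ``time``.
    """

    time: np.ndarray
    signal: np.ndarray
    onset: float = 0.0
    source: str = "imported"
    normalized: bool = False

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        y = np.asarray(self.signal, dtype=float)
        if t.ndim != 1 or y.shape != t.shape:
            raise TraceError("time and signal must be 1-D arrays of equal length")
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise TraceError("time must be strictly increasing with >= 2 samples")
        if not np.all(np.isfinite(y)):
            raise TraceError("signal contains non-finite values")
        if not (t[0] <= self.onset <= t[-1]):
            raise TraceError("onset must lie within the recorded time span")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "signal", y)

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.time)))


@dataclass(frozen=True)
class TraceMetrics:
    """Per-trace quantification results.

    ``half_decay_s`` and ``decay_rate_per_s`` are reciprocal companions and
    are defined (non-None) together.  ``first_interval_s`` requires at least
    two spikes.  ``oscillating`` is ``spike count >= 2``.
    """

    baseline: float
    spike_times: tuple[float, ...] = ()
    spike_amplitudes: tuple[float, ...] = ()
    half_decay_s: float | None = None
    decay_rate_per_s: float | None = None
    first_interval_s: float | None = None

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times)

    @property
    def oscillating(self) -> bool:
        return self.n_spikes >= 2


def normalize(trace: Trace, *, baseline_window_s: float = BASELINE_WINDOW_S,
              min_samples: int = 10) -> Trace:
    """Divide by the median of the pre-onset window, giving F/F₀.

    The baseline is the median of the samples in
    ``[onset - baseline_window_s, onset)`` (the median resists the sharp
    onset transient).  Raises :class:`TraceError` when fewer than
    ``min_samples`` pre-onset samples exist.
    """
    pre = (trace.time < trace.onset) & (trace.time >= trace.onset - baseline_window_s)
    if pre.sum() < min_samples:
        raise TraceError(
            f"need >= {min_samples} pre-onset samples for the baseline; "
            f"found {int(pre.sum())}"
        )
    f0 = float(np.median(trace.signal[pre]))
    if f0 <= 0:
        raise TraceError("baseline must be positive for F/F0 normalization")
    return Trace(trace.time, trace.signal / f0, trace.onset, trace.source,
                 normalized=True)


def _median_smooth(y: np.ndarray, width: int) -> np.ndarray:
    if width <= 1 or y.size < width:
        return y
    from scipy.ndimage import median_filter

    return median_filter(y, size=width, mode="nearest")


def detect_spikes(trace: Trace, ratio_threshold: float = RATIO_THRESHOLD,
                  *, rearm_fraction: float = 0.5, smooth_samples: int = 3
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Spike times and peak-to-baseline amplitudes on a normalized trace.

    A local maximum is a spike when its ratio to baseline strictly exceeds
    ``ratio_threshold``.  Consecutive spikes must be separated by a return
    below the re-arm level ``1 + rearm_fraction*(ratio_threshold - 1)``;
    maxima violating the re-arm rule are merged into the preceding spike
    (the larger peak wins).  Only post-onset samples are searched.

    Detection runs on a ``smooth_samples``-wide running-median copy of the
    signal (default 3 samples), which suppresses single-sample noise
    excursions and biases measured amplitudes slightly downward — the strict
    threshold therefore stays conservative under noise.  Set
    ``smooth_samples=1`` to score the raw samples.
    """
    if not trace.normalized:
        raise TraceError("detect_spikes expects a normalized trace (F/F0)")
    sel = trace.time >= trace.onset
    t = trace.time[sel]
    y = _median_smooth(trace.signal[sel], smooth_samples)
    if t.size < 3:
        return np.array([]), np.array([])
    # candidate local maxima above threshold (strict)
    idx, _ = find_peaks(y)
    # include an endpoint maximum: a spike still rising at the last sample
    if y.size >= 2 and y[-1] > y[-2]:
        idx = np.append(idx, y.size - 1)
    idx = idx[y[idx] > ratio_threshold]
    if idx.size == 0:
        return np.array([]), np.array([])
    rearm = 1.0 + rearm_fraction * (ratio_threshold - 1.0)
    kept: list[int] = []
    for k in idx:
        if not kept:
            kept.append(int(k))
            continue
        seg = y[kept[-1]: k + 1]
        if seg.min() < rearm:
            kept.append(int(k))
        elif y[k] > y[kept[-1]]:        # same event, keep the larger peak
            kept[-1] = int(k)
    kept_arr = np.array(kept, dtype=int)
    # Localize each spike on its rising edge: the time where the raw signal
    # first crosses 90 % of the peak excess (linearly interpolated).  The
    # rise is the sharpest feature of a calcium transient, so this is far
    # more noise-robust than the flat decay top, where sample noise shifts
    # the argmax by whole samples.
    raw = trace.signal[sel]
    times = np.empty(kept_arr.size)
    for j, k in enumerate(kept_arr):
        level = 1.0 + 0.9 * (y[k] - 1.0)
        start = kept_arr[j - 1] if j > 0 else 0
        below = np.nonzero(raw[start:k + 1] < level)[0]
        if below.size == 0 or below[-1] + start == k:
            times[j] = t[k]
            continue
        m = below[-1] + start
        frac = (level - raw[m]) / (raw[m + 1] - raw[m])
        times[j] = t[m] + frac * (t[m + 1] - t[m])
    return times, y[kept_arr]


def classify_oscillation(spike_times: np.ndarray) -> bool:
    """True iff the trace fired two or more calcium spikes."""
    return len(spike_times) >= 2


def half_decay(trace: Trace, spike_times: np.ndarray,
               spike_amplitudes: np.ndarray, *, smooth_samples: int = 3
               ) -> tuple[float | None, float | None]:
    """Half-decay time (s) of the initial spike and its reciprocal (s⁻¹).

    Measured from the first spike's peak until the normalized signal first
    falls to ``1 + (amplitude - 1)/2``.  Returns ``(None, None)`` when there
    is no spike or the signal plateaus above the half level for the rest of
    the trace.  The crossing time is linearly interpolated between samples;
    the crossing is detected on the same running-median smoothing as spike
    detection so sample noise does not trigger systematically early
    crossings.
    """
    if len(spike_times) == 0:
        return None, None
    if not trace.normalized:
        raise TraceError("half_decay expects a normalized trace")
    a0 = float(spike_amplitudes[0])
    half_level = 1.0 + 0.5 * (a0 - 1.0)
    after = trace.time >= float(spike_times[0])
    t = trace.time[after]
    y = _median_smooth(trace.signal[after], smooth_samples)
    # anchor at the peak itself: spike times mark the rising edge, the decay
    # clock starts at the maximum shortly after it
    peak_window = t <= t[0] + 5.0
    k0 = int(np.argmax(y[peak_window]))
    t = t[k0:]
    y = y[k0:]
    t0 = float(t[0])
    below = np.nonzero(y <= half_level)[0]
    if below.size == 0:
        return None, None
    k = int(below[0])
    if k == 0:
        t_half = t[0]
    else:
        # crossing time from a short local regression around the first
        # crossing sample (averages sample noise instead of trusting one
        # interpolation pair)
        lo = max(0, k - 2)
        hi = min(t.size, k + 3)
        tt, yy = t[lo:hi], y[lo:hi]
        slope, icpt = np.polyfit(tt, yy, 1)
        if slope < 0:
            t_half = (half_level - icpt) / slope
            t_half = min(max(t_half, t[k - 1]), t[k])
        else:
            frac = (y[k - 1] - half_level) / (y[k - 1] - y[k])
            t_half = t[k - 1] + frac * (t[k] - t[k - 1])
    dt_half = float(t_half - t0)
    if dt_half <= 0:
        return None, None

    # second pass: the measured peak carries one sample's noise, which maps
    # into the half level and hence the crossing.  Average several early
    # decay samples, each corrected for the expected exponential droop using
    # the first-pass rate, to get a lower-noise amplitude, then re-locate
    # the crossing against the refined half level.
    k1 = np.log(2.0) / dt_half
    early = (t >= t0) & (t <= t0 + min(3.0 * np.median(np.diff(t)), dt_half / 2))
    if early.sum() >= 3:
        corrected = 1.0 + (y[early] - 1.0) * np.exp(k1 * (t[early] - t0))
        a_ref = float(np.mean(corrected))
        if a_ref > 1.0:
            half_ref = 1.0 + 0.5 * (a_ref - 1.0)
            below = np.nonzero(y <= half_ref)[0]
            if below.size and below[0] > 0:
                k = int(below[0])
                lo = max(0, k - 2)
                hi = min(t.size, k + 3)
                slope, icpt = np.polyfit(t[lo:hi], y[lo:hi], 1)
                if slope < 0:
                    t2 = (half_ref - icpt) / slope
                    t2 = min(max(t2, t[k - 1]), t[k])
                    dt2 = float(t2 - t0)
                    if dt2 > 0:
                        dt_half = dt2
    return dt_half, 1.0 / dt_half


def first_interval(spike_times: np.ndarray) -> float | None:
    """Time between the first two spikes (s); ``None`` with < 2 spikes."""
    if len(spike_times) < 2:
        return None
    return float(spike_times[1] - spike_times[0])


def occurrence_rate(metrics: list[TraceMetrics]) -> float:
    """Percentage of traces classified as oscillating (≥ 2 spikes)."""
    if len(metrics) == 0:
        raise TraceError("occurrence_rate needs at least one trace")
    return 100.0 * sum(m.oscillating for m in metrics) / len(metrics)


def synchronization_index(spike_trains: list[np.ndarray],
                          *, window_s: float = 2.0,
                          pairs: list[tuple[int, int]] | None = None
                          ) -> float | None:
    """Mean pairwise spike-time coincidence in [0, 1].

    For each pair of trains the coincidence is the fraction of spikes (of
    the union) that have a partner in the other train within ``window_s``.
    Identical trains score 1; trains with no coincident spikes score 0;
    independent trains score near the chance level.  ``pairs`` restricts the
    average to given index pairs (e.g. topology neighbors); default is all
    pairs.  Returns ``None`` when fewer than two trains have spikes.
    """
    trains = [np.asarray(s, dtype=float) for s in spike_trains]
    nonempty = [i for i, s in enumerate(trains) if s.size > 0]
    if len(nonempty) < 2:
        return None
    if pairs is None:
        pairs = [(i, j) for a, i in enumerate(nonempty) for j in nonempty[a + 1:]]
    else:
        pairs = [(i, j) for (i, j) in pairs
                 if trains[i].size > 0 and trains[j].size > 0]
        if not pairs:
            return None
    scores = []
    for i, j in pairs:
        a, b = trains[i], trains[j]
        hit_a = np.array([np.min(np.abs(b - x)) <= window_s for x in a])
        hit_b = np.array([np.min(np.abs(a - x)) <= window_s for x in b])
        scores.append((hit_a.sum() + hit_b.sum()) / (a.size + b.size))
    return float(np.mean(scores))


def analyze_trace(trace: Trace, *, ratio_threshold: float = RATIO_THRESHOLD,
                  baseline_window_s: float = BASELINE_WINDOW_S) -> TraceMetrics:
    """Full per-trace pipeline: normalize → spikes → decay → interval."""
    pre = (trace.time < trace.onset) & (trace.time >= trace.onset - baseline_window_s)
    baseline = float(np.median(trace.signal[pre])) if pre.sum() else float("nan")
    norm = trace if trace.normalized else normalize(
        trace, baseline_window_s=baseline_window_s)
    st, sa = detect_spikes(norm, ratio_threshold)
    hd, dr = half_decay(norm, st, sa)
    return TraceMetrics(
        baseline=baseline if not trace.normalized else 1.0,
        spike_times=tuple(float(x) for x in st),
        spike_amplitudes=tuple(float(x) for x in sa),
        half_decay_s=hd,
        decay_rate_per_s=dr,
        first_interval_s=first_interval(st),
    )


def analyze_population(traces: list[Trace], **kw) -> list[TraceMetrics]:
    return [analyze_trace(tr, **kw) for tr in traces]


def read_trace_csv(path_or_buffer, *, onset: float, source: str = "imported"
                   ) -> list[Trace]:
    """Read the experimental-style trace CSV: first column time (s), one
    column per cell, header row with cell identifiers."""
    # round_trip parsing keeps re-analysis of written traces bit-identical
    df = pd.read_csv(path_or_buffer, float_precision="round_trip")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    return [Trace(t, df[col].to_numpy(dtype=float), onset, source)
            for col in df.columns[1:]]


def metrics_frame(metrics: list[TraceMetrics],
                  cell_ids: list | None = None) -> pd.DataFrame:
    """One row per cell; undefined metrics become NaN in the table (they are
    still excluded from the summary means)."""
    ids = cell_ids if cell_ids is not None else list(range(len(metrics)))
    rows = []
    for cid, m in zip(ids, metrics):
        rows.append({
            "cell": cid,
            "n_spikes": m.n_spikes,
            "oscillating": m.oscillating,
            "first_spike_s": m.spike_times[0] if m.n_spikes else np.nan,
            "amplitude_ratio": m.spike_amplitudes[0] if m.n_spikes else np.nan,
            "half_decay_s": np.nan if m.half_decay_s is None else m.half_decay_s,
            "decay_rate_per_s": (np.nan if m.decay_rate_per_s is None
                                 else m.decay_rate_per_s),
            "first_interval_s": (np.nan if m.first_interval_s is None
                                 else m.first_interval_s),
        })
    return pd.DataFrame(rows)


def population_summary(metrics: list[TraceMetrics]) -> dict:
    """Occurrence rate plus means (± s.e.m.) of defined decay/interval values."""
    rates = [m.decay_rate_per_s for m in metrics if m.decay_rate_per_s is not None]
    ivals = [m.first_interval_s for m in metrics if m.first_interval_s is not None]

    def mean_sem(x):
        if not x:
            return None, None
        x = np.asarray(x, dtype=float)
        sem = float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0
        return float(x.mean()), sem

    dr, dr_sem = mean_sem(rates)
    iv, iv_sem = mean_sem(ivals)
    return {
        "n_cells": len(metrics),
        "occurrence_rate_pct": occurrence_rate(metrics),
        "mean_decay_rate_per_s": dr,
        "sem_decay_rate_per_s": dr_sem,
        "n_decay_defined": len(rates),
        "mean_first_interval_s": iv,
        "sem_first_interval_s": iv_sem,
        "n_interval_defined": len(ivals),
    }
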