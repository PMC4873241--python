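"""Network ODE integration under agonist stimulus protocols.

A run equilibrates the network at resting parameters, applies a stimulus
protocol (a step to an agonist preset, or a train of agonist pulses with
washes), and records all five state variables per cell on a uniform output
grid.  Cell-to-cell desynchronization comes from seeded multiplicative
jitter of the initial states (optionally of per-cell parameters), mirroring
the natural heterogeneity that breaks the symmetry of identical coupled
cells.

Parameter switches are exact events: the integration restarts at each
switch time, so pipette-style agonist addition is a true step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .model import (CellParams, CellState, J_PLC_STIMULATED, NumericalFailure,
                    resting_params, steady_state)
from .network import Topology, coupling_matrices

__all__ = [
    "StimulusProtocol",
    "step_protocol",
    "pulse_protocol",
    "SimulationResult",
    "integrate",
    "network_rhs",
]


@dataclass(frozen=True)
class StimulusProtocol:
    """Piecewise-constant parameter schedule.

    ``segments`` is a sequence of ``(start_time_s, params)`` with strictly
    increasing start times; the first segment must start at 0 (pre-stimulus
    baseline).  ``onset_s`` marks agonist addition (used by trace analysis).
    """

    segments: tuple[tuple[float, CellParams], ...]
    onset_s: float
    kind: str = "custom"

    def __post_init__(self):
        starts = [t for t, _ in self.segments]
        if not starts or starts[0] != 0.0:
            raise ValueError("first protocol segment must start at t=0")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("segment start times must be strictly increasing")

    def params_at(self, t: float) -> CellParams:
        out = self.segments[0][1]
        for start, p in self.segments:
            if t >= start:
                out = p
            else:
                break
        return out

    @property
    def switch_times(self) -> tuple[float, ...]:
        return tuple(t for t, _ in self.segments[1:])


def step_protocol(level: int, *, onset_s: float = 200.0,
                  base: CellParams | None = None,
                  j_plc_stim: float = J_PLC_STIMULATED) -> StimulusProtocol:
    """Agonist step: resting parameters until ``onset_s``, then the preset
    (K, V_m3) with stimulated J_PLC, held for the rest of the run."""
    rest = resting_params(base)
    stim = rest.with_agonist(level, J_PLC=j_plc_stim)
    return StimulusProtocol(((0.0, rest), (onset_s, stim)), onset_s, "step")


def pulse_protocol(pulses: int, pulse_s: float = 30.0, wash_s: float = 60.0,
                   *, level: int = 4, onset_s: float = 200.0,
                   base: CellParams | None = None,
                   j_plc_stim: float = J_PLC_STIMULATED) -> StimulusProtocol:
    """Repeated agonist pulses with washes in between.

    ``pulses`` pulses of ``pulse_s`` seconds separated by ``wash_s`` second
    washes (the last pulse is not followed by a wash segment), emulating
    repetitive pipette application.  Total stimulated span =
    ``pulses*pulse_s + (pulses-1)*wash_s``.
    """
    if pulses < 1 or pulse_s <= 0 or wash_s <= 0:
        raise ValueError("pulses >= 1 and positive durations required")
    rest = resting_params(base)
    stim = rest.with_agonist(level, J_PLC=j_plc_stim)
    segs: list[tuple[float, CellParams]] = [(0.0, rest)]
    t = onset_s
    for k in range(pulses):
        segs.append((t, stim))
        t += pulse_s
        if k < pulses - 1:
            segs.append((t, rest))
            t += wash_s
    segs.append((t, rest))
    return StimulusProtocol(tuple(segs), onset_s, "pulse_train")


@dataclass(frozen=True)
class SimulationResult:
    """Trajectories plus the metadata needed to reproduce the run."""

    time: np.ndarray                    # (T,), seconds
    states: np.ndarray                  # (n_cells, 5, T) in state order c,s,v,w,I
    topology: Topology
    protocol: StimulusProtocol
    seed: int
    init_jitter: float
    rtol: float
    atol: tuple[float, ...]

    @property
    def n_cells(self) -> int:
        return self.states.shape[0]

    def cytosolic_calcium(self) -> np.ndarray:
        """(n_cells, T) cytosolic calcium (μM)."""
        return self.states[:, 0, :]

    def membrane_potential(self) -> np.ndarray:
        return self.states[:, 2, :]

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as h5:
            h5.create_dataset("time", data=self.time)
            gstates = h5.create_group("states")
            for k, name in enumerate(("c", "s", "v", "w", "I")):
                gstates.create_dataset(name, data=self.states[:, k, :])
            meta = h5.create_group("meta")
            meta.attrs["seed"] = self.seed
            meta.attrs["init_jitter"] = self.init_jitter
            meta.attrs["rtol"] = self.rtol
            meta.attrs["topology"] = self.topology.label
            meta.attrs["n_cells"] = self.topology.n_cells
            meta.attrs["protocol"] = self.protocol.kind
            meta.attrs["onset_s"] = self.protocol.onset_s

    def to_frame(self):
        """Long-format DataFrame: time, cell, state, value."""
        import pandas as pd

        frames = []
        for i in range(self.n_cells):
            for k, name in enumerate(("c", "s", "v", "w", "I")):
                frames.append(pd.DataFrame({
                    "time_s": self.time, "cell": i, "state": name,
                    "value": self.states[i, k, :]}))
        return pd.concat(frames, ignore_index=True)


# default absolute tolerances per state unit (c, s, v, w, I)
DEFAULT_ATOL = (1e-9, 1e-9, 1e-6, 1e-9, 1e-9)
DEFAULT_RTOL = 1e-6


def network_rhs(y: np.ndarray, params: CellParams, Lg: np.ndarray,
                LD: np.ndarray, n: int,
                cell_scale: np.ndarray | None = None) -> np.ndarray:
    """Coupled RHS for the flat state vector ``y`` of shape (5n,).

    Layout: cell-major, i.e. ``y[5i:5i+5] = (c, s, v, w, I)`` of cell *i*.
    Vectorized over cells; identical term-by-term to
    :func:`calnet.model.cell_derivatives`.  ``cell_scale`` optionally
    multiplies each cell's agonist-sensitive gains (F, V_m3) — the per-cell
    parameter-heterogeneity switch.
    """
    Y = y.reshape(n, 5)
    c, s, v, w, I = Y[:, 0], Y[:, 1], Y[:, 2], Y[:, 3], Y[:, 4]
    p = params
    sc_ = 1.0 if cell_scale is None else cell_scale
    ipr = sc_ * p.F * I * I / (p.K_r ** 2 + I * I)
    serca = p.B * c * c / (p.c_b ** 2 + c * c)
    cicr = (sc_ * p.V_m3 * (s * s / (p.s_c ** 2 + s * s))
            * (c ** 4 / (p.c_c ** 4 + c ** 4)))
    pmca = p.K * c
    leak = p.L * s
    vocc = p.G_Ca * (v - p.v_Ca1) / (1.0 + np.exp(-(v - p.v_Ca2) / p.R_Ca))
    naca = p.G_NaCa * c / (c + p.c_NaCa) * (v - p.v_NaCa)
    cl_gate = c / (c + p.c_Cl) if p.c_Cl > 0 else 1.0
    cl = p.G_Cl * cl_gate * (v - p.v_Cl)
    kcur = p.G_K * w * (v - p.v_K)
    k_act = ((c + p.c_w) ** 2
             / ((c + p.c_w) ** 2 + p.beta * np.exp(-(v - p.v_Ca3) / p.R_K)))
    dY = np.empty_like(Y)
    dY[:, 0] = ipr - serca + cicr - pmca + leak - vocc + naca - LD @ c
    dY[:, 1] = serca - cicr - leak
    dY[:, 2] = p.gamma * (-p.F_NaK - cl - 2.0 * vocc - naca - kcur) - Lg @ v
    dY[:, 3] = p.lam * (k_act - w)
    dY[:, 4] = p.J_PLC - p.k_deg * I
    return dY.ravel()


def _initial_states(topo: Topology, rest: CellParams, seed: int,
                    init_jitter: float, param_jitter: float) -> tuple[np.ndarray, list[CellParams]]:
    rng = np.random.default_rng(seed)
    ss = steady_state(rest).as_array()
    n = topo.n_cells
    y0 = np.tile(ss, (n, 1))
    if init_jitter > 0:
        y0 = y0 * (1.0 + init_jitter * rng.standard_normal((n, 5)))
        y0[:, 0] = np.abs(y0[:, 0])         # concentrations stay admissible
        y0[:, 1] = np.abs(y0[:, 1])
        y0[:, 4] = np.abs(y0[:, 4])
        y0[:, 3] = np.clip(y0[:, 3], 0.0, 1.0)
    # optional per-cell heterogeneity of the agonist-sensitive machinery
    cell_scale = (1.0 + param_jitter * rng.standard_normal(n)
                  if param_jitter > 0 else None)
    if cell_scale is not None:
        cell_scale = np.abs(cell_scale)
    return y0, cell_scale


def integrate(
    topo: Topology,
    protocol: StimulusProtocol,
    *,
    duration_s: float,
    output_dt_s: float = 0.5,
    seed: int = 0,
    init_jitter: float = 0.05,
    param_jitter: float = 0.0,
    rtol: float = DEFAULT_RTOL,
    atol: tuple[float, ...] = DEFAULT_ATOL,
    method: str = "LSODA",
    initial_states: np.ndarray | None = None,
) -> SimulationResult:
    """Integrate the coupled network under the given protocol.

    Initial states are the unstimulated steady state perturbed by seeded
    multiplicative jitter of relative amplitude ``init_jitter``;
    ``param_jitter`` optionally scales each cell's (F, V_m3) by a seeded
    factor.  ``initial_states`` (shape ``(n_cells, 5)``) overrides the
    jittered draw, e.g. to rerun one cell of a network in isolation from
    the identical starting point.  Output is sampled on a uniform grid of
    spacing ``output_dt_s``.  Reproducible bit-for-bit for a fixed seed.
    """
    if duration_s < protocol.onset_s:
        raise ValueError("duration must cover the protocol onset")
    if output_dt_s <= 0:
        raise ValueError("output_dt_s must be positive")
    n = topo.n_cells
    Lg, LD = coupling_matrices(topo)
    rest = protocol.segments[0][1]
    cell_scale = None
    if initial_states is not None:
        y0 = np.asarray(initial_states, dtype=float)
        if y0.shape != (n, 5):
            raise ValueError(f"initial_states must have shape ({n}, 5)")
        if param_jitter > 0:
            rng = np.random.default_rng(seed)
            cell_scale = np.abs(1.0 + param_jitter * rng.standard_normal(n))
    else:
        y0, cell_scale = _initial_states(topo, rest, seed, init_jitter,
                                         param_jitter)
    t_grid = np.arange(0.0, duration_s + 0.5 * output_dt_s, output_dt_s)
    atol_full = np.tile(np.asarray(atol, dtype=float), n)

    # integrate piecewise between parameter switches
    boundaries = [0.0, *[t for t in protocol.switch_times if t < duration_s],
                  duration_s]
    states = np.empty((len(t_grid), n, 5))
    filled = 0
    y = y0.ravel().copy()
    for a, b in zip(boundaries, boundaries[1:]):
        params = protocol.params_at(a)
        t_eval = t_grid[(t_grid >= a) & (t_grid <= b)]
        sol = solve_ivp(
            lambda t, yy: network_rhs(yy, params, Lg, LD, n, cell_scale),
            (a, b), y, method=method, rtol=rtol, atol=atol_full,
            t_eval=t_eval if t_eval.size else None, dense_output=False)
        if not sol.success:
            raise NumericalFailure(
                f"integration failed at t≈{sol.t[-1] if sol.t.size else a:.1f}s: "
                f"{sol.message}")
        if t_eval.size:
            take = sol.y.T.reshape(-1, n, 5)
            # segment boundaries are shared sample points; overwrite once
            states[filled:filled + take.shape[0]] = take
            filled_new = filled + take.shape[0]
            # the boundary sample b will be recomputed by the next segment
            if b != duration_s and t_eval[-1] == b:
                filled_new -= 1
            filled = filled_new
        y = sol.y[:, -1] if sol.t.size else y
        if not np.all(np.isfinite(y)):
            raise NumericalFailure(f"non-finite state at t={b:.1f}s")
    return SimulationResult(
        time=t_grid, states=states.transpose(1, 2, 0), topology=topo,
        protocol=protocol, seed=seed, init_jitter=init_jitter,
        rtol=rtol, atol=tuple(atol))
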