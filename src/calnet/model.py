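"""Single-cell calcium / membrane-potential dynamics.

The cell carries five state variables:

=====  =============================================  =====
state  meaning                                        units
=====  =============================================  =====
``c``  cytosolic free calcium concentration           μM
``s``  store (ER/SR) calcium concentration            μM
``v``  membrane potential                             mV
``w``  open probability of Ca²⁺-activated K⁺ channel  –
``I``  IP₃ concentration                              μM
=====  =============================================  =====

Fluxes (μM/s unless noted): Hill-type IP₃-receptor release
``F·I²/(K_r²+I²)``; SERCA uptake ``B·c²/(c_b²+c²)``; calcium-induced calcium
release ``V_m3 · s²/(s_c²+s²) · c⁴/(c_c⁴+c⁴)``; linear PMCA extrusion
``K·c``; store leak ``L·s``; sigmoidal voltage-gated Ca²⁺ entry; Na⁺/Ca²⁺
exchange; Na⁺-K⁺-ATPase; Cl⁻ current; Ca²⁺-activated K⁺ current.  Membrane
currents are expressed as equivalent calcium fluxes and scaled into mV/s by
the factor ``γ``.

The agonist (histamine) level is represented by the pair ``(K, V_m3)``
through four registered presets — rising agonist weakens PMCA extrusion and
strengthens CICR — plus the PLC-driven IP₃ production rate ``J_PLC`` which
steps from a small resting value to a stimulated value at agonist addition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from importlib import resources

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import fsolve

__all__ = [
    "CellState",
    "CellParams",
    "flux_set",
    "cell_derivatives",
    "agonist_to_params",
    "resting_params",
    "steady_state",
    "AGONIST_PRESETS",
    "STATE_NAMES",
    "InvalidStateError",
    "ConfigurationError",
    "NumericalFailure",
]

STATE_NAMES = ("c", "s", "v", "w", "I")

#: Agonist presets: ordinal level -> (K [s⁻¹], V_m3 [s⁻¹]).  Level 1 is the
#: lowest histamine concentration, level 4 the highest (5 μM).
AGONIST_PRESETS: dict[int, tuple[float, float]] = {
    1: (1.0, 300.0),
    2: (0.75, 400.0),
    3: (0.5, 500.0),
    4: (0.1, 600.0),
}

#: Guard band for the membrane potential (mV); excursions raise a diagnostic.
V_GUARD = (-100.0, 50.0)


class InvalidStateError(ValueError):
    """A state component is non-finite or outside its admissible range."""


class ConfigurationError(ValueError):
    """Unknown preset or invalid parameter configuration."""


class NumericalFailure(RuntimeError):
    """Root finding or integration failed to converge."""


@dataclass(frozen=True)
class CellState:
    """Per-cell state vector (see module docstring for units)."""

    c: float
    s: float
    v: float
    w: float
    I: float

    def __post_init__(self):
        arr = self.as_array()
        if not np.all(np.isfinite(arr)):
            raise InvalidStateError(f"non-finite state component: {self}")

    def as_array(self) -> np.ndarray:
        return np.array([self.c, self.s, self.v, self.w, self.I], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "CellState":
        return cls(*(float(x) for x in np.asarray(y, dtype=float)))

    def validate(self) -> None:
        """Raise when a component is outside its admissible range."""
        if self.c < 0 or self.s < 0 or self.I < 0:
            raise InvalidStateError(f"negative concentration in {self}")
        if not (0.0 <= self.w <= 1.0):
            raise InvalidStateError(f"gating variable w outside [0,1]: {self.w}")
        if not (V_GUARD[0] <= self.v <= V_GUARD[1]):
            raise InvalidStateError(
                f"membrane potential {self.v} mV outside guard band {V_GUARD}")


@dataclass(frozen=True)
class CellParams:
    """Kinetic constants of the single-cell model.

    ``K`` (PMCA extrusion rate, s⁻¹) and ``V_m3`` (maximal CICR rate, s⁻¹)
    jointly encode the agonist level; the remaining constants are fixed
    machinery.  All rates and conductances must be ≥ 0.  Defaults are the
    package's calibrated registry (see ``data/parameters.json`` and
    docs/methods.md for provenance).
    """

    # agonist-mapped pair
    K: float = 1.0                    # PMCA extrusion rate constant, s⁻¹
    V_m3: float = 300.0               # maximal CICR rate, s⁻¹ scale
    # IP₃ receptor release
    F: float = 0.1810                 # maximal IP₃R release, μM/s
    K_r: float = 0.7841               # IP₃R half-saturation, μM
    # SERCA uptake
    B: float = 0.6707                 # maximal SERCA rate, μM/s
    c_b: float = 0.2546               # SERCA half-saturation, μM
    # CICR half-saturations
    s_c: float = 2.698                # store half-saturation, μM
    c_c: float = 0.6210               # cytosolic half-saturation, μM
    # store leak
    L: float = 0.03168                # leak rate constant, s⁻¹
    # voltage-gated Ca²⁺ channel
    G_Ca: float = 0.001124            # whole-cell conductance, μM·mV⁻¹·s⁻¹
    v_Ca1: float = 100.0              # reversal potential, mV
    v_Ca2: float = -24.0              # half-activation potential, mV
    R_Ca: float = 8.5                 # activation slope, mV
    # Na⁺/Ca²⁺ exchange
    G_NaCa: float = 0.04894           # μM·mV⁻¹·s⁻¹
    c_NaCa: float = 0.3112            # half-saturation, μM
    v_NaCa: float = -30.0             # reversal potential, mV
    # Na⁺-K⁺-ATPase
    F_NaK: float = 0.0432             # constant pump flux, μM/s
    # Cl⁻ channel
    G_Cl: float = 0.006068            # μM·mV⁻¹·s⁻¹
    v_Cl: float = -25.0               # reversal potential, mV
    c_Cl: float = 0.0                 # Ca activation half-saturation, μM (0 = off)
    # K⁺ channel
    G_K: float = 0.01843              # μM·mV⁻¹·s⁻¹
    v_K: float = -94.0                # reversal potential, mV
    # K-channel activation
    c_w: float = 0.0                  # Ca shift of activation, μM
    beta: float = 0.01667             # activation scale, μM²
    v_Ca3: float = -27.0              # voltage shift, mV
    R_K: float = 12.84                # voltage slope, mV
    lam: float = 30.62                # gating relaxation rate, s⁻¹
    # membrane scaling
    gamma: float = 1917.0             # flux → voltage scale, mV/μM
    # IP₃ turnover
    J_PLC: float = 0.3347             # PLC-driven IP₃ production, μM/s
    k_deg: float = 0.1066             # IP₃ degradation rate, s⁻¹

    def __post_init__(self):
        bad = [k for k, x in asdict(self).items()
               if k not in ("v_Ca1", "v_Ca2", "v_NaCa", "v_Cl", "v_K", "v_Ca3")
               and x < 0]
        if bad:
            raise ConfigurationError(f"negative rate/conductance: {bad}")

    def as_dict(self) -> dict:
        return asdict(self)

    def with_agonist(self, level: int, *, J_PLC: float | None = None
                     ) -> "CellParams":
        """Copy with the (K, V_m3) pair of a registered preset."""
        K, V = agonist_to_params(level)
        kw = {"K": K, "V_m3": V}
        if J_PLC is not None:
            kw["J_PLC"] = J_PLC
        return replace(self, **kw)


def load_registry() -> dict:
    """The bundled parameter registry (``data/parameters.json``): the common
    kinetic constants with units in their key names, the four agonist
    presets, the resting block and the coupling defaults."""
    text = (resources.files("calnet") / "data" / "parameters.json").read_text()
    return json.loads(text)


def registry_params(level: int | None = None) -> CellParams:
    """CellParams built from the serialized registry (cross-checks that the
    shipped JSON and the dataclass defaults agree)."""
    reg = load_registry()
    kw = {}
    fields = [f for f in CellParams.__dataclass_fields__
              if f not in ("K", "V_m3", "J_PLC")]
    for key, val in reg["common"].items():
        # longest-prefix match so e.g. F_NaK_uM_per_s resolves to F_NaK, not F
        matches = [f for f in fields if key.startswith(f + "_")]
        if matches:
            kw[max(matches, key=len)] = val
    if level is None:
        block = reg["resting"]
        kw.update(K=block["K_per_s"], V_m3=block["V_m3_per_s"],
                  J_PLC=block["J_PLC_uM_per_s"])
    else:
        block = reg["presets"][str(level)]
        kw.update(K=block["K_per_s"], V_m3=block["V_m3_per_s"],
                  J_PLC=reg["stimulated_J_PLC_uM_per_s"])
    return CellParams(**kw)


def agonist_to_params(level: int) -> tuple[float, float]:
    """(K, V_m3) for an ordinal agonist level 1–4.

    Rising level mimics rising histamine concentration: extrusion K falls,
    CICR gain V_m3 rises.
    """
    try:
        return AGONIST_PRESETS[level]
    except (KeyError, TypeError):
        raise ConfigurationError(
            f"unknown agonist preset {level!r}; registered levels: "
            f"{sorted(AGONIST_PRESETS)}"
        ) from None


#: Stimulated PLC rate used by the step/pulse protocols (μM/s).
J_PLC_STIMULATED = 0.3347
#: Resting PLC rate before agonist addition (μM/s).
J_PLC_RESTING = 0.05


def resting_params(base: CellParams | None = None) -> CellParams:
    """Unstimulated parameter set: level-1 machinery with resting J_PLC."""
    p = base if base is not None else CellParams()
    K, V = AGONIST_PRESETS[1]
    return replace(p, K=K, V_m3=V, J_PLC=J_PLC_RESTING)


# ---------------------------------------------------------------------------
# fluxes and derivatives
# ---------------------------------------------------------------------------

def flux_set(state: CellState, params: CellParams) -> dict[str, float]:
    """Every flux term by name, individually inspectable.

    Calcium fluxes in μM/s; ``k_activation`` is the dimensionless steady
    state of the K⁺-channel gate; ``ip3_production``/``ip3_degradation`` in
    μM/s of IP₃.
    """
    c, s, v, w, I = state.c, state.s, state.v, state.w, state.I
    if not np.all(np.isfinite([c, s, v, w, I])):
        raise InvalidStateError(f"non-finite state: {state}")
    p = params
    ipr = p.F * I * I / (p.K_r ** 2 + I * I)
    serca = p.B * c * c / (p.c_b ** 2 + c * c)
    cicr = (p.V_m3 * (s * s / (p.s_c ** 2 + s * s))
            * (c ** 4 / (p.c_c ** 4 + c ** 4)))
    pmca = p.K * c
    leak = p.L * s
    vocc = p.G_Ca * (v - p.v_Ca1) / (1.0 + np.exp(-(v - p.v_Ca2) / p.R_Ca))
    naca = p.G_NaCa * c / (c + p.c_NaCa) * (v - p.v_NaCa)
    nak = p.F_NaK
    cl_gate = c / (c + p.c_Cl) if p.c_Cl > 0 else 1.0
    cl = p.G_Cl * cl_gate * (v - p.v_Cl)
    kcur = p.G_K * w * (v - p.v_K)
    k_act = ((c + p.c_w) ** 2
             / ((c + p.c_w) ** 2 + p.beta * np.exp(-(v - p.v_Ca3) / p.R_K)))
    return {
        "ipr_release": float(ipr),
        "serca_uptake": float(serca),
        "cicr": float(cicr),
        "pmca_extrusion": float(pmca),
        "store_leak": float(leak),
        "vocc": float(vocc),
        "na_ca_exchange": float(naca),
        "na_k_pump": float(nak),
        "cl_current": float(cl),
        "k_current": float(kcur),
        "k_activation": float(k_act),
        "ip3_production": float(p.J_PLC),
        "ip3_degradation": float(p.k_deg * I),
    }


def cell_derivatives(
    state: CellState,
    params: CellParams,
    external_ca_input: float = 0.0,
    external_v_input: float = 0.0,
) -> CellState:
    """Time derivative of the state (units per second).

    ``external_ca_input`` (μM/s) and ``external_v_input`` (mV/s) are the
    summed gap-junction coupling contributions for this cell; both are zero
    for an isolated cell.
    """
    f = flux_set(state, params)
    dc = (f["ipr_release"] - f["serca_uptake"] + f["cicr"]
          - f["pmca_extrusion"] + f["store_leak"] - f["vocc"]
          + f["na_ca_exchange"] + external_ca_input)
    ds = f["serca_uptake"] - f["cicr"] - f["store_leak"]
    dv = (params.gamma * (-f["na_k_pump"] - f["cl_current"] - 2.0 * f["vocc"]
                          - f["na_ca_exchange"] - f["k_current"])
          + external_v_input)
    dw = params.lam * (f["k_activation"] - state.w)
    dI = f["ip3_production"] - f["ip3_degradation"]
    return CellState(c=float(dc), s=float(ds), v=float(dv), w=float(dw),
                     I=float(dI))


def rhs_array(y: np.ndarray, params: CellParams) -> np.ndarray:
    """Vectorless RHS on a plain array (integration kernel)."""
    st = CellState.from_array(y)
    d = cell_derivatives(st, params)
    return d.as_array()


# ---------------------------------------------------------------------------
# steady state
# ---------------------------------------------------------------------------

def steady_state(
    params: CellParams,
    *,
    tol: float = 1e-8,
    relax_time_s: float = 2000.0,
    guess: CellState | None = None,
) -> CellState:
    """Unperturbed fixed point of the single cell.

    Found by damped root-finding seeded from a long relaxation integration;
    deterministic for fixed parameters.  Raises :class:`NumericalFailure`
    when the residual exceeds ``tol``.
    """
    if guess is None:
        y0 = np.array([0.1, 1.0, -60.0, 0.1, params.J_PLC / params.k_deg])
        sol = solve_ivp(
            lambda t, y: rhs_array(y, params), (0.0, relax_time_s), y0,
            method="LSODA", rtol=1e-10, atol=1e-12)
        if not sol.success:
            raise NumericalFailure(f"relaxation integration failed: {sol.message}")
        y0 = sol.y[:, -1]
    else:
        y0 = guess.as_array()
    yss, info, ier, msg = fsolve(
        lambda y: rhs_array(y, params), y0, full_output=True, xtol=1e-13)
    resid = float(np.max(np.abs(rhs_array(yss, params))))
    if ier != 1 or resid > tol:
        raise NumericalFailure(
            f"steady-state search did not converge (residual {resid:.3e}): {msg}")
    st = CellState.from_array(yss)
    st.validate()
    return st
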