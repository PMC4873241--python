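"""Single-cell model: fluxes, derivatives, presets, steady state."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from calnet.model import (AGONIST_PRESETS, CellParams, CellState,
                          ConfigurationError, InvalidStateError,
                          NumericalFailure, agonist_to_params, cell_derivatives,
                          flux_set, resting_params, steady_state)


REF_STATE = CellState(c=0.1, s=1.0, v=-60.0, w=0.1, I=0.5)


def oracle_fluxes(state, p):
    """Independent straight-line transcription of every flux formula.

    Kept deliberately separate from the implementation (no shared helpers)
    so the two can disagree.
    """
    c, s, v, w, I = state.c, state.s, state.v, state.w, state.I
    return {
        "ipr_release": p.F * I**2 / (p.K_r**2 + I**2),
        "serca_uptake": p.B * c**2 / (p.c_b**2 + c**2),
        "cicr": p.V_m3 * (s**2 / (p.s_c**2 + s**2)) * (c**4 / (p.c_c**4 + c**4)),
        "pmca_extrusion": p.K * c,
        "store_leak": p.L * s,
        "vocc": p.G_Ca * (v - p.v_Ca1) / (1 + np.exp(-(v - p.v_Ca2) / p.R_Ca)),
        "na_ca_exchange": p.G_NaCa * (c / (c + p.c_NaCa)) * (v - p.v_NaCa),
        "na_k_pump": p.F_NaK,
        "cl_current": p.G_Cl * (v - p.v_Cl) * (c / (c + p.c_Cl) if p.c_Cl > 0 else 1),
        "k_current": p.G_K * w * (v - p.v_K),
        "k_activation": (c + p.c_w)**2
        / ((c + p.c_w)**2 + p.beta * np.exp(-(v - p.v_Ca3) / p.R_K)),
        "ip3_production": p.J_PLC,
        "ip3_degradation": p.k_deg * I,
    }


class TestFluxSet:
    def test_extrusion_linear_form(self):
        p = CellParams(K=1.0)
        zero = flux_set(CellState(0.0, 1.0, -60.0, 0.1, 0.5), p)
        assert zero["pmca_extrusion"] == 0.0
        half = flux_set(CellState(0.5, 1.0, -60.0, 0.1, 0.5), p)
        assert half["pmca_extrusion"] == pytest.approx(0.5)

    def test_against_independent_transcription(self):
        p = CellParams()
        got = flux_set(REF_STATE, p)
        want = oracle_fluxes(REF_STATE, p)
        assert set(got) == set(want)
        for name in want:
            assert got[name] == pytest.approx(want[name], rel=1e-12), name

    @given(st.floats(0.01, 5.0), st.floats(0.01, 20.0), st.floats(-90.0, 40.0),
           st.floats(0.0, 1.0), st.floats(0.0, 5.0))
    @settings(max_examples=50, deadline=None)
    def test_oracle_agreement_on_random_states(self, c, s, v, w, I):
        p = CellParams()
        state = CellState(c, s, v, w, I)
        got = flux_set(state, p)
        for name, val in oracle_fluxes(state, p).items():
            assert got[name] == pytest.approx(val, rel=1e-10, abs=1e-14), name

    def test_nonfinite_state_rejected(self):
        with pytest.raises(InvalidStateError):
            CellState(float("nan"), 1.0, -60.0, 0.1, 0.5)

    def test_term_isolation(self):
        """Zeroing one conductance removes exactly that flux, leaving the
        others bit-identical."""
        base = CellParams()
        ref = flux_set(REF_STATE, base)
        for field, flux in [("G_Ca", "vocc"), ("G_NaCa", "na_ca_exchange"),
                            ("G_Cl", "cl_current"), ("G_K", "k_current"),
                            ("B", "serca_uptake"), ("F", "ipr_release"),
                            ("L", "store_leak"), ("K", "pmca_extrusion"),
                            ("V_m3", "cicr")]:
            mod = flux_set(REF_STATE, CellParams(**{field: 0.0}))
            assert mod[flux] == 0.0
            for name in ref:
                if name not in (flux, "k_activation"):
                    assert mod[name] == ref[name], (field, name)


class TestDerivatives:
    def test_finite_difference_oracle(self):
        """dc/dt assembled from the flux signs matches an independently
        assembled right-hand side."""
        p = CellParams()
        f = oracle_fluxes(REF_STATE, p)
        d = cell_derivatives(REF_STATE, p)
        dc = (f["ipr_release"] - f["serca_uptake"] + f["cicr"]
              - f["pmca_extrusion"] + f["store_leak"] - f["vocc"]
              + f["na_ca_exchange"])
        ds = f["serca_uptake"] - f["cicr"] - f["store_leak"]
        dv = p.gamma * (-f["na_k_pump"] - f["cl_current"] - 2 * f["vocc"]
                        - f["na_ca_exchange"] - f["k_current"])
        dw = p.lam * (f["k_activation"] - REF_STATE.w)
        dI = f["ip3_production"] - f["ip3_degradation"]
        assert d.c == pytest.approx(dc, rel=1e-12)
        assert d.s == pytest.approx(ds, rel=1e-12)
        assert d.v == pytest.approx(dv, rel=1e-12)
        assert d.w == pytest.approx(dw, rel=1e-12)
        assert d.I == pytest.approx(dI, rel=1e-12)

    def test_coupling_additivity(self):
        """External inputs add linearly to dc/dt and dv/dt only."""
        p = CellParams()
        d0 = cell_derivatives(REF_STATE, p, 0.0, 0.0)
        d1 = cell_derivatives(REF_STATE, p, 0.3, -5.0)
        d2 = cell_derivatives(REF_STATE, p, 0.6, -10.0)
        assert d1.c - d0.c == pytest.approx(0.3)
        assert d2.c - d1.c == pytest.approx(0.3)
        assert d1.v - d0.v == pytest.approx(-5.0)
        for name in ("s", "w", "I"):
            assert getattr(d1, name) == getattr(d0, name)
            assert getattr(d2, name) == getattr(d0, name)

    def test_gating_bound(self):
        """dw/dt pushes w back into [0, 1] at the boundaries."""
        p = CellParams()
        for c, v in [(0.05, -70.0), (1.0, -30.0), (3.0, -10.0)]:
            at0 = cell_derivatives(CellState(c, 1.0, v, 0.0, 0.5), p)
            at1 = cell_derivatives(CellState(c, 1.0, v, 1.0, 0.5), p)
            assert at0.w >= 0.0
            assert at1.w <= 0.0


class TestAgonistPresets:
    @pytest.mark.parametrize("level,expected", [
        (1, (1.0, 300.0)), (2, (0.75, 400.0)),
        (3, (0.5, 500.0)), (4, (0.1, 600.0)),
    ])
    def test_registered_pairs(self, level, expected):
        assert agonist_to_params(level) == expected

    @pytest.mark.parametrize("bad", [0, 5, -1, "high", None])
    def test_unknown_level_raises(self, bad):
        with pytest.raises(ConfigurationError):
            agonist_to_params(bad)

    def test_monotone_in_dose(self):
        """Rising histamine: K strictly falls, V_m3 strictly rises."""
        pairs = [agonist_to_params(k) for k in (1, 2, 3, 4)]
        Ks = [k for k, _ in pairs]
        Vs = [v for _, v in pairs]
        assert all(a > b for a, b in zip(Ks, Ks[1:]))
        assert all(a < b for a, b in zip(Vs, Vs[1:]))

    def test_negative_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            CellParams(K=-0.1)


class TestSteadyState:
    def test_derivatives_vanish(self):
        p = resting_params()
        ss = steady_state(p)
        d = cell_derivatives(ss, p)
        assert np.max(np.abs(d.as_array())) < 1e-8

    def test_idempotent(self):
        p = resting_params()
        ss = steady_state(p)
        again = steady_state(p, guess=ss)
        assert np.allclose(ss.as_array(), again.as_array(), rtol=1e-9, atol=1e-12)

    def test_agrees_with_long_relaxation(self):
        """Root-found fixed point matches the t→∞ limit of integration."""
        from scipy.integrate import solve_ivp

        from calnet.model import rhs_array

        p = resting_params()
        ss = steady_state(p)
        sol = solve_ivp(lambda t, y: rhs_array(y, p), (0.0, 2000.0),
                        np.array([0.1, 1.0, -60.0, 0.1, p.J_PLC / p.k_deg]),
                        method="LSODA", rtol=1e-10, atol=1e-12)
        assert np.allclose(sol.y[:, -1], ss.as_array(), rtol=1e-6, atol=1e-8)

    def test_state_is_admissible(self):
        ss = steady_state(resting_params())
        ss.validate()
        assert ss.c > 0 and ss.s > 0 and 0 <= ss.w <= 1


class TestParameterRegistry:
    def test_registry_matches_dataclass_defaults(self):
        """The serialized registry and the in-code defaults agree for the
        resting block and every agonist preset."""
        from calnet.model import J_PLC_STIMULATED, registry_params

        for lvl in (None, 1, 2, 3, 4):
            from_json = registry_params(lvl)
            if lvl is None:
                ref = resting_params()
            else:
                ref = resting_params().with_agonist(lvl,
                                                    J_PLC=J_PLC_STIMULATED)
            assert from_json == ref

    def test_registry_units_in_keys(self):
        from calnet.model import load_registry

        reg = load_registry()
        assert all("_" in k for k in reg["common"])
        assert set(reg["presets"]) == {"1", "2", "3", "4"}
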