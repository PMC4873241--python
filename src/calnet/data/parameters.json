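{
  "description": "Kinetic constants of the coupled endothelial calcium/membrane-potential cell model. Agonist presets carry the printed (K, V_m3) pairs; the remaining constants are the package's calibrated defaults (see docs/methods.md for provenance).",
  "common": {
    "F_uM_per_s": 0.181,
    "K_r_uM": 0.7841,
    "B_uM_per_s": 0.6707,
    "c_b_uM": 0.2546,
    "s_c_uM": 2.698,
    "c_c_uM": 0.621,
    "L_per_s": 0.03168,
    "G_Ca_uM_per_mV_s": 0.001124,
    "v_Ca1_mV": 100.0,
    "v_Ca2_mV": -24.0,
    "R_Ca_mV": 8.5,
    "G_NaCa_uM_per_mV_s": 0.04894,
    "c_NaCa_uM": 0.3112,
    "v_NaCa_mV": -30.0,
    "F_NaK_uM_per_s": 0.0432,
    "G_Cl_uM_per_mV_s": 0.006068,
    "v_Cl_mV": -25.0,
    "c_Cl_uM": 0.0,
    "G_K_uM_per_mV_s": 0.01843,
    "v_K_mV": -94.0,
    "c_w_uM": 0.0,
    "beta_uM2": 0.01667,
    "v_Ca3_mV": -27.0,
    "R_K_mV": 12.84,
    "lam_per_s": 30.62,
    "gamma_mV_per_uM": 1917.0,
    "k_deg_per_s": 0.1066
  },
  "resting": {
    "K_per_s": 1.0,
    "V_m3_per_s": 300.0,
    "J_PLC_uM_per_s": 0.05
  },
  "stimulated_J_PLC_uM_per_s": 0.3347,
  "presets": {
    "1": {
      "K_per_s": 1.0,
      "V_m3_per_s": 300.0
    },
    "2": {
      "K_per_s": 0.75,
      "V_m3_per_s": 400.0
    },
    "3": {
      "K_per_s": 0.5,
      "V_m3_per_s": 500.0
    },
    "4": {
      "K_per_s": 0.1,
      "V_m3_per_s": 600.0
    }
  },
  "coupling": {
    "g_uS_per_cm2": 1000.0,
    "D_per_s": 0.105,
    "membrane_capacitance_uF_per_cm2": 1.0
  }
}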