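{
  "version": 1,
  "generated_by": "scripts/fit_reference.py",
  "seed": 0,
  "drug": {
    "ka": 0.692917,
    "Vmax_li": 23.2139,
    "f_ki_Vmax": 999.908,
    "k_DAPEX_ki": 1.04098,
    "k_D3GEX_ki": 26.7601,
    "F_gut": 0.84,
    "Kp_DAP": 25.52,
    "Kp_rest": 4.04582,
    "Kp_D3G": 1.0,
    "Km": 479.0
  },
  "pd": {
    "RTG0": 10.0,
    "Imax": 0.9,
    "IC50": 4.81895
  },
  "targets": {
    "thalf_h": 13.0,
    "tmax_h": 2.5,
    "F_percent": 78.0,
    "urine_unchanged_percent": 1.5,
    "fed_cmax_reduction_percent": 38.0,
    "d3g_tmax_h": 3.5,
    "uge24_healthy_g": 35.0,
    "uge24_t2dm_g": 70.0
  },
  "achieved": {
    "thalf_h": 13.025527,
    "tmax_h": 2.511112,
    "F_percent": 77.373992,
    "urine_unchanged_percent": 1.500123,
    "fed_cmax_reduction_percent": 37.571223,
    "d3g_tmax_h": 3.501216,
    "cmax_ng_ml": 20.537273,
    "auc_inf_ng_h_ml": 343.559259,
    "uge24_healthy_g": 27.156521,
    "uge24_t2dm_g": 95.378281
  }
}
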