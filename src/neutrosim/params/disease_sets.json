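{
  "_comment": "Median neutrophil life-cycle and PD parameter sets per disease cohort. Units in field names; rates derived from the homeostatic cascade are computed, never stored.",
  "GBM": {
    "circ0_cells_per_l": 4.5e9,
    "ratio_reserv0_circ0": 3.0,
    "km_fraction": 0.6,
    "gamma": 0.02,
    "beta": 20.0,
    "t_half_neutrophil_h": 30.0,
    "k_d_per_h": 0.001,
    "emax": 0.9,
    "ec50_ng_per_ml": 15.0,
    "n_hill": 2.0
  },
  "DLBCL": {
    "circ0_cells_per_l": 4.5e9,
    "ratio_reserv0_circ0": 2.5,
    "km_fraction": 0.1,
    "gamma": 0.01,
    "beta": 20.0,
    "t_half_neutrophil_h": 30.0,
    "k_d_per_h": 0.001,
    "emax": 0.9,
    "ec50_ng_per_ml": 15.0,
    "n_hill": 2.0
  },
  "MM": {
    "circ0_cells_per_l": 4.5e9,
    "ratio_reserv0_circ0": 2.5,
    "km_fraction": 0.45,
    "gamma": 0.017,
    "beta": 20.0,
    "t_half_neutrophil_h": 30.0,
    "k_d_per_h": 0.001,
    "emax": 0.9,
    "ec50_ng_per_ml": 15.0,
    "n_hill": 2.0
  }
}
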