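{
  "_comment": "Exposure-calibrated apparent two-compartment oral PK set: clearance solved so that the trapezoidal cycle-1 AUC on the hourly grid is 236.17 ng/mL*h per mg on a 5/7 schedule (1417 ng/mL*h at 6 mg). Use this set when reproducing published exposure tables; the bundled default set is used for pharmacodynamic simulation.",
  "ka_per_h": 2.0,
  "cl_over_f_l_per_h": 44.655063234,
  "vc_over_f_l": 10.0,
  "q_l_per_h": 0.5,
  "vp_l": 20.0
}
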