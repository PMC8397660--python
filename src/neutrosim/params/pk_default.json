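{
  "_comment": "Default apparent two-compartment oral PK set. Source PK parameters for avadomide are not public; this set uses oral-absorption and disposition constants of plausible magnitude with the central volume calibrated so that cycle-1 Cmax on a 5/7 schedule is 23.83 ng/mL per mg dosed (143 ng/mL at 6 mg). This is the set used for simulation and virtual-trial screening.",
  "ka_per_h": 0.5,
  "cl_over_f_l_per_h": 3.0,
  "vc_over_f_l": 32.164448,
  "q_l_per_h": 2.0,
  "vp_l": 40.0
}
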