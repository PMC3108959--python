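# Baseline material properties for the standard mammary-carcinoma parameter set.
# Units: K cm^2/(mmHg s); Lp cm/(mmHg s); SV 1/cm; pressures mmHg;
# lymph_coeff 1/(mmHg s) (product of lymphatic wall conductivity and surface
# density; zero in solid tumors, which lack functional lymphatics).
tissues:
  tumor:
    K: 4.13e-8
    Lp: 2.8e-7
    SV: 200.0
    pv: 15.6
    sigma: 0.82
    pi_v: 20.0
    pi_i: 15.0
    lymph_coeff: 0.0
    pL: 0.0
  normal:
    K: 8.53e-9
    Lp: 3.6e-8
    SV: 70.0
    pv: 15.6
    sigma: 0.91
    pi_v: 20.0
    pi_i: 10.0
    lymph_coeff: 1.042e-6
    pL: 0.0
geometry:
  R: 1.0
  Rn: 0.0
boundary:
  kind: isolated
  p_surr: 0.0
analysis:
  eps: 0.01
  radii: [0.1, 0.25, 0.5, 1.0]
  rn_bars: [0.0, 0.2, 0.4, 0.6, 0.8, 1.0]
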