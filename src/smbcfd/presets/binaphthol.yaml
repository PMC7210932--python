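# 1,1'-bi-2-naphthol enantioseparation (component A = more retained enantiomer).
name: binaphthol
column:
  length_cm: 10.5
  inner_diameter_cm: 2.6
columns_per_zone: [2, 2, 2, 2]
bed_porosity: 0.4
switching_time_min: 2.75
feed_concentration_g_per_L: {A: 2.9, B: 2.9}
mass_transfer_coefficient_per_min: {A: 6.0, B: 6.0}
zone_flow_mL_per_min: [56.83, 40.83, 44.47, 35.38]
zone_dispersion_cm2_per_min: [0.281, 0.202, 0.220, 0.175]
isotherm:
  kind: bi_langmuir
  coefficients:
    a1_A: 3.73
    a1_B: 2.69
    b1_A: 0.0466
    b1_B: 0.0336
    a2_A: 0.3
    a2_B: 0.1
    b2_A: 3.0
    b2_B: 1.0
grid_points_per_column: 41   # h = L/40
boundary_method: pseudo
css_rel_tol: 1.0e-4
theta: 0.0
max_switches: 300
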