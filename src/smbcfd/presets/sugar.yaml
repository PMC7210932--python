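# Glucose-fructose SMB separation (component A = fructose, extract product).
name: sugar
column:
  length_cm: 52.07
  inner_diameter_cm: 2.6
columns_per_zone: [2, 2, 2, 2]
bed_porosity: 0.41
switching_time_min: 16.39
feed_concentration_g_per_L: {A: 363.0, B: 322.0}
mass_transfer_coefficient_per_min: {A: 0.72, B: 0.9}
zone_flow_mL_per_min: [15.89, 11.0, 12.67, 9.15]
zone_dispersion_cm2_per_min: [1.105, 0.765, 0.881, 0.633]
isotherm:
  kind: linear_coupled
  coefficients: {H_A: 0.675, H_B: 0.32, k_AB: 0.000457}
grid_points_per_column: 65   # h = L/64
boundary_method: pseudo
css_rel_tol: 1.0e-4
theta: 0.0
max_switches: 300
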