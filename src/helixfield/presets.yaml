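# Named solvent presets for the hybrid nonlocal dielectric function.
# Every quantity carries an explicit unit suffix; lengths in Å, wavevectors
# in 1/Å.  "tip3p" matches the response function of TIP3P water with the
# short-range constant estimated from the partial charges; "tip3p-eps1" is
# the same correlation spectrum with eps_star -> 1 (bare-spectrum variant
# used for illustration plots).
solvents:
  tip3p:
    eps_bulk: 94.0
    eps_star: 5.75
    lambda1_A: 3.67
    lambda2_A: 1.77
    lambda_osc_A: 2.13
    gamma: 0.05
  tip3p-eps1:
    eps_bulk: 94.0
    eps_star: 1.000000000001
    lambda1_A: 3.67
    lambda2_A: 1.77
    lambda_osc_A: 2.13
    gamma: 0.05

# Default helical charge model (B-DNA).
helix:
  pitch_A: 34.0
  rise_A: 3.4
  phi_s_rad: 2.2
  phosphates:
    sigma_bar_uC_cm2: -16.3
    delta_eff_A: 0.25
    radius_A: 10.0
    delta_a_A: 0.5
  counterions:
    theta: 0.1
    f1: 0.1
    f2: 0.9
    f3: 0.0
    f4: 0.0
    dz1_A: 0.75
    dz2_A: 0.75
    dz3_A: 0.75
    radius_A: 6.0
    delta_a_A: 0.75
  bound_water:
    p0_uC_cm2: -8.0
    w1: 1.0
    w2: 0.75
    dzw1_A: 0.75
    dzw2_A: 0.75
    radius_A: 5.0
    delta_a_A: 0.75

electrolyte:
  molarity_M: 0.154
  species: [[1, 1], [-1, 1]]
  temperature_K: 300.0
  eps_for_screening: 94.0

solver:
  n_max: 50
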