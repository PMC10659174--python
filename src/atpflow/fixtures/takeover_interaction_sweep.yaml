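# Effect of the antagonistic interaction strength on the takeover: the
# sweep varies the interaction scale c (alpha_i = c*r_i/K) at a fixed
# intermediate malignant growth rate. Stronger antagonism delays the
# regime shift and can keep the normal population alive.
model: competition
params:
  # 1/(tau*(1 - Qss/K)): the initial stock 0.02*K is then exactly the
  # normal population's steady state
  r1_per_h: 0.014172335600907028
  r2_per_h: 1.47e-2
  tau1_h: 72.0
  tau2_h: 72.0
  K_atpeq: 4.05e21
  interaction_scale_c: 0.0
  eta1: 0.4
  eta2: 0.4
initial:
  Q1_atpeq: 8.1e19
  Q2_atpeq: 5.0e10
integration:
  t_end_years: 60.0
  dt_out_years: 0.01
sweep:
  parameter: c
  values: [0.0, 1.0, 2.0]
  outputs: [extinction_time, Q1_final, Q2_final]
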