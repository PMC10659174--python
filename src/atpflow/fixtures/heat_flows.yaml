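# Power and total heat flow time series during a takeover at the fastest
# calibrated malignant growth rate; the trajectory CSV carries P1, P2 and
# Jh = P1/eta1 + P2/eta2 alongside the stocks.
model: competition
params:
  # 1/(tau*(1 - Qss/K)): the initial stock 0.02*K is then exactly the
  # normal population's steady state
  r1_per_h: 0.014172335600907028
  r2_per_h: 1.53e-2
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
  outputs: [extinction_time, Jh_final]
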