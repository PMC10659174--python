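# Growth-regime taxonomy of the self-limited autocatalytic cycle: the base
# scenario sits in the sub-optimal regime (r*tau = 1.5); the sweep visits
# the optimal (maximum-power, r*tau = 2) and super-optimal (r*tau = 10)
# regimes by varying r at fixed tau = 72 h.
model: single
params:
  r_per_h: 2.0833333333333332e-2   # r*tau = 1.5
  tau_h: 72.0
  K_atpeq: 4.05e21
  eta: 0.4
  xi: 0.5
initial:
  Q_atpeq: 8.1e19
integration:
  t_end_years: 2.0
  dt_out_years: 0.001
sweep:
  parameter: r
  values: [2.0833333333333332e-2, 2.7777777777777776e-2, 1.3888888888888888e-1]
  outputs: [Q_final, Pss, Jh_final]
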