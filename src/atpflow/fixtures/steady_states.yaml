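# Single-population steady states of the calibrated normal plasma-cell
# phenotype (sub-optimal growth regime, r*tau just above 1).
model: single
params:
  r_per_h: 1.39e-2
  tau_h: 72.0
  K_atpeq: 4.05e21
  eta: 0.4
  xi: 0.5
initial:
  Q_atpeq: 8.1e19
integration:
  t_end_years: 10.0
  dt_out_years: 0.01
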