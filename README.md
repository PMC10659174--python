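# atpflow

Stock-flow energetics of competing cell populations, in ATP-equivalent
units.

`atpflow` models the metabolism and competition of cell populations as an
energy system: every stock and flow is measured in ATP-equivalents (one
cell ≡ 5·10¹⁰ ATPeq ≡ 5·10⁻⁹ J), so growth, maintenance and dissipation
live on a single energetic scale. The shipped calibration describes normal
and malignant plasma cells competing for the bone-marrow niche — the
setting of Multiple Myeloma onset — but the machinery is generic to any
pair of populations sharing a limited resource.

## The model

A single population holding an energy stock *Q* (ATPeq) obeys the balance
of net ATP production against proteome turnover,

    dQ/dt = P(Q) − R(Q) = r·Q·(1 − Q/K) − Q/τ,

with intrinsic growth rate *r* (h⁻¹), carrying capacity *K* (ATPeq) and
turnover time *τ* (h). The product *r·τ* fixes the steady state
*Q*ss = *K*(1 − 1/(*r·τ*)) and a regime taxonomy anchored at the
**maximum-power state**: the power curve *P*(*Q*) peaks at *Q* = *K*/2
with *P*max = *r·K*/4, and the steady state sits there exactly when
*r·τ* = 2 (sub-optimal below, super-optimal above, non-viable at
*r·τ* ≤ 1). Total dissipation is *J*h = *P*/*η* with *η* the ATP-production
efficiency (0.40 for oxidative phosphorylation), and a scalar potential
*V*(*Q*) with d*V*/d*Q* = −d*Q*/d*t* orders the stability of the states.

Two populations competing for the shared resource *N* = *K* − *Q*₁ − *Q*₂
and antagonising each other (Lotka–Volterra interaction flows
*α*ᵢ·*Q*₁·*Q*₂) follow

    dQᵢ/dt = rᵢ·Qᵢ·(1 − Q₁/K − Q₂/K) − Qᵢ/τᵢ − αᵢ·Q₁·Q₂.

The exclusion state where the normal population sits alone at its steady
state is stable only if *α*₂ exceeds a closed-form threshold; under the
plasma-cell calibration (*α*ᵢ = *c·rᵢ*/*K*, *c* ≤ 2) it never does, so a
single malignant cell triggers an irreversible takeover — a regime shift
whose timescale (years to decades) shrinks with the malignant growth rate
and stretches with the interaction strength.

## Worked example

Stability analysis of the calibrated competition scenario (normal
phenotype at 2 % occupancy of *K* = 4.05·10²¹ ATPeq, malignant growth rate
1.53·10⁻² h⁻¹):

```sh
$ atpflow fixtures copy heat_flows .
$ atpflow steady --config heat_flows.yaml
Fixed points and linear stability
  origin       Q1=0.000000e+00 Q2=0.000000e+00 eig_re=(2.834467e-04, 1.411111e-03) stable=False
  exclusion-a  Q1=8.100000e+19 Q2=0.000000e+00 eig_re=(-2.834467e-04, 1.105111e-03) stable=False
  exclusion-b  Q1=0.000000e+00 Q2=3.735294e+20 eig_re=(-1.411111e-03, -1.023660e-03) stable=True
exclusion-state threshold on alpha2: 1.364335e-23 1/h/ATPeq (state a stable: False; state b stable: True)
```

The normal-resident state (exclusion-a, *Q*₁ = 8.1·10¹⁹ ATPeq) has a
positive eigenvalue: a malignant invader grows at ≈ 1.1·10⁻³ h⁻¹. The
takeover state (exclusion-b, *Q*₂ ≈ 3.7·10²⁰ ATPeq) is stable. Integrating
the same scenario from a single mutated cell:

```sh
$ atpflow simulate --config heat_flows.yaml --out traj.csv --t-end 8
trajectory written to traj.csv (801 points)
regime shift detected: Q1 extinct at t = 4.713 years after a coexistence period of 4.713 years (threshold 5.000e+10 ATPeq)
```

The trajectory CSV carries the stocks (Q1, Q2, N), the production flows
(P1, P2), turnover (R1, R2), interaction flows (I1, I2) and the total heat
flow Jh = P1/η₁ + P2/η₂ at each 0.01-year output point. The same analyses
are available as library calls (`atpflow.stability_report`,
`atpflow.integrate`, `atpflow.run_takeover_growth_sweep`, ...), and
`atpflow sweep` runs one-at-a-time parameter sweeps from the `sweep` block
of a scenario file.

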