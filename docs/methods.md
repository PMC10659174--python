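# Methods

## Model

A cell population is treated as an energy stock *Q* in ATP-equivalent
units (1 cell ≡ 5·10¹⁰ ATPeq; 1 ATP ≡ 10⁻¹⁹ J). Growth is a self-limited
autocatalytic cycle: the production inflow is proportional to the external
energy source *E*, the available resource stock *N* and the cell stock
itself, while mass conservation slaves the resource to the stock,
*N* = *N*T − *f·Q*. Eliminating *N* yields logistic dynamics

dQ/dt = r·Q·(1 − Q/K) − Q/τ,  with K = N_T/f, r = k₁·E·N_T, τ = 1/k₂,

so the ecological parameters are aggregates of diagram-level kinetic
constants (`kinetics.to_ecological` / `from_ecological`; *E* and *f* are a
gauge freedom of the inverse map and default to 1). The kinetic
coefficients must satisfy the first-law closure k₀ + k₃ = k₁ + k₄, which
`KineticParams` enforces at construction; `from_ecological` resolves the
remaining freedom by the convention k₃ = 0, k₄ = k₂ (heat coefficient
mirroring the outflow), k₀ = k₁ + k₄.

Steady states: Qss = K(1 − 1/(rτ)), Pss = Qss/τ, Jh,ss = Pss/η. The power
curve P(Q) = rQ(1 − Q/K) peaks at Q = K/2 with Pmax = rK/4; the steady
state coincides with the peak exactly at rτ = 2, defining the
maximum-power state and the regime taxonomy (non-viable rτ ≤ 1,
sub-optimal 1 < rτ < 2, optimal rτ = 2 within relative tolerance 10⁻⁹,
super-optimal rτ > 2). Stability is summarised by the scalar potential
V(Q) = ∫(R − P)dQ = rQ³/(3K) + Q²/(2τ) − rQ²/2, whose defining identity
dV/dQ = −dQ/dt is enforced by a finite-difference test; note the r factor
on the cubic term, required by that identity. V's raw units are
nonphysical (ATPeq²/h-scaled); a V/K² normalisation is offered for
cross-parameter plots.

Two-population competition couples the balances through the shared
resource N = K − Q₁ − Q₂ and antagonistic Lotka–Volterra flows αᵢQ₁Q₂.
Fixed points are the origin and the two exclusion states; linear stability
comes from the analytic Jacobian. The closed-form condition for the
resident state (population 1 alone) to be stable,

α₂ > (r₂/K)·[(1 − 1/(r₂τ₂))/(1 − 1/(r₁τ₁)) − 1],

is validated against the eigenvalue signs over randomised parameters
rather than transcribed from a determinant. A generic 2×2 linear system
also admits an interior coexistence solution; the two-state taxonomy of
the model does not cover it, so it is reported with a `beyond_paper` flag
whenever both coordinates are positive (with α₁ = α₂ = 0 the system is
singular and no interior point exists).

## Energy bookkeeping

Dissipation is tied to production by P = η·J_in, so the total heat flow is
J_h = P/η (single population) or P₁/η₁ + P₂/η₂ (competition). The recycled
fraction ξ of the turnover outflow (default 0.5) splits J_h into a
production component P/η − (1−ξ)R and a consumption component (1−ξ)R but
never changes J_h or the dynamics — asserted by test. Near carrying
capacity the production component can go negative ((1−ξ)R > P/η); the
ledger flags this as an inconsistency of the partition at that state
rather than failing, since the total remains correct. Along trajectories
J_h(t) is reported as P(t)/η, the steady-state identity extended
pointwise; a `balance` field exposes J_in − (P − R) for users wanting
instantaneous closure. The interaction efficiency δ (default 1: interaction
energy fully dissipated) likewise touches only heat attribution, never the
stocks.

## Calibration

Shipped defaults (`units.CalibrationDefaults`): K = 4.05·10²¹ ATPeq
(≈ 8.1·10¹⁰ plasma cells), normal steady-state occupancy Qss/K = 0.02,
τ = 72 h (proteome turnover), η = 0.40 (oxidative phosphorylation), and a
malignancy grid RGR ∈ {3, 4, 6, 10} % giving rₘ = (1 + RGR)/τ =
1.43–1.53·10⁻² h⁻¹. The RGR recipe is read as a fractional increment over
the turnover rate because that interpretation reproduces both calibrated
endpoints exactly at τ = 72 h. For the normal phenotype two values
circulate: the rounded 1/τ = 1.39·10⁻² h⁻¹ and the occupancy-consistent
r = 1/[τ(1 − Qss/K)] = 1.4172·10⁻² h⁻¹. They are mutually inconsistent
(with 1.39·10⁻², the steady state is ≈ 8·10⁻⁴·K, not 0.02·K). Both are
exposed through `growth_rate_normal`; the analytic examples and stability
tables use the rounded value, while the takeover simulation scenarios use
the occupancy-consistent value so that the initial stock Q₁(0) = 0.02·K is
exactly the resident's steady state — only then is a single malignant cell
the smallest possible perturbation of a stationary resident, and only then
do the interaction sweeps show the delay-and-survival behaviour the
competition analysis predicts. Interaction strengths follow αᵢ = c·rᵢ/K
with c ∈ {0, 1, 2}, keeping α₁/α₂ = r₁/r₂.

## Numerics

Integration uses the implicit Radau IIA method (`scipy.integrate.solve_ivp`)
with the analytic Jacobian, relative tolerance 10⁻⁸ and absolute tolerance
10⁴ ATPeq — far below the single-cell stock 5·10¹⁰ so early malignant
growth from one cell is resolved. Internal time is hours; output is
sampled on a regular yearly grid (Δt = 0.01 yr, 1 yr = 8760 h) for
horizons up to the default 60 years, matching human-lifespan timescales.
Stocks that round off slightly negative (within the absolute tolerance)
are clamped to zero with a logged warning; larger negativity aborts with
diagnostics. Dynamics are fully deterministic: identical scenarios produce
bit-identical trajectories, and CSV exports use 17-significant-digit
formatting so files round-trip exactly.

Regime shifts are detected as the first crossing of Q₁ below one
cell-equivalent (5·10¹⁰ ATPeq, configurable), linearly interpolated
between output points. Fixed-point residuals are accepted below the
scale-aware tolerance 10⁻⁶·K/τ_min.

One-at-a-time sweeps re-integrate the base scenario independently per grid
value (no warm starts), flagging inadmissible values row-wise. Analytic
steady-state sensitivities (dQss/dr = K/(r²τ), dQss/dτ = K/(rτ²),
dPss/dr = K/(r²τ²), dPss/dτ = −(K/τ²)(1 − 2/(rτ))) are certified against
central finite differences of the analytic steady state at relative
tolerance 10⁻⁸.

## Scenario fixtures and what they exercise

The bundled YAML scenarios use explicit unit suffixes (tau_h,
t_end_years, K_atpeq) because the model mixes hours and years.
`steady_states` evaluates the calibrated single-population state;
`growth_regimes` sweeps rτ ∈ {1.5, 2, 10}; `takeover_growth_sweep` runs
the malignant growth-rate grid at c = 0; `takeover_interaction_sweep`
sweeps c ∈ {0, 1, 2} at r₂ = 1.47·10⁻² h⁻¹; `heat_flows` exports the power
and heat time series at r₂ = 1.53·10⁻² h⁻¹. Under these conditions the
takeover times span ≈ 4–40 years, shrink with r₂ and grow with c, with the
strongest interaction averting the shift within the 60-year horizon.

## Scope and limitations

The model is a deliberately minimal, deterministic, well-mixed
description: two phenotypes, one aggregated resource stock, constant
parameters. It does not represent phenotypic heterogeneity beyond the
growth-rate grid, stochastic mutation or demographic noise, spatial
structure of the niche, therapy schedules (time-dependent parameters), or
more than two populations. The resource exchange with the environment has
no dynamics of its own (N is algebraically slaved to the stocks). Passing
tests therefore certify the internal consistency of the energetic
bookkeeping and the calibrated dynamics, not clinical predictive power;
timescale checks are band checks (years to decades), as no point values
exist for the transition times.
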