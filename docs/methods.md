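# Methods

This note records the models the package implements, the conventions and
calibrations behind its defaults, and what the tests do and do not
establish.

## Dual-rail mass-action networks

A signed signal `x` is the difference of two species, `x = x⁺ − x⁻`,
with a fast annihilation `x⁺ + x⁻ →η ∅`. η is never fixed by the
designs beyond being "fast"; the default is `η = 1e6 /M/s` and a
dedicated test checks that operator fixed points are insensitive to any
η ≥ 1e4. All networks are restricted to uni- and bimolecular reactions
(the compilability condition for DNA strand displacement; the two-step
bimolecular DSD template with auxiliary gate/translator species at a
working concentration `C_max` is provided, the unimolecular template is
not — its auxiliary machinery is different and not implemented here).

Simulation uses stiff-capable integrators (LSODA by default, BDF/Radau
with an analytic Jacobian available) at `rtol 1e-8 / atol 1e-12`; rate
constants across the designs span ~5e-6 to 1.6e4 /s plus the
annihilation, so stiffness is the norm. Concentrations are never
clipped: mass action from non-negative initial states is
forward-invariant, and trajectories are checked post hoc for
non-negativity (floor −1e-9 M) and conservation (1e-6 relative drift).
Units are molar and seconds throughout; e.g. the ultrasensitive preset's
phosphatase total 0.1 µM is stored as 1e-7 M.

Each operator's compiled fragment has a reduced effective ODE
(`dy/dt = γ(K x − y)` for a gain, etc.). Both share fixed points;
circuits can be evaluated either as one merged CRN ("crn" mode) or by
integrating the block ODEs ("effective" mode), the latter being the
practical route for the 928/1875-reaction series designs.

One printed-reaction-listing discrepancy: the subtraction operator's
listing shows the subtrahend feeding the same output rail, but the
operator's own ODE `de/dt = γ_Sb(r − y − e)` requires crossed rails
(`y⁺ → y⁺ + e⁻`); the crossed form is implemented.

## The covalent modification cycle

Reduced ODEs (signed, with `x_e = E − x_C2` and
`x_p = S − x_out − x_C1 − x_C2`):

    dx_out/dt = k2 x_C1 − k3 x_out x_e
    dx_C1/dt  = k1 x_p x_in − k2 x_C1
    dx_C2/dt  = k3 x_out x_e − k4 x_C2

**Input convention.** The steady-state map takes the input as the
*total* amount introduced (free plus bound in `x_C1`); circuits
accordingly feed inputs as initial concentrations, and each cycle block
receives its own pool (a cycle consumes its input transiently, so two
cycles must not drain one shared species). A clamped-free-input mode
exists for analysis. The map is solved as a bracketed scalar root in
the output itself (the cyclic flux `v(out) = k3·out·E/(1 + k3·out/k4)`
makes the substrate-balance residual strictly increasing), which is
exact, cancellation-free and unique; a property test checks it against
long-time integration to 1e-4 over random parameter draws.

**Substrate totals.** The regime presets carry the published rate
constants verbatim, but no substrate total is published anywhere, and
the map's shape depends on it essentially: with a buffered (constant)
substrate the map is convex and *cannot* approximate a logarithm
(concavity of ln forces `f(4) ≈ 2 f(2)`, impossible for a convex map
through the origin), so substrate depletion is part of the mechanism,
not a nuisance. Each preset's total is therefore calibrated once
against the regime's design target: hyperbolic `S = 10.53 M` (best
absolute match to ln on [2, 10]), ultrasensitive `S = 1e-3 M` (the
switch saturates at ±1e-3, matching the stated output range),
threshold-hyperbolic `S = 10 M` (near-unit slope after the dead zone),
signal-transducing `S = 150 M` (clear linear region before the
plateau). The steady-state map is invariant under a uniform scaling of
k1..k4 (that only rescales time), so only rate *ratios* and the totals
shape it.

**Rectification.** The dual-rail cycle is *not* odd in its input. For
positive inputs the map saturates by substrate depletion. For negative
inputs, in the threshold-hyperbolic and signal-transducing regimes, the
minus-rail pathway recycles through the crossed-sign binding reactions
and annihilation and produces ~zero net output (verified by full
14-reaction simulation: |output| < 0.5 % of the positive-branch value),
while the ultrasensitive regime converts its whole substrate pool to the
minus rail and saturates at −S. This intrinsic one-sidedness is what
the absolute-value circuit exploits; it is a quasi-steady behaviour
(annihilation slowly erodes the pool, ~5 % per 1e4 s for the
ultrasensitive preset), which is why circuit evaluation uses a settled
check rather than a strict equilibrium.

**Regime fitting.** `fit_regime` is a Nelder-Mead simplex search on
log10-transformed rates (optionally the substrate total too) inside
biologically-plausible bounds `[1e-6, 1e6]`, restarted once from the
best point, with SSE or minimax-relative objectives; a constant-zero
target returns a degenerate-flagged result.

## Circuit designs

Reaction totals (all reproduced exactly by the compilers): ln-series 928
(order 10: `l+3` sum/sub, 1 multiplication, powers 3..2l+1, `l+2`
gains), log-arbitrary 1875 series / 47 CMC, square root 50, signum 83
series / 19 CMC, absolute value 57 series / 45 CMC.

*Dividers.* Ratios (the z of the series log, `ln a / ln b`, the
reciprocal in signum) are high-gain feedback loops: subtraction forms
the residual `num − c·den`, a multiplication closes the loop, and a
gain block with `K = 1000` (default) drives the residual down, leaving
a relative error `1/(1 + K·den)`. The gain block runs at a slow rate
(4e-4 /s) so the loop crossover `γ·K·den` stays well below the other
blocks' poles (10 /s); the divider gain must be matched to the
denominator's scale (`K·den ≳ 20` for percent accuracy,
`γ·K·den ≲ 3` for stability).

*Square root.* A continuous Newton-Raphson flow
`dz/dt = γ_N (z − w z³)/2` converges to `z = w^(−1/2)` from `z(0) = 1`
for any `w > 0` (the continuous flow is monotone toward the fixed
point, unlike the discrete iteration); `w·z` then gives `√w`. Inside
the block the operator rates are 50 /s and `γ_N = 0.25 /s`: the flow's
initial local gain `γ_N(3 w z₀² − 1)/2` must stay below the internal
poles, and these defaults keep it stable for `w` up to ~100. The
printed inventory includes a second subtraction whose placement the
source design leaves open; it is wired as the output stage.

*Signum, CMC variant.* One ultrasensitive cycle (±1e-3 saturation,
switching threshold ~1e-9 M) plus a gain `K = 1000` rescaling to ±1.
The series variant computes `x/√(x²)`; at the microscale (1e-6 M)
inputs of the published simulations its reciprocal stage spans 12
decades (`z* = 5e5`, `z³ ≈ 1e17`) and defeats practical integration, so
it is validated at unit-scale inputs (signum is scale-invariant) with a
matched divider gain of 1e4.

*Absolute value, CMC variant.* `y = K1·TH(u) + K2·ST(−u)` with `K1 = 1`
and `K2 = 1/20`: the threshold-hyperbolic branch answers positives with
unit slope, the signal-transducing branch (input rails crossed — a free
wiring operation) answers negatives with slope 20, and the combining
subtraction's crossed subtrahend rails add the branches. The branch
parameter sets are obtained by the package's own fitting machinery
(started from the printed regime rates) against the ideal rectifier
targets, because the printed rates with any substrate total leave
residual dead-zone/saturation deviations of ~13 % at intermediate
inputs; with the fitted sets accuracy is ~0.2 % across ±1..6 M. The
published design reports deviations at ±1 and ±6 M; those points are
the dead-zone and saturation edges of the unfitted maps.

*Log, CMC variant.* Both natural-log blocks use a hyperbolic-regime
parameter set fitted (minimax, rates + substrate) to the ln target;
maximum error 3.6 % on [2, 10] and ≤3.8 % on all `log_b a` ratios with
`a ∈ {2..10}, b ∈ {2, 10}` — within the 5 % design tolerance, against
~8 % for the printed preset rates under this package's map (whose exact
published substrate context is unrecoverable).

## Closed loops and step metrics

The loop (reference → subtraction → controller → process) integrates
the reduced ODEs with per-reaction split rates
(`de/dt = γ_Sb1 r − γ_Sb2 y − γ_Sb3 e`, etc.). Metric conventions,
calibrated once against the published nominal characteristics and then
frozen: rise time 10→90 % of the achieved final value, settling band
2 % of the achieved final value, overshoot relative to the achieved
final value, `e_ss = |r − y_∞|`.

The published CMC-controller ODE prints its binding term as `k1 e`
although `k1` is bimolecular, so three readings are implemented behind
`rhs_form`: `as_printed`, `mass_action` (`k1 e x_p`, error species read
catalytically) and `mass_action_consuming` (binding consumes the error
species). Calibration against the published nominal tables selects
`mass_action_consuming` for the linear process (worst deviation 7.6 %
vs 30 % for the catalytic form) and `mass_action` for the nonlinear
process (2.4 % vs 153 %); `as_printed` is an order of magnitude off for
both. The selection is recomputed, not hard-coded, and recorded in
output metadata. For the nonlinear case the tabulated parameter values
(γ's = 4e-4 /s, K_I = 3e-4) take precedence over conflicting in-text
figures. The CMC loops carry a small standing error (~1.4e-3 M for the
linear process) because the cycle's back-flux needs nonzero input; the
published tables print 0.00 at their two-decimal resolution.

The linear stability law: with static actuation `u = K y` the process
obeys `dy/dt = (k_p1 K − k_p2) y`, stable iff `K < k_p2/k_p1`.
`controller_io_map` evaluates the open-loop error→actuation map at a
fixed finite horizon (a pure integrator has no static map); the horizon
is a convention reported with the curve.

## Monte-Carlo robustness

Parameters perturb one-sidedly, `p → p(1 + Δu)`, `u ~ U(0,1)` i.i.d.
per parameter (the published worst-case parameter ranges all sit at or
above nominal; a symmetric option exists behind a flag). The perturbed
parameter lists are the tabulated ones per system (12 / 9 / 13 / 10
parameters). Sample sizes follow the Chernoff bound
`N ≥ ln(2/(1−c))/(2ε²)` — 1060 at (0.05, 99 %); the default test-scale
N is 200, with full-scale runs available from the CLI.

**Instability classification.** A sample is unstable when its state
diverges (non-finite, or |y| beyond 100× the reference) or fails to
settle within the observation horizon: the output must stay inside the
2 % band of its own final value over the last 5 % of the horizon.
Settling to a large steady-state error still counts as stable (the
published worst cases include e_ss up to 1.12 M as finite outcomes).
Horizons are 1000 s (linear) and 1e5 s (nonlinear), roughly twice the
worst published settling time; the classification is insensitive to the
choice between 1000 and 1500 s. Unstable samples are excluded from
worst-case maxima and counted separately; worst cases are sample
maxima, and the reported parameter "ranges" are the min–max envelope
over the four per-metric argmax draws (sample-path dependent, so
reproducible only under a fixed seed).

Instability of the perturbed PI + linear loop at Δ = 1.2 is a rare
event (~0.3 % of draws, consistent with its detection in a 1060-sample
study); at N = 200 the probability of observing at least one such draw
is only ~40 %, so the scaled-down comparison is seed-sensitive. The
test suite pins seed 0, under which the full qualitative pattern
reproduces: PI stable at Δ = 1.0 with one unstable draw at Δ = 1.2, CMC
stable through Δ = 1.4 with onset at 1.6–1.8 (N = 500), and a larger
worst-case overshoot for PI than CMC at Δ = 1.0.

## What the synthetic targets do and do not cover

`generate_fixture` produces the four idealised regime targets (log
curve, sharp sigmoid, dead-zone linear, saturating linear) with
optional seeded Gaussian noise. They emulate the *shapes* the cycle can
express, not real enzymatic data: no measurement error model beyond
additive noise, no substrate-level stochasticity, no crosstalk between
circuits sharing species, and no resource competition. Passing tests
therefore demonstrate that the designs realise their mathematical
specifications under mass-action kinetics — not that a wet-lab DSD
implementation would achieve the same accuracy, where leak reactions,
strand synthesis errors and concentration drift would add error terms
this package does not model.

## Known limitations

- Stochastic (Gillespie) and spatial simulation are out of scope.
- The unimolecular DSD template is not implemented (see above).
- Steady-state maps are defined for non-negative inputs; signed
  behaviour comes from full dual-rail simulation.
- The series signum/square-root designs require scale-matched divider
  gains; there is no automatic scaling.
- The exact substrate context behind the published regime rate sets is
  unrecoverable, so the package's fitted design sets, not the raw
  presets, carry the accuracy guarantees.
- Formal nonlinear (Lyapunov) stability analysis of the closed loops is
  not attempted; "stability" in the Monte-Carlo analysis is the
  operational settledness criterion above.
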