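# Methods

## Model structure and assumptions

Two well-mixed cell populations, normal `N(t)` and tumor `T(t)` (cells),
evolve deterministically in continuous time. Each has an intrinsic growth
law from the Richards (generalized-logistic) family,

    dx/dt = (r/ν) x (1 − (x/K)^ν),   ν > 0,

normalized so that `ν → 0` gives exactly the Gompertz law
`dx/dt = r x ln(K/x)` and `ν = 1` the plain logistic equation. This
normalization was a genuine design choice: it is the standard Richards form
with the Gompertz limit built in, and its `ν = 1` member reproduces the
logistic dynamics at the same printed rates, so one parameter family covers
both tumor variants (logistic with `r_T = 0.3`, `K_T = 1.2·10⁶`; Gompertz
with `γ = 0.083`, plateau `h`). The Gompertz tumor is the `ν = 0` member
with `rate = γ`, `capacity = h`; a time-decaying-rate parametrization of
Gompertz growth is deliberately not used. `x = 0` and `x = K` are fixed
points of every member (the Gompertz flux at 0 is defined by continuity),
so extinction is absorbing.

The compartments interact through two fluxes added to the intrinsic laws:

* GMF effect on normal cells:
  `f_N(T)·N = β N (T/k_scale)(1 − T/T*) T/(ρ₁+T)`.
  The exact published algebra of this rule is not recoverable; this form is
  a reconstruction satisfying every qualitative constraint the model
  narrative imposes — zero effect without tumor, stimulation below the
  critical size `T*`, an exact sign switch at `T*`, inhibition/kill above
  it, proportionality to `N` — and, with the standard parameter set,
  reproduces the documented landmarks (normal cells stimulated to
  ≈1.15·10⁶ by `t = 40`; crossing of `T*` near `t = 43`). `k_scale`
  defaults to the active tumor carrying capacity, which keeps the
  stimulation per-capita rate of order `β·T/K_T` rather than `β`; a bare
  per-capita `β = 2` would drive the normal plateau to
  `(1 + β/r_N)K_N = 6·10⁶`, contradicting the ≈1.1·10⁶ landmark. Both
  rules are pluggable strategies; a Hill variant
  `β N (T^m/(ρ₁^m+T^m))(1 − (T/T*)^m)` with the same zeros and signs is
  selectable by config (`variant: "hill"`, integer degree `m ≥ 1`).
* Normal-cell suppression of the tumor:
  `f_T(N,T) = −k (N/(ρ₀+N)) (T/(ρ₁+T))`, never positive, saturating at the
  ceiling `k` (cells/time) for large `N` — normal cells can restrain the
  tumor only up to a constant effect — and vanishing with either
  population. `ρ₁ = 1000 ≪ T*` gives both rules a smooth onset at small
  tumor sizes and prevents a one-cell tumor from being suppressed outright.

Setting `β = k = 0` decouples the system exactly; the test suite verifies
the decoupled trajectories against the closed-form logistic/Gompertz
solutions to 1e-6 relative.

## Chemotherapy

The drug enters as a per-capita loss `F_i(u) = a_i(1 − e^{−m u})` on each
compartment (`i = N, T`): the fractional-cell-kill law, zero without drug,
strictly increasing, saturating at the response coefficient `a_i` (1/time).
The pharmacokinetic exponent `m` defaults to 1. Exposure `u(t)` is zero
before the therapy start `t_rx`, then constant (`static`) or exponentially
decaying `u₀ e^{−d(t − t_rx)}` (`exp_decay`); the decay clock is anchored
at `t_rx` because `u₀` is the administered amount, meaningful only at
administration. Static regimes may be specified directly by the lumped
constant `a_i(1 − e^{−m u₀})` — the form in which drug strengths are
usually quoted — and the two entry styles are bit-identical because the
constant is resolved once before integration. Linear or bell-shaped decay
schedules and multi-dose regimens are out of scope.

Therapy starts either at a fixed time (`t_rx = 40` in the Model-1 presets)
or, for the Gompertz presets, when the tumor first reaches `T*`
(`therapy_trigger: tumor_exceeds_tcrit`) — operationalizing "therapy begins
when the normal cells enter the inhibition phase", since in this model the
normal-cell peak coincides with the `T*` crossing. Trigger resolution
integrates the drug-free system with a terminal event at `T = T*`.

## Numerics

* Integrator: LSODA via `scipy.integrate.solve_ivp`, rtol 1e-10,
  atol 1e-8, dense output retained. The tight rtol is needed for the
  trajectories to track the analytic growth solutions to 1e-6 relative
  through the early near-exponential phase from one cell.
* The therapy start is a step discontinuity in the right-hand side, so the
  horizon is integrated piecewise `[0, t_rx]`, `[t_rx, t_end]`; adaptive
  steppers lose order across interior discontinuities otherwise.
* State is clamped at 0 from below when the solver probes marginally
  negative values; sampled values within 1e-9 of zero are reported as 0.
  Populations below one cell are otherwise reported as-is: this is a
  continuous deterministic model with no demographic stochasticity.
* Output is sampled on a uniform grid (default step 0.1 time units).
  Event metrics do not depend on the grid: threshold crossings are refined
  by bracketing (`brentq`) on the dense solution to |Δt| ≤ 1e-6, and peaks
  by bounded scalar minimization around the grid argmax (ties break to the
  earliest time; a refined candidate must strictly beat the grid value).
  Halving the grid step moves event times by < 1e-3.
* `trajectory_distance` is the L2 norm of the stacked (N, T) difference
  divided by the larger of the two stacked path norms. Normalizing by the
  larger norm (rather than by one designated path) keeps the distance
  symmetric and zero iff the sampled paths coincide.
* `inhibition_onset_delay` is the treated-minus-untreated normal-cell peak
  time, computed against the scenario's drug-free twin (same parameters,
  `drug.mode = "none"`). It is censored (`inf`) when the treated normal
  population is still rising at the horizon or when the treated tumor never
  reaches `T*` — in either case the inhibition regime was never entered.
  Note the peak is a kink, not a smooth maximum, when the drug kills normal
  cells: for normal-kill constants ≥ ~0.05 the global peak sits exactly at
  the therapy onset `t = 40`, so the peak-based delay can be negative even
  though the tumor's `T*` crossing — the mechanism that actually starts the
  inhibition phase — is postponed. Comparative analyses of regimes with a
  normal-cell kill should therefore read `tcrit_crossing` alongside the
  delay.

## Horizons and defaults

Model-1 presets integrate to `t_end = 100`, Gompertz presets to 60 —
horizons that contain every described event (crossing, peak, collapse or
rescue); figure axes are not available to fix them exactly, so end-of-
horizon metrics ("terminal" sizes) are reported at these documented
`t_end` values. The sample step 0.1 resolves every event to well under the
refinement tolerance.

## The Gompertz parameter inconsistency

The printed Gompertz tumor parameters (`h = 10⁵`, `γ = 0.083`) are mutually
inconsistent with two other stated properties: that the Gompertz and
logistic tumors reach "almost the same" long-run size (logistic
`K_T = 1.2·10⁶`) and that the Gompertz tumor crosses `T* = 3·10⁵`. With a
plateau of `10⁵ < T*` neither can happen: the GMF stimulation never
switches off, the normal compartment equilibrates near 4.2·10⁶ with no
inhibition phase, and size-triggered therapy never engages (the treated
literal presets coincide with the untreated one). The registry therefore
ships both the literal presets (`fig4_*`) and consistency presets
(`fig4_consistent_*`, identical except `h = 1.2·10⁶`). Which variant the
original simulations used cannot be determined, so no quantitative
Model-2 landmark is asserted anywhere; the qualitative Model-2 claims
(initially faster Gompertz growth since `γ ln h > r_T`; very fast
inhibition-phase entry; normal cells preserved by a moderate tumor kill and
their decline suppressed by a stronger one) are verified on the
consistency presets.

## What the presets do and do not show

The presets are idealized well-mixed two-compartment cultures: no spatial
structure, no immune compartment, no drug absorption delay, no
cell-cycle or age structure, no stochastic extinction. Conclusions from
passing tests are about the coupled-ODE caricature — orderings and
qualitative regime changes under therapy parameters — not quantitative
predictions for real tissue. The interaction algebra is a reconstruction
(see above): all quantitative statements tied to it (e.g. the normal-cell
size ≈1.15·10⁶ at `t = 40`) are properties of this package's default rules
and would shift under a different `f_N` satisfying the same qualitative
contract.
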