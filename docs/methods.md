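# Methods

## Model

A two-state system (closed ⇌ open) at constant pressure with equilibrium
constant K_eq = P/(1 − P). Enthalpy and entropy differences between the
states derive from the heat-capacity difference ΔC_p(T):

    ΔH(T) = ΔH(T₀) + ∫_{T₀}^{T} ΔC_p(T′) dT′
    ΔS(T) = ΔS(T₀) + ∫_{T₀}^{T} ΔC_p(T′)/T′ dT′

with ΔG = ΔH − TΔS = −RT ln K_eq and the van 't Hoff relation
d ln K_eq/dT = ΔH/(RT²). When ΔC_p ≡ 0 the van 't Hoff plot
(ln K_eq vs 1/T) is a straight line; a nonzero ΔC_p bends it, and the point
of the package is to estimate that bend without committing to a functional
form.

## Fitting procedure

The observable is a series {T_m, y_m = ln K_eq, σ_m}. For a chosen
temperature scale x(T) ∈ {T, 1/T} and interval count N, y is modelled by a
natural cubic spline S(x) through knots s_0 < … < s_N. The edge knots are
pinned to the data extremes in x; the free parameters are the N − 1
interior positions and all N + 1 knot values (2N parameters). The weighted
residual χ² = Σ_m [(y_m − S(x_m))/σ_m]² is minimized and candidates over
the (N, scale) grid are ranked by BIC = χ²_min + 2N ln(n_points), χ² being
twice the negative log-likelihood for Gaussian residuals. The BIC's sample
size is the number of data points entering the fit. Ties within
`bic_tie_tol` (default 1e−6) go to the smaller N, then to the reciprocal
scale (the conventional van 't Hoff abscissa). The full candidate table is
always reported so a selection can be audited; when the user supplies no
measurement errors, unit weights are used and the report flags BIC
comparisons as relative-only.

### Optimization

The natural-spline interpolant is *linear in its knot values*, so for any
trial set of positions the optimal values are obtained exactly by weighted
linear least squares (variable projection). The remaining nonlinear search
runs over the N − 1 interior positions only, via trust-region least squares
from multiple starts (default 10): start one places interior knots at
evenly spaced x-quantiles, the rest jitter that layout with a seeded
generator. Free-knot problems are multimodal; multistart is the guard.
All randomness flows from the single configured seed, so identical
configuration gives bit-identical reports.

Knot ordering is enforced structurally, not by penalties: the optimizer
works on unconstrained increments mapped through a softmax onto interval
widths with a guaranteed floor of ε = 1e−3 of the span, so every iterate
is a valid, strictly increasing knot set.

Each refinement is capped at 60 function evaluations per free parameter;
starts that exhaust the cap are recorded in the per-start χ² log and do not
set the convergence flag (the χ² tolerance itself defaults to 1e−10).
Model candidates are fitted in order of increasing N, and each N is
additionally warm-started from the previous N's optimum with one knot
inserted at the midpoint of its widest interval. Since a natural spline is
exactly representable after knot insertion, the enlarged family contains
the previous optimum, and trust-region refinement never increases the cost
from its start — χ²_min is therefore non-increasing in N by construction,
not by luck.

For N = 1 the natural boundary conditions force the single cubic to be a
straight line and the fit reduces to one closed-form weighted
least-squares solve.

## Thermodynamic extraction

With S the fitted spline and x(T) the scale map,

    ΔG = −RT·S,   ΔH = RT²(dx/dT)·S′,   ΔS = (ΔH − ΔG)/T,
    ΔC_p = R·d/dT[T²·dx/dT]·S′ + R·T²·(dx/dT)²·S″.

The first ΔC_p term is written with the derivative acting only on the
prefactor; this is the reading under which ΔC_p ≡ dΔH/dT exactly, matching
the definition of the heat capacity at constant pressure (the alternative —
letting the derivative also hit S′ — double-counts the curvature term).
On the reciprocal scale T²·dx/dT = −1 is constant, so ΔC_p = R·S″(x)/T²;
on the linear scale ΔC_p = 2RT·S′ + RT²·S″. Both closed forms are verified
against finite differences of ΔH in the tests; the agreement is O(h²)
*piecewise* — ΔH″ jumps at interior knots because the spline is only C²,
so finite-difference stencils straddling a knot are excluded from that
comparison.

Q10(T) = K_eq(T+10)/K_eq(T) is evaluated on the fitted spline as
ln Q10 = S(x(T+10)) − S(x(T)), and the implied enthalpy
ΔH_Q10 = RT² ln(Q10)/10 is anchored at the lower temperature of the pair
(mid-point anchoring would change the bias). For a constant-ΔH model the
finite difference is biased low by exactly T/(T+10) — about 3% at 300 K —
and a generalized step-δ helper shows the bias vanish as δ → 0.

## Error propagation from replicates

Replicate open probabilities at one temperature are reduced by their sample
mean P̄ and unbiased variance s² (N − 1 denominator) to

    y = ln(P̄/(1−P̄)),    σ_y = sqrt[(1/N)·(1/(P̄ − P̄²))²·s²],

the delta-method propagation of the standard error of the mean through the
logit. Temperatures with a single replicate are rejected rather than
imputed, identical replicates (zero variance) are rejected rather than
given zero error, and means outside `p_bounds` (default (0.01, 0.99),
overridable, off for direct ln K_eq input) are dropped with a logged
warning: near-saturating open probabilities are dominated by variability
unrelated to gating. A Monte-Carlo test confirms the propagated σ tracks
the empirical spread of y within 10% in the small-noise regime.

## Synthetic data

The generator draws from the two-state model above with constant ΔC_p in
closed form (an arbitrary ΔC_p(T) callable is integrated by a fixed-step
trapezoid at 0.01 K). Noise is Gaussian and homoscedastic, either directly
on ln K_eq (σ_y) or on replicate open probabilities (σ_P); replicate draws
outside (0, 1) are rejected and redrawn, keeping the replicate mean
unbiased. Defaults used across the test suite as the standard study
conditions: 21 temperatures on 283–323 K, σ_y = 0.05, and ground truths
ΔH = 100 kJ/mol, ΔS = 300 J/(mol K) (constant-ΔH case, TRPV-like
magnitudes) or ΔC_p = −10 kJ/(mol K) with ΔH(310 K) = 0 (strongly curved
case).

What the generator does *not* emulate: temperature-dependent measurement
error, voltage-dependent gating, drift or artifacts in current recordings,
multi-state kinetics, or correlated replicates. Passing recovery tests on
this generator therefore demonstrates the estimator's correctness under
its own statistical assumptions, not robustness to instrumental artifacts
in real recordings.

### Scale-indistinguishability demonstration

The linear-vs-reciprocal comparison uses data from a linear-in-T truth with
slope b = 0.05 K⁻¹ (equivalent ΔH ≈ 37 kJ/mol, Q10 ≈ 1.7 — a moderately
temperature-sensitive equilibrium) and σ = 0.2, a typical replicate-derived
ln K_eq standard error. The geometric gap between a line in T and a line in
1/T over 283–323 K is a sagitta of roughly 3% of the total signal range;
indistinguishability is the regime where that gap sits below the noise.
This is a genuine limitation of the claim, not of the implementation: very
precise data with steep slopes (large |ΔH|, tiny σ) *can* separate the two
scales even over 40 K, and the BIC table makes that visible when it
happens.

## Problem sizes and numerical choices

- Default model scan: N = 1 … min(8, ⌊(n_points−1)/2⌋), both scales,
  10 starts. The recovery and indistinguishability test suites use
  n_max = 4 (3 for the scale comparison) and 5 starts over 50 seeded
  replicates, which the parameter-recovery results show is ample for
  21-point series.
- Thermodynamic-identity checks run on 200-point grids; ΔC_p-vs-dΔH/dT uses
  800 points.
- Evaluation outside the fitted x-range raises instead of extrapolating;
  reporting inside the range is accompanied by a per-point "constrained"
  flag, true iff a datum lies within one mean inter-datum spacing in x
  (factor configurable) — an operational stand-in for the qualitative
  notion of a spline region unsupported by data.
- Temperatures are Kelvin-only internally; the input unit is declared,
  never guessed.
- Splines serialize as knot coordinates only; coefficients are recomputed
  on load.

## Known limitations

- BIC selection assumes honest σ_m; artifacts or unreasonably small error
  bars distort both χ² and the selected complexity.
- No confidence intervals on knots or on the extracted curves; the
  replicate-based σ enters the fit weights but is not yet propagated to
  ΔH(T) bands.
- Multistart local optimization carries no global-optimum guarantee,
  although the nesting construction prevents the most visible symptom
  (χ² rising with N).
- Two-state description only; channels with multiple open/closed states
  need a different likelihood.
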