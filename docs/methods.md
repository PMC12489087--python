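# Methods

## Model

The simulator integrates the four-compartment enzyme network

    D^{δ(t)} S = β₂H − β₁ES
    D^{δ(t)} E = β₃H + β₂H − β₁ES
    D^{δ(t)} H = −β₃H − β₂H + β₁ E(t−τ₁) S(t−τ₂)
    D^{δ(t)} P = β₃P        (as_printed)   |   β₃H   (classical_product)

where D^{δ(t)} is a variable-order Caputo derivative with
δ(t) ∈ (0, 1]. The working definition is the Volterra integral form
with the **order frozen at the outer evaluation time**: at time t both
the kernel exponent and the Γ factor use α = δ(t),

    y(t) = y(0) + 1/Γ(δ(t)) ∫₀ᵗ (t−v)^{δ(t)−1} f(v) dv.

This is a modeling choice, not a mathematical necessity: other
variable-order operators (incremental-kernel definitions) give
different dynamics. Its consequences matter; see *Positivity* below.

Delays enter only the complex-formation term — past enzyme E(t−τ₁)
and past substrate S(t−τ₂) drive H, while the S and E equations use
instantaneous products. The pre-history is constant and equal to the
initial state for all t ≤ 0; no other history rule is implied by the
model statement, and the choice is recorded in every run's metadata.

Two closures of the product equation are provided. `as_printed`
(default) uses dP = β₃P, i.e. autocatalytic exponential product
growth, which matches the exponential P curves of the source
experiments. `classical_product` uses the standard dP = β₃H. P feeds
back into nothing, so S, E, H are identical under both (tested).

### Parameters

| parameter | meaning | default | units |
|---|---|---|---|
| β₁ | binding rate | 0.0530 | 1/(conc·time) |
| β₂ | product-formation rate | 0.012 | 1/time |
| β₃ | catalysis rate | 0.040 | 1/time |
| τ₁, τ₂ | binding delays | scenario-dependent: (0,0), (0.5,0.5), (0.5,2) | time |
| S₀,E₀,H₀,P₀ | initial concentrations | 10, 5, 4, 0.1 | conc |
| δ(t) | order function | families: constant, cosine, sine, linear | — |

The published source lists the three rates as an unordered triple
(x, y, z) without tying them to β₁, β₂, β₃. The mapping above
(listing order) is frozen only after empirical validation:
`validate_parameter_mapping` integrates all 6 permutations on the
classical path against the published zero-delay integer-order H column
and the listing order wins uniquely (mean relative error 6.8 % versus
≥ 50 % for the runner-up). The same routine runs in the acceptance
script so the validation is reproduced, not remembered.

The shipped linear order function is δ(t) = 0.99 − (0.01/100)·t. The
printed headers disagree between tables (0.001/100 in one, 0.01/100
with a dropped sign in the others); a positive slope would leave
(0, 1], so the sign is restored and the majority magnitude used. The
choice is written into every table's metadata sidecar rather than
hidden.

## Numerical scheme

### Fractional path (PECE)

The solver discretizes the integral form with Diethelm-type
product-integration rules on a uniform grid t_n = nh:

* predictor: product-rectangle weights
  (h^α/Γ(α+1))[(n+1−j)^α − (n−j)^α];
* corrector: product-trapezoid (Adams–Moulton) weights
  (h^α/Γ(α+2))·a_j with the classical a_j coefficients;
* per step the **whole history is re-weighted** with α = δ(t_{n+1}),
  which is the direct discretization of the frozen-order integral
  form; one corrector sweep by default (configurable).

The memory term is always full-history (O(N²) work overall); at the
default fractional resolution h = 0.05 over T = 200 (N = 4000) a run
costs well under a second, and the δ≡1 cross-check at h = 0.01
(N = 20000) a few seconds, so no short-memory truncation is used.

Exact solutions of constant-order problems behave like t^α near the
origin, which degrades the product-trapezoid rule's accuracy on the
first steps. The stepper therefore integrates the first 2 coarse
intervals on a 16× finer sub-grid and transfers the coincident nodes.
On the oracle problem D^{1/2}y = −y, y(0)=1 (closed form
e^t·erfc(√t)) at h = 0.001 this reduces the max-norm error on [0, 1]
from 1.3·10⁻⁴ to 6.2·10⁻⁵; terminal error is ~10⁻⁶.

Delays must satisfy τ_i/h ∈ ℕ so delayed states are read exactly from
computed grid rows (or from the history rule when t − τ ≤ 0); the
scenario delays 0.5 and 2 align with both default steps. Misaligned
configurations raise an error instead of interpolating inside the
memory convolution.

### Classical path (δ ≡ 1)

For the integer-order regime the model is an ordinary delay ODE and is
integrated by classical RK4 with cubic-Lagrange interpolation of the
computed history for delayed stage values. This path is
scheme-independent of the fractional machinery and is used to
cross-validate it: PECE at constant order 1 agrees with RK4 on the
enzyme model to ≤ 10⁻³ max-norm over [0, 200] (measured ≈ 6·10⁻⁵).
Without kink tracking, interpolation stencils that straddle the
solution's derivative discontinuity at t = τ leave a local error of
order 10⁻⁵ at h = 0.1 (visible in the method-of-steps test); this is
standard for DDE integrators of this class.

### Numerical edge cases

* Order functions are validated over the whole horizon before
  stepping; a value outside (0, 1] raises, never clamps.
* Non-finite states abort the run with the offending step index.
* Γ factors go through log-gamma; no special-casing is needed on
  (0, 1].
* Uniform grids only; T/h must be integral.
* Weight mass is exact by construction: corrector weights sum to
  t_{n+1}^α/Γ(α+1) (machine precision; property-tested over random
  n, h, α).

## Monitors and certificates

**Conservation.** With zero delays the E and H kernels cancel exactly
(L₂ + L₃ = 0), so E + H is conserved at E₀ + H₀ = 9. Both schemes
preserve this to machine precision because the quadrature is linear in
the rates. With delays the cancellation breaks and the drift of E+H
equals the integral of β₁(E_lag·S_lag − E·S); the monitor reports the
sup drift either way (≈ 3.1 for the τ = (0.5, 2) fractional scenario).

**Positivity.** For constant and slowly varying orders all four
compartments stay non-negative (minima ≥ −10⁻⁸) on the reference
runs. This is **not** true for the large-amplitude cosine order
δ(t) = 0.98 + 0.008·cos(t/10): the converged solution (h-independent
across h = 0.1/0.05/0.025) dips to S ≈ −0.095 and H ≈ −0.459 at late
times. The mechanism is intrinsic to the frozen-order formulation:
once S and H hug zero, re-weighting the entire memory integral as δ(t)
oscillates shifts the reconstructed state by a few percent of the
accumulated integral — enough to cross zero. A memoryless model cannot
do this (at S = 0 the rate β₂H ≥ 0 points inward), so boundary
arguments for positivity do not transfer to this operator. The
positivity monitor reports the genuine minima rather than asserting a
claim the model does not satisfy.

**Boundedness.** The total mass N = S+E+H+P is reported as a series
plus supremum, with no pass/fail: under the as_printed closure P grows
exponentially, so N is unbounded by design; under classical_product,
dN = (β₂+β₃)H − β₁ES and N decreases wherever binding dominates
(tested against direct quadrature).

**Lipschitz / uniqueness / Ulam–Hyers.** Under sup-norm bounds
b₁..b₄ on the compartments, the kernels are Lipschitz with
Φ₁ = β₁b₂, Φ₂ = β₁b₁, Φ₃ = β₃+β₂, Φ₄ = β₃ and ζ = max Φ_j
(cross-checked against dense finite-difference sampling of the kernels
over the bounded box, within 5 %). With κ̃(t) = t^{δ(t)}/Γ(δ(t)+1),
uniqueness holds on [0, t] when κ_j = κ̃Φ_j ≤ 1 and the Ulam–Hyers
constants are ψ_j = κ̃/(1 − κ̃Φ_j). These are contraction-type
certificates: on [0, 1] with the default parameterization all
κ_j < 1 (worst κ₂ ≈ 0.53), while at t = 200, κ₂ ≈ 106 and the bound
is vacuous. The empirical experiment (`uh_experiment`) therefore
defaults to [0, 1] and refuses horizons where the condition fails
unless explicitly overridden; bounds default to trajectory-derived
sup norms, with user-specified bounds accepted for hand calculations.
Perturbations are supplied as bounded callables and validated by
dense sampling (1000 points). Observed sup deviations under
|ϑ| ≤ ε = 0.01 stay well inside ψ·ε (worst ratio ≈ 0.19) and scale
linearly as ε → 0.

## Reproduction of the published tables

`reproduce_table` runs one simulation per order column (classical RK4
at h = 0.01 for δ = 1; PECE at h = 0.05 otherwise) and extracts H at
t = 0, 20, …, 200, rounding to 4 decimals for display while keeping
machine precision in the data frame. `compare_table` scores each cell
against the printed values with tiered tolerances — 2 % relative for
the scheme-independent integer columns, 5 % for the fractional columns
whose generating scheme was never disclosed — and marks the printed
duplicate rows t = 160/180 as "paper anomaly" instead of scoring them.

The comparison currently **fails the integer-order tier**, and the
discrepancy is informative: the converged classical solution of the
stated model with the stated parameters differs from the printed
integer-order columns by ≈ 3 % at t = 20 and ≈ 7 % from t = 40
onward, consistently across all three delay scenarios — while a
least-squares fit shows the printed column is reproduced to < 0.2 %
by slightly different rates and initial conditions
(β ≈ (0.043, 0.008, 0.040), S₀ ≈ 10.5). The printed values therefore
appear to come from a different parameterization than the printed one;
no consistent integrator (RK4, Euler, Heun, implicit Euler over a wide
range of steps) reproduces them from the stated inputs. The fractional
columns disagree more strongly at late times (their tails decay
nearly exponentially, which no power-law-memory solution does). The
comparison report documents this per cell; the package's own
correctness rests on the property suite (conservation, oracles,
reduction, quadrature mass, stability bounds), which is fully green.

## What the defaults do and do not show

The default conditions are the published study conditions: rates
(0.0530, 0.012, 0.040), initial state (10, 5, 4, 0.1), horizon
T = 200, delay scenarios (0,0)/(0.5,0.5)/(0.5,2), and the six shipped
order functions. Passing tests show the solver reproduces closed-form
fractional solutions, the classical limit, and the model's structural
invariants under these conditions. They do not show that the
variable-order model describes any real enzyme assay (no fitting to
experimental data is attempted), and the positivity finding above
shows that conclusions drawn from small-amplitude order variation do
not automatically extend to larger amplitudes.

## Known limitations

* State-dependent or distributed delays and adaptive stepping are out
  of scope; delays must be grid-aligned.
* The full-history convolution is O(N²); horizons much beyond
  T ≈ 10³ at h = 0.05 become slow.
* Generalized Ulam–Hyers stability with nonlinear comparison functions
  is not implemented; only the linear ψ·ε bound is.
* The frozen-order convention is one of several variable-order Caputo
  definitions; results for strongly varying δ(t) are
  convention-dependent.
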