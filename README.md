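# vokinetics

Variable-order fractional delay kinetics: a simulator for
enzyme–substrate dynamics whose memory strength changes over time.

## The problem

Classical Michaelis–Menten-type enzyme kinetics is memoryless: the
reaction rates at time *t* depend only on the concentrations at time
*t*. Real enzymatic systems show history dependence — slow binding and
unbinding, conformational rearrangement, cofactor regeneration — which
fractional calculus captures through power-law memory kernels, and
which time lags in complex formation capture through explicit delays.
`vokinetics` implements a four-compartment enzyme network (substrate S,
free enzyme E, enzyme–substrate complex H, product P) driven by a
**variable-order Caputo fractional derivative** with two constant
delays:

```
D^{δ(t)} S = β₂H − β₁ES
D^{δ(t)} E = β₃H + β₂H − β₁ES
D^{δ(t)} H = −β₃H − β₂H + β₁ E(t−τ₁) S(t−τ₂)
D^{δ(t)} P = β₃P
```

with δ(t) ∈ (0, 1] a smooth order function (constant, sinusoidal or
linear families), β₁ the binding rate, β₂ the product-formation rate,
β₃ the catalysis rate, and a constant pre-history for t ≤ 0. The
integral (Volterra) form freezes the order at the outer evaluation
time:

```
y(t) = y(0) + 1/Γ(δ(t)) ∫₀ᵗ (t−v)^{δ(t)−1} f(v, y(v), y_lag(v)) dv.
```

The package provides, as separately usable layers:

* **`fractional`** — order functions and Diethelm-type
  product-integration weights (rectangle predictor / trapezoid
  corrector) for the weakly singular kernel, plus the variable-order
  Riemann–Liouville integral.
* **`solver`** — an Adams–Bashforth–Moulton predictor–corrector
  (PECE) for vector variable-order fractional delay systems with
  full-history memory and a refined sub-grid start, and a classical
  RK4 delay path for the δ ≡ 1 regime used as a scheme-independent
  cross-check.
* **`enzyme`** — the kinetic right-hand side, both product-equation
  closures, and runtime monitors (E+H conservation, positivity, total
  mass).
* **`stability`** — the Lipschitz constants Φ₁..Φ₄ = (β₁b₂, β₁b₁,
  β₃+β₂, β₃), the uniqueness contraction factor
  κ_j = t^{δ(t)}/Γ(δ(t)+1)·Φ_j, the Ulam–Hyers constants
  ψ_j = κ̃/(1 − κ̃Φ_j), and a direct perturbation experiment that
  tests the ψ·ε bound empirically.
* **`experiments` / `cli`** — deterministic pipelines that regenerate
  the published trajectory tables and figure series as CSV with YAML
  metadata sidecars, compare them cell by cell against the printed
  values, and validate the rate-constant assignment.

## Worked example

```python
from vokinetics import (PAPER_PARAMETERS, PAPER_INITIAL_STATE,
                        STANDARD_ORDERS, SolverConfig, simulate_enzyme,
                        conservation_check, make_stability_report)

traj = simulate_enzyme(PAPER_PARAMETERS, PAPER_INITIAL_STATE,
                       STANDARD_ORDERS["const_0.97"], delays=(0.5, 2.0),
                       config=SolverConfig(h=0.05, T=200.0))
for t in (0, 20, 40, 100, 200):
    S, E, H, P = traj.at_time(t)
    print(f"t={t:>3}  S={S:8.4f}  E={E:7.4f}  H={H:7.4f}  P={P:10.4f}")
print("E+H drift:", conservation_check(traj, PAPER_INITIAL_STATE))
```

prints

```
t=  0  S= 10.0000  E= 5.0000  H= 4.0000  P=    0.1000
t= 20  S=  1.7641  E= 3.0950  H= 8.4078  P=    0.2112
t= 40  S=  0.2889  E= 6.5469  H= 5.4735  P=    0.4377
t=100  S=  0.0272  E=11.1732  H= 0.9438  P=    3.8524
t=200  S=  0.0056  E=11.9368  H= 0.1310  P=  143.9985
E+H drift: 3.1207774437941236
```

Substrate is consumed, the complex H peaks near t ≈ 20 and decays,
enzyme is regenerated, and the product grows exponentially (the
as-printed closure dP = β₃P). With delays active the E/H cancellation
is broken, so E+H drifts away from its zero-delay invariant value 9 —
here by up to ≈ 3.12 concentration units, driven by the delayed binding
term. A stability certificate on the unit interval:

```python
rep = make_stability_report(PAPER_PARAMETERS, traj, (0.0, 1.0),
                            STANDARD_ORDERS["const_0.97"])
print(rep.constants.as_tuple(), rep.constants.zeta)   # Phi_j and zeta
print(rep.kappas, rep.psis)
```

gives Φ = (0.265, 0.530, 0.052, 0.040), ζ = 0.530, contraction factors
κ = (0.268, 0.537, 0.053, 0.040) — all below 1, so the solution is
unique on [0, 1] and the Ulam–Hyers constants
ψ = (1.38, 2.18, 1.07, 1.06) certify that an ε-approximate trajectory
stays within ψ·ε of the exact one there.

The same pipelines are scriptable from the shell:

```sh
vokinetics table 4                 # regenerate the zero-delay H table
vokinetics compare --table 4       # cell-by-cell comparison report
vokinetics simulate --order cosine:0.98,0.008,10 --tau1 0.5 --tau2 2 \
    --h 0.05 -T 200 --out run.csv
vokinetics stability --interval 0 1
vokinetics validate-mapping
```

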