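# tamsdesign

Design and validation of **two-arm / multi-arm multi-stage (TAMS / MAMS)
time-to-event trials with stopping guidelines for lack of benefit**.

Many randomized phase II/III trials evaluate treatments that ultimately show
no advantage over control. A multi-stage design screens the experimental arm
at a series of interim looks on an *intermediate* outcome **I** (e.g.
progression-free survival) — earlier and more frequent than the *definitive*
outcome **D** (e.g. overall survival) — and terminates recruitment early
whenever the estimated hazard ratio fails to show a predefined advantage. A
multi-arm trial is treated as a set of pairwise comparisons with a shared
control, so the same machinery serves both.

This package is for trial statisticians who need to (a) size such a design,
(b) compute its overall operating characteristics, and (c) validate both by
simulation.

## The model

A design with `s` stages specifies, per stage *i*, a one-sided significance
level `α_i` (strictly descending), a power `ω_i`, and null/alternative hazard
ratios `Δ⁰_i` (usually 1) and `Δ¹_i` (e.g. 0.75). The estimated log hazard
ratio at stage *i* is treated as normal with variances

    σ₀²_i = (1 + 1/A) / e_i            under H₀
    σ₁²_i = 1/e_i + 1/e*_i             under H₁

where `e_i` is the cumulative number of control-arm events at the look, `A`
the allocation ratio, and `e*_i` the expected experimental-arm events under
H₁ at the look time. The stopping boundary is the **critical hazard ratio**

    ln δ_i = ln Δ⁰_i + Φ⁻¹(α_i)·σ₀_i ,

and recruitment stops for lack of benefit if the estimated HR exceeds `δ_i`.
The event target `e_i` is the smallest integer whose **attained power**
`Φ((ln δ_i − ln Δ¹_i)/σ₁_i)` reaches `ω_i`, found by an integer-increment
iteration. Stage calendar times come from a closed-form expected-event
calculus under stagewise-uniform accrual and exponential survival, inverted
by Newton–Raphson; the event targets themselves need only proportional
hazards.

Overall significance level and power are `s`-dimensional normal
lower-orthant probabilities at the stagewise quantiles, with correlations
`R_ij = √(e_i/e_j)` between same-outcome looks and `R_is = c·√(e_i/e_s)`
across outcomes, where `c ∈ (0,1]` is an attenuation factor (default 0.6,
with a sensitivity analysis over [0.4, 0.8] recommended).

The simulator generates patient-level correlated (I, D) times from a
Gaussian copula with exact exponential marginals, runs whole trials with
event-driven looks and Cox partial-likelihood estimates, and reports
empirical stagewise/overall operating characteristics, cross-stage
correlations and the estimated `c`.

## Worked example

A 3-stage design: I-outcome median 1 yr, D-outcome median 2 yr, control-arm
accrual 125 patients/yr, equal allocation, `α = (0.5, 0.25, 0.025)`,
`ω = (0.95, 0.95, 0.9)`, alternative HR 0.75:

```python
from tamsdesign import DesignSpec, build_design, build_R, overall_oc

spec = DesignSpec(3, (0.5, 0.25, 0.025), (0.95, 0.95, 0.9), 0.75,
                  accrual=125, hazard_I=0.693, hazard_D=0.347)
design = build_design(spec)
print(design.to_frame().round(3).to_string(index=False))

oc = overall_oc(spec.alpha, design.attained_powers,
                build_R(design.e_control, c=0.6))
print(f"overall: alpha={oc.alpha_overall:.4f} omega={oc.omega_overall:.4f}")
```

prints

```
 stage outcome  alpha  omega  delta  e_control  e_total  t_end  duration  n_cumulative  power_attained
     1       I  0.500   0.95  1.000         74  133.878  1.538     1.538       384.490           0.951
     2       I  0.250   0.95  0.923        140  256.477  2.262     0.724       565.519           0.951
     3       D  0.025   0.90  0.843        265  484.891  4.369     2.107      1092.267           0.901
overall: alpha=0.0149 omega=0.8448
```

Reading: the first look fires after 74 control-arm intermediate events
(about 1.5 years in), stopping the comparison if the estimated HR on the
intermediate outcome exceeds 1.000; the definitive analysis needs 265
control-arm deaths at about 4.4 years and uses boundary 0.843. About 1092
patients are recruited in total. With attenuation `c = 0.6` the overall
one-sided significance level of the comparison is 0.015 and the overall
power 0.845 — both necessarily below the final-stage 0.025 and 0.9.

The same is available from the shell:

```sh
tamsdesign design --config design.yaml --format csv
tamsdesign oc --config design.yaml --c-grid 0.4:0.8:0.1
tamsdesign simulate --config design.yaml --truth h1 --reps 10000 --seed 7
tamsdesign calibrate --median-d 2 --median-i 1 --rho 0.6
```

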