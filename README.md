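# seqtrial

Group-sequential designs for two-arm clinical trials with binary
endpoints, built around a pair of Phase II/III designs for hospitalized
COVID-19 patients:

- an **intermediate-risk design** (WHO stages 3–5) testing whether a
  treatment raises the proportion of patients discharged by day 15
  (failure is the composite of non-discharge, progression to a higher
  stage, or death), with two interim analyses, 16-stratum randomization
  and continuous toxicity monitoring; and
- a **high-risk design** (stages 6–7) testing a reduction in 30-day
  mortality, with two interims, 8 strata and no toxicity monitoring.

The package is for trial statisticians who need the whole design
pipeline in one reproducible place: error-spending boundaries, sample
sizes, toxicity stopping rules, stratified block randomization, interim
test statistics and patient-level simulation of the resulting operating
characteristics.

## The statistics in brief

Interim z-statistics follow the canonical joint normal model,
`Cov(Z_j, Z_k) = √(t_j/t_k)` at information fractions `t`, with drift
`δ = θ√I_max` under the alternative `θ = p₁ − p₀`. One-sided errors are
allocated by the power-family spending function `f(t) = total·t^ρ`
(`α = 0.05`, `β = 1 − power` spent under the alternative, `ρ = 3`).
Boundaries come from the standard first-passage recursion (Simpson
quadrature + Brent root finding); futility is non-binding by default.
Sample size converts the solved maximum information through the
unpooled-variance identity `I = [p₀q₀/n₁ + p₁q₁/n₂]⁻¹`. Stratified
analysis pools per-stratum risk differences by inverse-variance
weights; toxicity monitoring compares cumulative event counts with a
non-decreasing step boundary whose crossing probability is computed by
exact dynamic programming. Details and numerical conventions are in
[docs/methods.md](docs/methods.md).

## Worked example

The recommended intermediate-risk design: response 40% → 60%, one-sided
α = 0.05, 90% power, 1:2 allocation, looks at 1/3, 2/3 and full
enrollment:

```python
from seqtrial import (DesignInput, LookSchedule,
                      group_sequential_sample_size, inflate_for_dropout)

sched = LookSchedule([1/3, 2/3, 1])
design = DesignInput(0.40, 0.60, alpha=0.05, power=0.90,
                     allocation=(1, 2), schedule=sched)
res = group_sequential_sample_size(design)
print(f"n1={res.n1}  n2={res.n2}  total={res.total}")
print("per-look enrollment:", res.per_look_enrollment)
print(f"attained power: {res.attained_power:.4f}")
print("inflated total:", inflate_for_dropout(res, 0.05).total)
bd = res.boundaries
for k, t in enumerate(sched.fractions):
    fut = f"futility p > {bd.futility_p[k]:.3f}" if k < 2 else "(no futility)"
    print(f"look {k+1} (t={t:.2f}): efficacy p < {bd.efficacy_p[k]:.3f}  {fut}")
```

prints

```
n1=81  n2=162  total=243
per-look enrollment: ((27, 54), (54, 108), (81, 162))
attained power: 0.9023
inflated total: 256
look 1 (t=0.33): efficacy p < 0.002  futility p > 0.830
look 2 (t=0.67): efficacy p < 0.014  futility p > 0.298
look 3 (t=1.00): efficacy p < 0.046  (no futility)
```

Read: the trial enrolls 81 standard-care and 162 treated patients
(256 after 5% dropout inflation). After 81 patients (54 treated) the
trial stops for efficacy only if the one-sided p-value of the
stratified test falls below 0.002, and for futility if it exceeds
0.830; the final analysis declares efficacy below 0.046. Swapping in
`DesignInput(0.70, 0.55, direction="decrease", ...)` gives the
high-risk mortality design (133 / 266 patients) with identical
boundaries.

The same operations are exposed on the command line:

```bash
seqtrial boundaries --alpha 0.05 --power 0.9
seqtrial samplesize --p0 0.4 --p1 0.6 --ratio 1:1 --ratio 1:2
seqtrial toxmonitor --n-observed 5 --n-toxic 2   # -> stop
seqtrial randomize --patients patients.csv --ratio 1:2 --seed 17
seqtrial simulate --config sim.yaml --seed 1
```

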