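# Methods

`seqtrial` implements a pair of group-sequential two-arm designs for
binary endpoints in hospitalized COVID-19 patients — a 15-day-discharge
response design for intermediate-risk patients (WHO stages 3–5) and a
30-day-mortality design for high-risk patients (stages 6–7) — together
with the machinery needed to build, size, randomize, monitor and
simulate them. This note records the model, the numerical choices, and
the places where the design space was genuinely open.

## Sequential model

The test statistic is taken in canonical joint-normal form. At
information fractions `t_1 < … < t_K = 1` the z-statistics satisfy

    E[Z_k] = θ √(t_k I_max),    Cov(Z_j, Z_k) = √(t_j / t_k),

where `θ = p_1 − p_0` is the risk difference and `I_max` the maximum
statistical information. Information fraction is defined as the
fraction of evaluated patients, which for a binary endpoint with a
fixed allocation ratio equals the information fraction exactly. The
*drift* `δ = θ √I_max` is the expected z at full information;
`δ = z_α + z_β` in a fixed-sample design.

### Error spending

Both one-sided error probabilities are allocated over looks by the
power family `f(t) = total · t^ρ` with `ρ = 3` by default: the type-I
error `α = 0.05` is spent under the null, the type-II error
`β = 1 − power` under the design alternative (β-spending). `ρ = 3`
concentrates spending late, so early stopping for efficacy demands
strong evidence (first-look nominal p ≈ 0.002 of the default 3-look
schedule `1/3, 2/3, 1`).

### Boundary recursion

Per-look boundaries are found by the standard first-passage recursion:
the sub-density of the non-stopped score statistic `S_k = Z_k √t_k` is
propagated across looks by numerical integration (composite Simpson on
601 nodes per continuation region, search range ±8.5 SD) and each
boundary is solved by bracketed root finding (Brent, |Δspend| well
below 1e-8). The drift attaining the target power is itself the root
of `u_K(δ) − l_K(δ)`, the gap between the final efficacy and futility
boundaries.

**Futility is non-binding by default.** Efficacy boundaries are
computed ignoring the futility boundary, so the type-I error is
protected even if a monitoring committee overrides a futility stop;
futility boundaries (and power) always honor both. This convention,
which is also the default of the major commercial design packages,
reproduces the published three-look nominal levels of these designs —
efficacy 0.002 / 0.014 / 0.046 with futility 0.830 / 0.298 at 90%
power and 0.835 / 0.312 at 80% — to three decimals, and it yields an
information inflation factor of 1.0415 (90% power) over the
fixed-sample design. The binding construction is available behind a
flag; it gives a final-look nominal p of 0.047 and inflation 1.030,
and does not match the published tables.

A note on the one-interim variant: a single interim at `t = 0.5` with
`ρ = 3` spends 0.05·0.5³ = 0.00625 (nominal 0.006) at the interim. Our
recursion puts the final look at 0.048 and the β-spending futility
threshold near 0.56; published values of 0.047 and 0.716 exist for a
similar design but are not reproducible from any `ρ ∈ {2, 3}` spending
construction we can identify, so the package reports the
spending-consistent values.

## Sample size

The two-proportion comparison uses unpooled variances throughout and
no continuity correction. Information converts to per-arm sizes via

    I(n1, n2) = [ p0 q0 / n1 + p1 q1 / n2 ]⁻¹,   n2 = r · n1,

with `r` the treatment-per-control allocation ratio. The solver takes
`I_max = (δ*/θ)²` from the solved drift, rounds the continuous `n1` up,
and sets `n2 = ceil(r · n1)`; per-look cumulative enrollment is the
per-arm ceiling of the schedule fractions. Attained power is
re-evaluated at the integer sizes through the crossing-probability
recursion. Mortality designs (benefit = rate decrease) map onto the
same canonical increasing-effect scale; binomial variance is symmetric
under complementing both rates, so sample sizes are unchanged.

Dropout inflation multiplies the total by `1 + fraction` (default 5%),
takes the ceiling, and splits preserving the allocation ratio
(treatment arm rounded up). The recommended 1:2 design, total 243,
inflates to 256.

## Toxicity monitoring

The intermediate-risk treatment arm is monitored continuously: after
every evaluated treated patient the cumulative count of adjudicated
toxicity events (CTCAE grade > 2, drug-related) is compared with a
non-decreasing step boundary `b(n)`. The package ships a reference
boundary for monitored toxicity probability 0.25 at stated level 0.01
(change points from (5, 2) to (164, 58)); between change points the
boundary holds the value of the most recent change point, and no stop
is possible below n = 5. Monitoring semantics and boundary
construction are deliberately decoupled: the constructor offers a
pointwise exact-binomial rule (stop when `P(X ≥ k | n, p) ≤` a
per-test level) and a Pocock-type rule whose constant per-test level
is calibrated — by binary search over the attainable set of binomial
tail probabilities, conservatively from below — so the *overall*
crossing probability equals a target. That overall probability is
computed exactly by dynamic programming over (n, count) states of
non-stopped paths; under `p = 0.25` the reference boundary's overall
crossing probability is ≈ 0.73, so its stated 0.01 can only refer to a
per-test-type quantity, and the package reports the DP value rather
than asserting any interpretation.

## Stratification and randomization

WHO stages 1–2 are low risk (not enrolled), 3–5 intermediate, 6–7
high, 8 dead. Intermediate strata cross stage group (3–4 vs 5, i.e.
non-ICU vs ICU), age (< 60 / ≥ 60), sex, and a cardiovascular-risk
flag (any of obesity, hypertension, diabetes): 16 strata. High-risk
strata drop the stage factor (stage 7 is too scarce to stratify on)
and cut age at 65: 8 strata. Stratum indices follow the fixed order
(stage, age, sex, cvd) so assignments are reproducible; stage-7 counts
per arm can be surfaced from the assignment records when the analyst
needs the drop-stage-7 contingency.

Randomization is Zelen-style stratified permuted blocks with an
independent stream per stratum, seeded by (seed, stratum index). For
1:1 allocation each block's size is drawn uniformly from {4, 6}; a 1:2
split cannot fit a block of four, so 1:2 uses fixed blocks of six
(2 + 4). Within-stratum imbalance is therefore bounded by 3 and
completed blocks are exactly balanced.

## Stratified analysis

Within each stratum the treatment effect is the risk difference;
strata are pooled by weights and the pooled z is compared with the
nominal boundary p-values. Three schemes are provided:

- `inverse_variance` (the `stratified_z` default): weights are
  reciprocals of the unpooled variances `p̂1q̂1/n1 + p̂2q̂2/n2`; with one
  stratum this is exactly the ordinary unpooled two-proportion z.
  Degenerate arms (0% or 100%) contribute through variances evaluated
  at shrunk proportions `(x + 0.5)/(n + 1)`.
- `null_variance` (the simulator default): stratum variances are
  evaluated at the pooled within-stratum proportion. Estimated
  unpooled weights correlate with extreme observed differences when
  strata hold only a few patients per arm — at the first look of the
  216-patient design this inflates the empirical type-I error to
  ≈ 0.15 — whereas the pooled-proportion weights are nearly
  independent of the differences and keep the empirical size at the
  nominal level (≈ 0.05).
- `cmh`: Cochran–Mantel–Haenszel count pooling against the
  hypergeometric null variance (cross-checked against
  `statsmodels.stats.contingency_tables.StratifiedTable`).

Strata with fewer than 2 patients in either arm at a look are merged
into the nearest adequate stratum by canonical index before testing.

## Simulator

Each replicate draws stratum membership from a prevalence mix (uniform
over the risk group's strata by default — real enrollment will be
skewed toward older, male, comorbid patients, but with homogeneous
within-arm rates the operating characteristics depend on the mix only
through block-filling granularity), randomizes with the block scheme,
draws independent Bernoulli outcomes at the arm's true rate and
independent Bernoulli toxicity flags on the treated, monitors toxicity
continuously, and evaluates the stratified statistic at each look's
cumulative enrollment. Outcomes are treated as available at
evaluation: the 15-/30-day windows define the endpoint, not the
timeline, so no accrual or readout lag is modelled. Toxicity and
efficacy outcomes are independent; correlated toxicity–response models
are out of scope. All randomness descends from (seed, replicate,
stratum) keys, so a configuration and seed fully determine the result.

With 10,000 replicates of the recommended 1:1 design (108/arm) the
empirical power at 0.40 → 0.60 is ≈ 0.90 and the empirical type-I
error ≈ 0.05; tolerance bands in the tests are three Monte-Carlo
standard errors plus a 0.01 allowance for binomial discreteness and
blocked-allocation effects, since the boundary theory is a continuous
normal approximation. What passing these simulations shows is that
the calculator, the randomizer and the monitor are mutually
consistent under the design's own assumptions; it does not validate
those assumptions (independent outcomes, fixed rates, instantaneous
evaluation) against real trial data.

## Known limitations

- Power and sample size use the normal approximation; exact binomial
  operating characteristics at very small n (< ~15/arm cells of the
  sample-size tables) will deviate by more than the tables suggest.
- Repeated confidence intervals, stage-wise adjusted estimates and
  conditional power are not provided.
- Allocation ratios other than 1:1 and 1:2 pass through the design
  solver but the randomizer's block scheme supports only those two.
- The reference toxicity boundary is abbreviated at its published
  change points; between the n = 28 and n = 52 change points the step
  interpolation is coarser than a fully enumerated boundary would be.
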