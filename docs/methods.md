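# Methods

## The simulated decision problem

The package models a single ICU in situational overload.  Beds are a hard
resource: `B` identical, fully staffed treatment capacities.  Demand
exceeds supply at initialization (`d > B`) and again at every consecutive
time point, when `w` new patients queue for the unit.  The model excludes
natural patient flows — nobody recovers or dies *during* the horizon, and
a patient's prognosis is frozen at arrival — so the only dynamics are the
allocation decisions themselves.  Patients never admitted, or discharged
by ex post triage, leave the system permanently; the outcome measure is
the prospective mortality of the currently treated cohort,
`m_t = (1/B)·Σ y_i`, not population mortality.  This isolates exactly the
quantity the policy debate is about (what happens *on the unit*) at the
price of ignoring what happens to the turned-away.

## Death-probability distributions

Each group's death probability follows a triangular distribution
`Δ(minimum; maximum; mode)` — note the display convention: the mode is
listed third although its magnitude lies between minimum and maximum.
The triangle was chosen over a beta or logit-normal because its three
parameters map directly onto the minimum, maximum and most frequent case
fatality reported by surveillance data.  The baseline group uses
`Δ(0.04; 0.41; 0.045)` with mean `(0.04+0.41+0.045)/3 = 0.165`.

Comorbidity distributions are calibrated from published odds/hazard
ratios, treated uniformly as "relative risks of death" and applied to the
baseline mean: the target is `E(p|k) = RR_k × 0.165`.  Confidence
intervals of the ratios are carried as metadata only; the point estimate
drives the simulation.  The hypertension group ships the published triple
`Δ(0.19; 0.63; 0.23)` (mean exactly 0.35).  For the other four conditions
no published triple exists, so the package derives one (`strategy:
"scale"`):

1. scale the whole baseline triple by `RR` (this multiplies the mean by
   `RR` and preserves the left-skewed shape exactly);
2. if the scaled maximum exceeds 1, pin the maximum at 1 and re-solve
   under the mean constraint `a + c = 3·E − 1`, keeping the scaled
   minimum and raising it only as far as the constraint forces
   (`a = max(RR·a, 3E − 2)`), with the mode absorbing the remainder.

Step 2 guarantees support `⊆ [0,1]` and — because `3E − 2 < 0.41`
for every relative risk whose target mean is a probability — keeps the
derived minimum below the baseline maximum, so the supports overlap and a
comorbid patient can genuinely out-rank a healthy one.  For high relative
risks (CVD at 4.85, target mean 0.80) the feasible window is narrow: any
valid triple must have its minimum in `[0.40, 0.41)` and mode near 1, so
the derived distributions for CVD and trisomy 21 are strongly
right-concentrated.  Every derived triple is written to the run manifest.

A caveat that matters when interpreting the single-comorbidity battery:
how much ex post triage helps depends on the *spread* of the calibrated
distribution, not only its mean.  The derived type-2-diabetes triple has a
long right tail while the published hypertension triple is narrow, so
hypertension — despite the slightly larger relative risk — shows the
smallest triage benefit of the five conditions.  The package asserts only
the robust ordering (both high-RR conditions benefit more than both
low-RR conditions); the within-pair order is an artifact of the
underdetermined derivation and should not be over-read.

The overlap coefficient `∫ min(f1, f2) dx` is computed by exact
piecewise-linear segment arithmetic (breakpoints at the six parameter
points plus density crossings, trapezoid integration of linear pieces)
rather than quadrature, removing any tolerance ambiguity.  For the
baseline/hypertension pair it evaluates to 31.71%, close to the commonly
cited 31.35% — the residual difference presumably reflects a plot-based
or differently rounded computation upstream and is treated as
irreducible; the parameters are *not* adjusted to force agreement.

## Prevalence weights

The assignment probabilities for the five conditions inside the comorbid
group are not published as numbers.  The packaged defaults are German
adult population prevalences — hypertension 0.32, type-2 diabetes 0.09,
cardiovascular disease 0.06, trisomy 21 0.002, ALS 0.00008 — normalized
within category after the fixed 10%/90% impairment/pre-existing split.
They are a documented, editable block in `data/profiles.yaml`, every run
manifest records the weights used, and they should be replaced when
better estimates exist.  With these defaults the comorbid-group expected
death probability is ≈0.438 and the cohort mixture mean ≈0.356.

## Simulation and seeding

One replication: generate the `d`-patient demand, fill the unit by the
policy's initial rule, record metrics; then for each `t = 1..T` generate a
fresh `w`-patient queue (t=0 overflow does not roll over), apply the
consecutive rule, record metrics.  The random consecutive rule exchanges
`k = round(0.1·B)` beds (capped at the queue length); ex post triage keeps
the `B` lowest decision scores of the pooled treated+queue, with ties
broken by patient id (ties have probability zero under continuous draws
but must be deterministic).  Decision scores `e·p_i` are never clipped —
they are ordinal, and clipping could create artificial ties.

Each replication seed spawns two independent sub-streams: patient
generation and policy randomness.  All policies consume the generation
stream identically (the full demand is always generated, with random
initial occupancy implemented as a uniform choice of `B` from `d` — 
distributionally identical to generating only `B`), so under the default
paired-seed design policies sharing an initial rule see identical `t = 0`
cohorts replication-by-replication, and varying `e` leaves every decision
bit-identical.  `paired=False` (CLI `--independent-seeds`) gives each
policy its own stream for an independent-samples design.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `B` | 60 | operable ICU beds (a large university hospital in a peak situation) |
| `d` | 70 | patients competing at initialization |
| `w` | 10 | queue length per consecutive time point |
| `T` | 3 | consecutive triage cycles after `t = 0` |
| `s` | 0.7 | fraction of patients with a comorbidity |
| `impairment_share` | 0.1 | P(impairment | comorbid); rest pre-existing |
| `e` | 1.0 | misestimation factor on decision scores (ordinal only) |
| `R` | 10,000 | Monte-Carlo replications per policy |

With `R = 10,000` the standard error of a reported mean mortality is
below 0.1 percentage points (per-replication SD of `m_t` is ≈ 0.05–0.09),
so differences of a percentage point or more are Monte-Carlo-stable.

## Statistical comparison

`compare_policies` runs a one-way ANOVA across policies on the
per-replication overall mortality at a chosen time point, followed by
all-pairs post-hoc tests (Tukey HSD by default; Bonferroni-corrected
Welch tests as an alternative — the correction is named in the output).
The unit of analysis is the replication, which is the natural choice here
though other aggregations are conceivable.  Pairs sharing an
initial-occupancy rule are flagged as expected nulls at `t = 0`; under
paired seeds their `t = 0` samples are literally identical, in which case
the pairwise test degenerates and is reported as non-significant.  A
fully degenerate comparison (zero variance everywhere) returns NaN with a
diagnostic note rather than a spurious F.

## What the generator does and does not emulate

The synthetic cohorts reproduce the *study conditions*: group mixture,
calibrated marginal death probabilities, frozen outcomes, and fixed
arrival batches.  They do not emulate real ICU data: no arrival process,
no length of stay, no time-varying prognosis (scores in practice shift
substantially during treatment), no correlation between comorbidity and
age or between queue composition and time.  Passing tests therefore
demonstrate properties of the allocation mechanisms under these
idealized conditions — e.g. that ex post triage lowers treated-cohort
mortality and that the comorbid group bears most of the discharge burden
— not predictions for any specific hospital.

## Numerical and engineering choices

- Sampling is by inverse-CDF transform of uniforms (closed form), checked
  against an independent reference implementation (scipy's triangular
  distribution) and by KS tests at the 1% level in the suite.
- Degenerate inputs: a point-mass triple samples its atom; an empty
  patient group reports mortality `None`/NaN, never 0; `R = 1` reports
  NaN standard deviations with a warning.
- The acceptance script runs `R = 10,000` replications of policy 5 only
  (the quantities it reports need no other policy), which keeps it under
  a minute on one CPU; the test suite runs the full six-policy reference
  experiment once per session.
- Replications are plain Python loops over numpy-backed cohorts
  (~1 ms per replication); the full reference experiment is ~1 minute.

## Known limitations

All limitations of the underlying model apply: turned-away patients are
assumed lost (mortality is conditional on treatment), prognosis is static,
pure ex ante triage of a whole unit is unrealistic and serves as a bound,
and results transfer to other regions only insofar as the relative risks
and prevalence weights do.  The derivation of non-hypertension triples is
one defensible rule among several; conclusions that depend on the shape
(not the mean) of a derived distribution should be checked against
alternative parameterizations supplied via a custom profile file.
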