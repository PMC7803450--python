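# Methods

## The decision problem

`hypercea` evaluates whether starting antihypertensive drug treatment is
cost-effective for adults with stage 1 hypertension (clinic blood pressure
140–159/90–99 mm Hg) without established cardiovascular disease (CVD),
stratified by 10-year CVD risk. Two strategies are compared over a lifetime
horizon from the perspective of a single payer: start drug treatment now, or
start it only after a first CVD event. The output of the deterministic
comparison is an incremental cost-effectiveness ratio (ICER = ΔC/ΔQ in £ per
quality-adjusted life-year); a strategy is deemed cost-effective when it is
dominant or when its ICER is at or below the willingness-to-pay threshold
λ = £20 000/QALY.

## Model structure

A Markov cohort model with 1-year cycles over 15 states:

* `well` — alive, no CVD event;
* six event-year *tunnel* states, one per nonfatal first-event category
  (stable angina, unstable angina, myocardial infarction, stroke, transient
  ischaemic attack, heart failure), occupied for exactly one cycle and
  carrying first-year costs and utility multipliers;
* six corresponding post-event states, left only by death — repeat events
  are not modelled, so post-event care costs are set to include downstream
  event costs where the user's cost inputs allow;
* two absorbing death states (`death_cvd`, `death_noncvd`).

The whole cohort starts in `well`. Occupancy is propagated through per-cycle
row-stochastic transition matrices (occupancy(t+1) = occupancy(t)·M(t)). The
horizon is `min(max_cycles, max_age − start_age)` cycles: at most 60 cycles
and never past age 100 (`max_age`), by which point almost all of the cohort
has died.

## Baseline risk calibration

Each scenario is defined by a 10-year first-event risk `r10`. The annual
probability of a first event starts at `p1` and rises additively by a fixed
increment δ per year of age, continuing past year 10:

    p(t) = p1 + (t − 1)·δ,     1 − Π_{t=1..10} (1 − p(t)) = r10.

The compounding identity pins down `p1` given δ; it is solved by guarded
bisection on (1e-12, 1 − 9δ − 1e-12) to an interval width of 1e-13 (the
product is strictly increasing in `p1`, so the root is unique). δ itself is
a model input: the identity is one equation in two unknowns, so the
increment cannot be inferred from `r10` alone. If δ alone compounds past
`r10`, the configuration is rejected as infeasible rather than silently
truncated. The per-cycle total risk is split across the seven first-event
categories (six nonfatal plus fatal CVD) using the event-distribution table
for the age band and sex reached at that cycle, and is capped at
`max_annual_risk` (default 0.95) with a logged warning.

In the synthetic fixtures δ is tied to the subgroup: δ = 0.01·r10 per year
(0.001/year for the 10% subgroup). A single absolute δ across subgroups
would make the calibration infeasible below r10 ≈ 45δ; the proportional rule
keeps every subgroup (and the threshold search, which varies `r10`
continuously while holding δ/r10 fixed) well posed.

## Mortality

Non-CVD mortality in the `well` state is the all-cause lifetable probability
times the non-circulatory death fraction at the current age and sex, so
that circulatory deaths enter only through the calibrated CVD risk. In
event-year and post-event states, total mortality is the all-cause
probability scaled by a per-category standardized mortality ratio (SMR) on
the rate scale, q' = 1 − (1 − q)^SMR, which stays below 1 for any SMR ≥ 1.
The background non-circulatory share (q·f_noncirc) is attributed to non-CVD
death and the remainder — circulatory background plus the SMR excess — to
CVD death; `excess_death_to_cvd=False` switches to splitting the total by
the non-circulatory fraction instead.

Setting `r10 = 0` (allowed as a degenerate limit) with the non-circulatory
fraction at 1 removes all CVD pathways, and the model's survival curve then
reproduces the lifetable product exactly; this is the standard lifetable
validation exercise and is enforced by a test.

## Treatment

Treatment multiplies each first-event probability — including fatal CVD —
by a category-specific relative risk, itself multiplied by an age-band
transformation factor; non-CVD mortality is unaffected. Relative risks are
assumed constant across risk subgroups, so absolute benefit scales with
baseline risk. The treated arm is on treatment whenever alive. The
comparator arm starts treatment after any nonfatal event (event-year and
post-event states), and otherwise never, unless a finite
`comparator_treatment_delay` is configured — the differential-duration
sensitivity analysis. While on treatment an arm incurs annual drug and
monitoring costs and an expected adverse-event burden (annual probability ×
cost, and × disutility), applied to alive on-treatment person-years with no
explicit adverse-event state; event-year states are included. Off-treatment
person-years can carry a background adverse-event probability (default 0).

## Payoffs, discounting, half-cycle correction

State utility = general-population baseline utility (age band, sex) ×
event/post-event multiplier, minus expected adverse-event disutility;
negative values are clamped to 0 with a warning. Recurring payoffs
(utilities; drug, monitoring, adverse-event and post-event annual costs)
accrue on the mean of the two cycle-boundary occupancies (half-cycle
correction — transitions happen on average mid-cycle). One-off costs are
deliberately not half-cycle corrected: the first-year cost of a nonfatal
event applies to the full end-of-cycle occupancy of its tunnel state, and
the fatal-event cost to the cycle's increment in CVD-death occupancy,
because these are within-cycle quantities, not boundary stocks. Cycle t
(1-based) is discounted by (1+r)^(−t) with r = 3.5%/year for both costs and
QALYs (NICE reference case); an event-free immortal cohort therefore
reproduces the annuity factor (1 − (1+r)^(−n))/r exactly.

## Incremental analysis

`compare` reports ΔC, ΔQ (treated − comparator), the ICER when the ratio is
meaningful, dominance labels (dominant ⟺ ΔC<0 ∧ ΔQ>0; dominated ⟺ ΔC>0 ∧
ΔQ<0), net monetary benefit λ·ΔQ − ΔC, and the cost-effectiveness verdict.
|ΔQ| < 1e-12 is treated as a tie: the ICER is undefined and the comparison
reduces to cost minimization.

The 10-year number needed to treat is the deliberately crude companion
statistic: NNT = 1/(r10·(1 − mean RR)) with the unweighted mean of the
effective per-event relative risks at the starting age, reported rounded up
alongside the raw value. It uses the 10-year risk directly, not the modelled
lifetime trajectory.

## Probabilistic sensitivity analysis

Each draw resamples the uncertain parameters independently from
role-appropriate families — beta for probabilities and utility multipliers
(method-of-moments from mean and SE), gamma for costs (mean and SE),
lognormal for relative risks (median = base RR, SD on the log scale) — and
reruns both arms. Draws are reproducible from (seed, draw index) via
independent substreams; a draw violating any parameter invariant is
resampled up to 50 times, then errors. The probability cost-effective at λ
is the fraction of draws with NMB(λ) > 0; the CEAC sweeps λ over £0–£50 000
in £1000 steps. Default 5000 draws. No correlation structure is imposed
(none is specified for the inputs). Drug and monitoring costs are treated
as tariffs and held fixed by the default specification; everything else
uncertain gets a distribution (RRs: log-SD 0.08; costs: 20% CV; utility
multipliers: SE 0.03).

## Threshold search

For a given age/sex, NMB at λ rises with baseline risk. `find_threshold_risk`
first probes the bracket (default 1%–30% 10-year risk, 5 probes) and raises
a diagnostic error if NMB is not monotone, then bisects for the sign change
to an absolute tolerance of 1e-4 on the risk scale (0.01 percentage points —
far finer than the ~1-point precision at which such thresholds are usually
reported). If treatment is already cost-effective at the lower edge, or
still not at the upper edge, the edge is returned with an explanatory flag
instead of a root. `probabilistic_threshold` reruns the PSA at a given risk;
at the deterministic threshold the probability sits near 0.5 by
construction.

## Synthetic parameter bundles

No deposited dataset exists; the model consumes parameter tables. The
`synthetic` module generates complete bundles so the pipeline is testable
offline. The base-case fixture is a deterministic, realistic-scale UK-like
stand-in — it is **not** the published input set, and nothing in the package
pretends otherwise. A `fixtures/supplement_transcribed/` slot is reserved
for users who transcribe the published tables; until then the tests that
require the published headline numbers fail with an explanatory message.

Generator ranges (chosen once at field-plausible magnitudes):

| Input | Base-case fixture | Random generator range |
|---|---|---|
| All-cause mortality | Gompertz A·e^(B·age), A=4.0e-5/2.2e-5 (M/F), B=0.090/0.092, cap 0.9 | A ∈ [1.5e-5, 8e-5], B ∈ [0.082, 0.098] |
| Non-circulatory fraction | 0.85 − 0.0025·(age−40), clipped to [0.55, 0.95] | base ∈ [0.7, 0.9] |
| First-event split | 3 age bands × sex, e.g. male 60–74: SA .16, UA .09, MI .25, stroke .22, TIA .11, HF .07, fatal .10 | Dirichlet-style (normalized gamma) |
| SMR | SA 1.4, UA 1.8, MI 2.5, stroke 2.2, TIA 1.5, HF 3.0 | [1, 3] |
| Relative risks | stroke 0.75, HF 0.72, TIA 0.80, MI 0.85, UA 0.88, SA 0.90, fatal 0.85 | [0.6, 1.0] |
| RR age factors | 0.95 / 1.00 / 1.05 (bands 40–59 / 60–69 / 70+) | [0.9, 1.1] |
| Baseline utility | 0.87→0.72 (M), 0.85→0.69 (F) over 5 age bands | start [0.80, 0.95], non-increasing |
| Event-year utility multipliers | stroke 0.63 … TIA 0.90 | [0.5, 1.0] |
| Costs | drug £30/yr, monitoring £45/yr; event year £1600–£11 500; post-event £120–£2100/yr; fatal £1700 | drug [10, 100], events [1000, 15 000], post [100, 3000] |
| Adverse events | p=0.02/yr on treatment, £400, disutility 0.05 | p [0, 0.05], cost [0, 1000], disutility [0, 0.2] |
| Risk increment δ | 0.01·r10 per year | [0, r10/60] |

What the generator emulates: the stratification structure (age bands, sex),
orders of magnitude (event costs ≫ annual treatment costs; generic
antihypertensives are cheap), monotone age gradients, and internal
consistency constraints. What it does not: the published point estimates,
between-parameter correlation, secular mortality trends, or risk-calculator
(QRISK) linkage. Passing tests therefore demonstrate the *method* —
calibration, conservation, dominance logic, CEAC mechanics — at realistic
scales, not the published point results.

## Numerical choices

* Calibration bisection: interval width 1e-13, ≤200 iterations; residual on
  the compounded risk well below 1e-9.
* Transition-matrix rows are constructed to sum to 1 and rejected if they
  deviate by more than 1e-9; well-state exits summing above 1 are a hard
  error rather than a renormalization.
* Serialization writes floats with shortest round-trip repr and reads with
  round-trip parsing, so save→load→save is byte-identical.
* Ages advance one integer year per cycle; all table lookups use the
  current integer age (no interpolation between bands).
* Ties in cost-effectiveness (|ΔQ| < 1e-12) are labelled, not ratioed.

## Problem sizes used in the shipped checks

The test suite's microsimulation cross-check runs 10^6 individuals over a
12-cycle high-risk scenario (every state frequency within three binomial
standard errors of the cohort trace). Property tests run the calibration
inversion over 1000 random (r10, δ) pairs. `scripts/acceptance.py` runs the
deterministic grid, two threshold searches, and four PSAs of 1000 draws
each — a couple of minutes end to end on one core. These sizes are the
package's own reporting choices; all are user-adjustable.

## Known limitations

* No repeat CVD events and a single one-year tunnel per event; post-event
  costs must absorb downstream event costs.
* Adverse events enter as expected values, not states; severe, persistent
  harms are under-represented in the tails of the PSA.
* Independent PSA draws; correlated uncertainty (e.g. between event costs)
  is not modelled.
* The additive risk increment is linear in age for life; real CVD risk
  accelerates at older ages, which biases against treatment in the oldest
  cohorts.
* Treatment adherence is assumed perfect; trial-derived relative risks may
  overstate real-world effect.
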