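# hypercea

A Markov cohort cost-utility model for deciding **at what 10-year
cardiovascular disease (CVD) risk it becomes cost-effective to start
antihypertensive drug treatment in stage 1 hypertension** (clinic blood
pressure 140–159/90–99 mm Hg, no established CVD). It is written for health
economists and guideline modellers who want a scriptable, testable
implementation of this class of decision model: lifetime QALY/cost
accumulation with half-cycle correction, probabilistic sensitivity analysis
with acceptability curves, and a risk-threshold search.

## The model in brief

Two strategies are compared for a cohort of given age, sex and 10-year
first-CVD-event risk r₁₀: start drug treatment now, versus start it only
after a first CVD event. The cohort moves through 15 states — well, six
one-year event states (stable/unstable angina, MI, stroke, TIA, heart
failure), six post-event states, and CVD/non-CVD death — in annual cycles
up to 60 cycles, never past age 100.

The annual first-event risk is calibrated so that, growing by a fixed
additive increment δ per year of age, it compounds to the subgroup risk:

    1 − Π_{t=1..10} (1 − (p₁ + (t−1)δ)) = r₁₀

Treatment multiplies each event probability (including fatal CVD) by a
relative risk with an age-band adjustment, and adds drug/monitoring costs
plus an expected adverse-event cost and disutility. Post-event mortality is
the lifetable probability scaled by a standardized mortality ratio on the
rate scale, q′ = 1 − (1 − q)^SMR. Costs and QALYs are half-cycle corrected
and discounted at 3.5%/year; the headline statistics are

    ICER = ΔC / ΔQ        NMB(λ) = λ·ΔQ − ΔC        NNT = 1 / (r₁₀(1 − R̄R))

with treatment cost-effective when dominant or ICER ≤ λ = £20 000/QALY.

All inputs live in a `ParamSet` (YAML config + CSV tables; see
`fixtures/base_case/` for the format). The shipped parameter bundle is a
**synthetic, realistic-scale stand-in**, generated by `hypercea.synthetic`;
it reproduces the structure and magnitudes of published base-case inputs
for this decision problem, not their exact values.

## Worked example

```sh
hypercea compare --age 60 --sex male --risk 0.1 --out out/
```

prints (numbers from the synthetic base case):

```json
{
  "age": 60,
  "sex": "male",
  "r10": 0.1,
  "cost_treated": 3090.41,
  "cost_comparator": 2351.44,
  "qalys_treated": 11.3845,
  "qalys_comparator": 11.2756,
  "delta_cost": 738.97,
  "delta_qalys": 0.1089,
  "icer": 6785.77,
  "label": "icer",
  "nmb": 1439.03,
  "cost_effective_at_wtp": true,
  "wtp": 20000.0,
  "nnt_10yr": 56
}
```

Reading this: starting treatment at age 60 with a 10% 10-year risk costs an
extra £739 over the cohort's remaining lifetime and gains 0.109 QALYs per
person, i.e. £6786 per QALY gained — comfortably below the £20 000
willingness-to-pay, so treatment is cost-effective for this subgroup (net
monetary benefit +£1439 per person). Fifty-six such people must be treated
for ten years to prevent one CVD event.

Other entry points, all with `--help`:

```sh
hypercea simulate   --arm comparator --out out/    # cohort trace CSV per arm
hypercea psa        --draws 5000 --seed 1 --out out/  # PSA scatter, CEAC, summary
hypercea threshold  --sex female --out out/        # risk threshold + probability
hypercea scenarios  --out out/                     # full age x sex x risk table
hypercea make-fixtures --age 70 --risk 0.15 --out fixtures/my_case
```

The same operations are available as library functions
(`hypercea.run_arm`, `compare`, `run_psa`, `find_threshold_risk`,
`run_scenarios`, …); every run writes its resolved parameter bundle and
seed next to its outputs so it can be reproduced exactly.

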