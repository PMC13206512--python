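# Methods

## Scope and model structure

`ascvdsim` is a patient-level discrete-event microsimulation of lifetime
atherosclerotic cardiovascular disease.  Each simulated person carries a
lifetime lipid set-point (LDL-C, HDL-C, triglycerides), a sex, comorbidity
latents, and a growing event history; the population is organised as four
equal birth cohorts defined by the HDL-C/LDL-C ratio (cut at 0.45 / 0.35 /
0.25) with a parallel four-way classification on LDL-C alone (3.1 / 4.0 /
5.0 mmol/L).  Both partitions are lower-closed: a ratio of exactly 0.45
belongs to the low-risk group.  The ratio cut points are sometimes quoted
with the boundary attached to the very-high-risk side; we fix the
lower-closed convention throughout because it is the one consistent with the
reference tables, and expose the cut points in `RiskGroupSpec` for anyone
who wants the other convention.

Five event types compete: myocardial infarction (MI), ischaemic heart
disease (IHD), ischaemic stroke (IS), heart failure (HF), and death from any
other cause.  Haemorrhagic stroke, treatment pathways, costs, and
calendar-period effects are out of scope; time is pure cohort age.

## Hazards

**Cumulative exposure.**  Lipid levels are treated as stable over life, so
cumulative LDL-C exposure is the running integral of the set-point:
E(t) = 38.67 · L · t in mg/dL-years (38.67 mg/dL per mmol/L).  Exposure
accrues from birth.

**MI** follows the cumulative-exposure picture of atherogenesis:

    h_MI(t) = λ0(sex) · e^{a·t} · m_s · exp(β · max(E(t) − E*, 0)) · RR_comorb · r

with threshold E* = 5000 mg-years, excess slope β (per mg-year), per-stratum
multiplier m_s, and a recurrence multiplier r after a first non-fatal MI or
IHD event.  The exponential form in (E − E*) is the minimal form consistent
with risk "rising exponentially" past a threshold, and it is continuous at
the threshold by construction.  The stratum multiplier, not the threshold,
is what produces very early events in the worst stratum: exposure alone
cannot cross 5000 mg-years before roughly age 35 at realistic LDL-C levels,
whereas first MIs in the very-high-risk group are seen from about age 20.

**IHD** shares the MI shape (same stratum multiplier and exposure term) at a
lower baseline.  A single shared multiplier cannot reproduce the MI and IHD
stratum gradients simultaneously — the IHD gradient across the middle strata
is flatter than the MI gradient — and the calibration prioritises MI; see
Limitations.

**IS** scales as a power law in the LDL-C level: each 1 mmol/L decrease
multiplies the hazard by `stroke_rr_per_mmol` = 0.84 (a 16% reduction),
relative to a reference level of 3.0 mmol/L.  The hazard is zero before an
onset age of 60 y — first strokes occur decades after first MIs — and grows
exponentially with age past onset.

**HF** has no lipid term at all: only age, sex and comorbidity relative
risks.  Its apparent *decline* across risk strata in lifetime counts is
purely survivorship.

**Other-cause mortality** is Gompertz–Makeham per sex,
μ(t) = c + α·e^{γt}, with parameters chosen to give background life
expectancies of about 84 y (women) and 80 y (men) before ASCVD mortality is
added.

**Comorbidities** (smoking, diabetes, hypertension, atrial fibrillation,
and systolic blood pressure per 10 mmHg above 120) enter as multiplicative
relative risks, the standard log-linear epidemiological convention.  Onset
is governed by non-decreasing age-ramp prevalence curves and a fixed latent
uniform per person per condition, so a flag can switch on but never off.

## Discrete-event engine

Cycles are annual (configurable down to any step ≤ 1 y).  Within a step all
hazards are held at their start-of-step values, one exponential candidate
time is drawn per event type, and the earliest candidate inside the step
fires; the others are discarded.  At most one clinical event occurs per
step: after a non-fatal event the person completes the step event-free.
Fatal events terminate the trajectory at the event time; survivors at the
age cap (110 y) receive a forced other-cause death exactly at the cap, so
every completed history ends in exactly one fatal record.  Event fatality is
a Bernoulli draw from a per-event, per-sex, per-stratum case-fatality table.

Randomness is organised as per-person substreams keyed by (seed,
person_id); each person consumes one pre-drawn block of variates.  Cohort
results are therefore invariant to execution order, and the vectorized
array driver reproduces the scalar per-person driver event-for-event (this
equivalence is asserted in the tests).

## Synthetic population

The generator emulates the statistical *shape* of adult lipid panels and
comorbidity prevalence — correlated log-normal lipids with a negative
TG/HDL-C correlation, sex- and stratum-specific metabolic markers — not any
individual-level dataset.  Within a stratum the ratio is drawn from a
log-normal restricted to the stratum interval by rejection; the underlying
location is pre-compensated analytically (truncated log-normal mean,
inverted by root finding) so that post-rejection stratum means of LDL-C and
HDL-C match the configured targets exactly in expectation.  LDL-C is drawn
independently and HDL-C is the product ratio × LDL-C.  Sexes are split
deterministically 50/50.  Rejection sampling aborts with a configuration
error if the acceptance rate falls below 10⁻³.

What the generator does *not* emulate: within-life lipid drift (set-points
are fixed, consistent with lipid stability over age in the absence of
treatment), ethnicity-specific lipid structure, secular trends, measurement
error, and any correlation between lipids and non-lipid risk factors beyond
the shared stratum index.  Passing tests therefore demonstrate the internal
consistency of the model under these idealised conditions, not calibration
to any real cohort.

## Outcomes

Life expectancy is the mean age at death.  QALYs integrate an age-declining
baseline utility (intercept ≈ 0.94, slope 0.0022/y, floor 0.35) times
multiplicative decrements for prevalent conditions (post-MI 0.88, post-IS
0.85, HF 0.80, IHD 0.92, diabetes 0.95), in closed form per piecewise
segment.  Discounting defaults to zero: the QALY/life-expectancy ratios of
the reference tables (≈ 0.84–0.86 across strata with very different life
expectancies) are inconsistent with material discounting.

Event counts per 100,000 births count *persons with at least one qualifying
event* per type (first occurrence); heart failure qualifies only when no
IHD event precedes it, matching the convention of the reference event
table.  The mortality-adjusted cumulative stroke risk is the net-risk
product-integral of the cause-specific hazard — a Kaplan–Meier complement
with competing deaths treated as censoring (computed via `lifelines`).
"Mortality adjustment" is not uniquely defined in the literature summaries
this package mirrors; the net-risk construction is this package's choice,
and alternative estimators (e.g. subdistribution risk) can be swapped in at
the `mortality_adjusted_cum_risk` boundary.  The net curve dominates the
crude curve pointwise by construction.

## Calibration

The baseline rates and multipliers are not published quantities; they are
declared calibration parameters stored in `src/ascvdsim/data/
default_config.yaml` and tuned toward soft lifetime targets: stratum-1
lifetime MI risk ≈ 5% and life expectancy ≈ 80 y, stratum-4 lifetime MI
risk ≈ 73%, a roughly twofold male excess of MI in strata 1–3, lifetime MI
case fatality spanning roughly 49–64% and IHD 34–86% across sex-by-stratum
cells, and the stroke survivorship inversion.  Per-event case-fatality
probabilities were set below the target *lifetime* (person-level) fatality
shares because recurrent events compound: a person who survives a first MI
in a high-hazard stratum faces repeated further opportunities for a fatal
one.

Residual misfits of the default calibration, stated so nobody mistakes them
for noise: the very-high-risk stratum reaches ≈ 72% lifetime MI with
person-level MI fatality ≈ 0.71–0.78 (above the ≈ 0.62–0.64 share implied by
per-event rates — the recurrence floor); its male life expectancy is ≈ 62 y
rather than ≈ 55 y; and IHD shares in the middle strata overshoot because
the stratum multiplier is shared with MI.  All qualitative lifetime
patterns — strictly decreasing life expectancy across strata, female
longevity advantage in every stratum, strictly increasing MI burden, fewer
lifetime strokes in the very-high-risk stratum than the moderate stratum
alongside a monotone mortality-adjusted stroke risk in LDL-C — hold at the
default seed and n = 10,000 per stratum.

## Numerical choices

- Exposure bookkeeping in mg/dL-years; 38.67 mg/dL per mmol/L exposed as a
  constant (`ascvdsim.units`).
- Competing candidate times are exact exponential draws; ties (measure
  zero) resolve to the first event type in the fixed order MI, IHD, IS, HF,
  other death.
- The threshold departure of the MI hazard is identifiable by grid scan: the
  hazard equals its plateau exactly at and below E* and exceeds it strictly
  above, so the last on-plateau grid point recovers E* to one grid step.
- QALY integration is closed-form per segment (linear utility × exponential
  discount), with segment breaks at event ages, the diabetes onset age, the
  utility floor kink, and death.
- Degenerate inputs: empty cohorts are rejected in aggregation; dt = 0 is
  the identity for exposure accrual; negative dt, non-positive lipids,
  unordered cut points, and out-of-range probabilities raise errors listed
  in the validation report.

## Test problem sizes

Stochastic checks run at n = 10,000 persons (per stratum for the pattern
checks), where three Monte-Carlo standard errors resolve the targeted
contrasts comfortably; structural checks use small constructed histories
and four strata of 400.  These sizes are the package's chosen reference
conditions for its own verification; the full pipeline scales to larger
cohorts linearly in persons.
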