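# Methods

This note documents the models implemented in `pneumocea`, the defaults and
why they were chosen, what the synthetic cohorts do and do not emulate, and
the numerical decisions that matter for reproducing results.

## The clinical question and analysis chain

First-episode primary spontaneous pneumothorax (PSP) with CT-confirmed
blebs can be managed with chest tube drainage (cheap, high 5-year recurrence
risk) or video-assisted thoracoscopic surgery (VATS: bullectomy with
pleurodesis — expensive up front, low recurrence risk). In observational
data the two arms differ systematically (younger, smaller-bleb patients are
operated more often), so the analysis chain is: propensity-score matching to
remove measured confounding, recurrence effect measures and time-to-event
analysis on the matched cohort, then a utility-based cost-effectiveness
model with probabilistic sensitivity analysis.

## Synthetic cohort generator

Patient-level data from real cohorts of this kind are not publicly
deposited, so every stage is exercised on a calibrated generator
(`cohort.py`). It emulates:

- **Covariates.** Seven baseline covariates (sex, age ≥45, smoking,
  laterality, degree of lung collapse, maximum bleb diameter in three
  categories, bleb count in three categories), drawn independently within
  arm from arm-specific marginals taken from a published matched PSP cohort
  (e.g. 85.6 % of the VATS arm under 45 versus 36.8 % of the chest-tube
  arm). Independence across covariates is a deliberate simplification: only
  marginals are published, no joint distribution.
- **Confounding.** Treatment–covariate association is controlled by a
  single multiplier `m`: category probabilities follow the log-linear blend
  p(m) ∝ p_pooled^(1−m)·p_arm^m, so `m = 0` removes all association
  (randomised-like assignment), `m = 1` reproduces the calibrated arms
  exactly, and `m > 1` exaggerates imbalance. This makes "amount of
  confounding" a monotone, testable dial while keeping the calibrated arm
  marginals exact at the default.
- **Recurrence.** Exponential proportional-hazards times with
  administrative censoring at the 60-month follow-up horizon. The
  chest-tube monthly hazard solves 1 − e^(−60h) = 0.456 (the observed
  5-year recurrence fraction); the treatment effect is a hazard ratio of
  0.166 on the VATS arm. A constant hazard is the minimal model consistent
  with a single published hazard ratio; no time-varying hazards, repeat or
  contralateral recurrences are modelled.
- **Costs and length of stay.** Log-normal per arm, parameterized by the
  published medians (¥6,256 chest tube, ¥26,922 VATS) with the log-scale
  sigma recovered from the interquartile ratio (σ = ln(Q3/Q1)/1.349).
  Recurrence in the chest-tube arm adds one further drainage-episode cost
  draw; prolonged air leak leading to rescue VATS (probability 0.105 × 0.6)
  adds a VATS-cost draw and is costed to the chest-tube strategy while the
  patient stays in the chest-tube arm for all effectiveness analyses
  (intention-to-treat).
- **Age** is generated as a real (uniform within the under-45 and 45–75
  strata) and dichotomized at 45; the propensity model uses the indicator,
  mirroring how the balance table stratifies age.

What passing tests on these cohorts show: the pipeline recovers generating
parameters (hazard ratio, marginals), matching removes the engineered
confounding, and all identities/oracles hold. What they do not show:
robustness to covariate correlation, non-proportional hazards, informative
censoring, or cost–outcome dependence beyond the recurrence increment —
none of which the generator produces.

## Propensity matching

The propensity model is a logistic regression of treatment (VATS = 1) on
the seven covariates, dummy-coded (reference levels: female→`sex=male`
indicator, <45, non-smoker, right side, 30–50 % collapse, bleb diameter
<1 cm, bleb count 1–2), fitted by Newton–Raphson (statsmodels; tolerance
1e-8, max 100 iterations). Constant design columns are dropped (recorded in
the fit) so reduced cohorts stay full rank; fitted probabilities within
1e-10 of 0/1 raise a separation error rather than returning a fragile fit.

Matching is greedy 1:1 nearest-neighbor on the logit without replacement.
The caliper defaults to **0.02 standard deviations of the logit**
(`sd_scaled`); an absolute-logit caliper is available because the
literature uses both conventions. Ties between equidistant controls break
to the lower control id.

**Order of processing.** Greedy matching needs an order over treated units.
Processing in propensity order (descending or ascending) makes each forced
cross-pattern mismatch drift in one direction along the logit axis, which
accumulates into systematic covariate imbalance; at the default study
conditions it left the mean post-match SMD above 0.1 in ~30 % of
replicates. The default is therefore a **seeded random permutation**
(deterministic given the seed), which lets mismatch directions cancel;
descending and data order remain selectable.

Balance is reported as one-vs-rest binary SMDs per covariate level (11
levels: five binary indicators plus all three levels of the two
three-category covariates; continuous age excluded, the ≥45 indicator
included), with the mean SMD the unweighted mean over those levels — the
averaging set is recorded in the report since published tables rarely state
theirs. Post-match SMDs on an empty match are reported as NaN, not zero.

## Outcome statistics

Standard definitions throughout: ARR = p_control − p_treated, NNT = 1/ARR
(undefined marker when ARR ≤ 0, never an exception), RR = p_T/p_C. The
matched-pair test is exact McNemar (doubled binomial tail, capped at 1),
with the 1-df chi-square version (optional continuity correction)
available. Kaplan–Meier and the two-group log-rank test are delegated to
lifelines (log–log survival CI; median "not reached" marked by an infinite
value). The Cox model is a purpose-written single-covariate damped-Newton
fit of the log partial likelihood — convergence |Δβ| < 1e-9, Breslow ties
by default, Efron selectable, SE from observed information — because the
tie-handling contract (Breslow default) is not available in the installed
survival libraries; lifelines' Efron fit serves as an independent
cross-check in the tests, and a brute-force partial-likelihood maximization
is the oracle on small instances. Monotone likelihoods (|β̂| → ∞) raise a
convergence error with a diagnostic.

Sample size uses the two-independent-proportions normal approximation in
both the pooled and unpooled variants (they differ by 2–4 subjects at the
study's proportions; published reports rarely say which was used), with a
ceil-based inflation helper for attrition. Raw values are kept at full
precision everywhere; presentation rounding (1 dp for percentages, 2 dp for
NNT) happens only in report rendering.

## Cost-effectiveness model

Each patient follows a piecewise-constant utility path over the 60-month
horizon: an initial pneumothorax episode at utility 0.7 for 14 days, then
stable at 1.0; a recurrence restarts utility 0.7 for 14 days (truncated at
the horizon, flagged) followed by 0.95 (post-recovery) to the horizon.
Patients who never recur return to 1.0, not 0.95 — the minimal consistent
reading of a three-state utility set; both the mapping and all values are
configurable. QALYs are the integral of the path against e^(−ρt) with
ρ = ln(1 + annual rate), which gives closed forms for every segment (the
tests check them against trapezoid quadrature to 1e-8); an annual-cycle
accrual mode is available. Costs are not discounted by default: in this
setting almost all cost is incurred at time zero.

ICERs are reported per QALY (cohort ΔCost / cohort ΔQALY) and per
recurrence avoided (per-patient ΔCost / ARR). The per-recurrence ICER uses
full-precision ARR by default; a `rounded_arr` presentation option
reproduces printed-table arithmetic in which the ARR is rounded to three
decimals before dividing. Dominance (ΔCost < 0, ΔQALY > 0) is flagged
instead of reporting a negative ratio. Willingness-to-pay thresholds
default to 1× and 3× GDP per capita, ¥95,749 and ¥287,247 per QALY.

## Probabilistic sensitivity analysis

Parameter uncertainty: utilities as beta distributions (method of moments
from mean and SE, default SE = 10 % of the mean), per-arm recurrence
probabilities as beta(events + 1, non-events + 1), incremental cost as
gamma (default SE = 20 % of the mean); log-normal and fixed (degenerate)
kinds are also supported, and infeasible beta moments (s² ≥ m(1−m)) are a
configuration error naming the parameter. Each parameter draws from its own
named substream (seed combined with a CRC of the parameter name), so adding
a parameter never perturbs another's draws and every run is bit-reproducible
from the seed.

Each iteration recomputes cohort ΔQALY through the accrual model as
n_pairs · (p_C − p_T) · (QALY_no-recurrence − QALY_recurrence) with the
drawn utilities and probabilities (recurrence placed at a representative
15 months, the matched cohort's median time to recurrence), and ΔCost from
the drawn per-patient increment. Decisions use net monetary benefit,
NMB(λ) = λ·ΔQALY − ΔCost > 0, with ties counted as not cost-effective; the
CE plane classifies draws by strict positivity of ΔQALY (east) and ΔCost
(north). Non-finite iterations would be excluded from the CEAC and counted,
never silently dropped. The one-way scenario grid varies pneumothorax
utility (0.5/0.8), recurrence duration (7/21 days), total cost (±20 %) and
discount rate (0/3/6 %), holding each varied parameter fixed in the
accompanying PSA re-run.

## Pipeline and reproducibility

One run seed fans out to per-stage seeds (stage-name keyed CRC + seed into
a `SeedSequence`), so stages are individually reproducible and re-running
with the same configuration yields byte-identical CSVs (fixed column order,
`%.10g` floats, UTF-8). Input CSVs are schema-checked strictly — unknown
columns are rejected unless explicitly allowed — because silent column
misuse is the dominant failure mode for tabular clinical data. Default
problem sizes (500 per arm for pipeline runs, 2,000 per arm over 100
replicates for hazard-ratio recovery checks, 10,000 PSA iterations) were
chosen so each quantity's Monte Carlo error is small relative to the
decision margins it feeds.

## Known limitations

- Covariates are sampled independently within arm; real bleb size/count/age
  are correlated.
- The recurrence law is memoryless; published KM curves suggest declining
  hazard after the first year.
- The QALY model has three utility states and fixed episode durations; no
  EQ-5D mapping, no societal costs, no extrapolation beyond 60 months.
- The per-patient cost model attributes crossover surgery wholly to the
  chest-tube strategy at the time of the initial episode (no discounting of
  the delayed cost stream by default).
- Matching supports greedy 1:1 without replacement only — no optimal/full
  matching, no IPTW.
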