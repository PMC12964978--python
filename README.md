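# pneumocea

Comparative-effectiveness and cost-effectiveness analysis of **video-assisted
thoracoscopic surgery (VATS)** versus **chest tube drainage** for
first-episode primary spontaneous pneumothorax (PSP) with CT-confirmed
blebs, built as a reusable, fully tested pipeline:

1. **Synthetic cohort generation** — patient-level two-arm cohorts with
   confounded treatment assignment over seven baseline covariates, an
   exponential proportional-hazards recurrence law censored at 60 months,
   and right-skewed (log-normal) cost distributions, calibrated to a
   published matched PSP cohort.
2. **Propensity score matching** — logistic propensity model, greedy 1:1
   nearest-neighbor matching on the logit with a caliper (default 0.02 SD of
   the logit), and standardized-mean-difference (SMD) balance diagnostics.
3. **Recurrence outcomes** — rates, absolute risk reduction
   (ARR = p_C − p_T), number needed to treat (NNT = 1/ARR), relative risk,
   exact McNemar matched-pair test, Kaplan–Meier curves, two-group log-rank
   test, single-covariate Cox model (Breslow/Efron ties), rank tests, and
   the two-proportion sample-size formula.
4. **Cost-effectiveness** — a three-state utility model (stable 1.0,
   pneumothorax episode 0.7, post-recovery 0.95) integrated with
   continuous-time discounting into QALYs, and incremental
   cost-effectiveness ratios ICER = ΔCost/ΔEffect per QALY gained and per
   recurrence avoided, judged against willingness-to-pay thresholds of 1×
   and 3× GDP per capita (¥95,749 and ¥287,247 per QALY).
5. **Sensitivity analysis** — Monte Carlo probabilistic sensitivity analysis
   (beta utilities/probabilities, gamma costs), cost-effectiveness plane,
   acceptability curve (CEAC) under the net-monetary-benefit rule
   NMB(λ) = λ·ΔQALY − ΔCost, and a deterministic one-way scenario grid.

The package is aimed at health-economics and clinical-epidemiology users who
want the whole chain — matching, survival analysis, decision model, PSA —
reproducible from one seed, with every stage testable on synthetic data.

## Worked example

```python
from pneumocea import pipeline
manifest = pipeline.run_pipeline(pipeline.RunConfig(seed=7, n_per_arm=500), "out/")
```

writes the full artifact bundle (cohort, pair list, balance report, effect
summary, KM curve data, CEA table, scenario table, CE-plane and CEAC CSVs,
and a manifest). With seed 7 the run matches 144 pairs and reports, among
others:

```
mean SMD (pre -> post):   0.636 -> 0.020
recurrence VATS:          9.7 %        chest tube: 48.6 %
ARR 38.9 %, NNT 2.57      Cox HR 0.157 (95% CI 0.088-0.278)
log-rank chi2 52.6        McNemar exact p = 5.8e-12
ICER: 226,300 CNY/QALY    31,984 CNY per recurrence avoided
cost-effective at 3x GDP per capita: True
```

Matching collapses the engineered confounding (mean SMD falls from 0.64 to
0.02, well under the conventional 0.1 threshold), the Cox hazard ratio
recovers the generating value 0.166 within sampling error, and the ICER
falls between the 1× and 3× GDP-per-capita thresholds, so surgery is
cost-effective at the upper WHO-style threshold but not the lower one.

The same run is available from the shell:

```bash
pneumocea all --seed 7 --out out/
pneumocea simulate --seed 7 --n-per-arm 500 --out out/   # cohort only
pneumocea match --cohort-csv out/cohort.csv --out out/   # matching only
```

## Layout

```
src/pneumocea/
  cohort.py     synthetic cohort generator + baseline summaries + CSV I/O
  matching.py   propensity model, greedy caliper matching, SMD balance
  outcomes.py   effect measures, McNemar, KM, log-rank, Cox, sample size
  cea.py        QALY accrual, discounting, ICER computation
  psa.py        Monte Carlo PSA, CEAC, one-way scenarios
  pipeline.py   stage orchestration and artifact bundle
  cli.py        click command-line interface
  plots.py      optional matplotlib helpers over the figure-data CSVs
docs/methods.md model assumptions, parameter defaults, design choices
```
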