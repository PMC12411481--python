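# Methods

This note documents the modelling conventions, numerical choices and
calibration decisions behind the package, and what its tests do and do not
demonstrate.

## Cohort model

Three states (PFS, PD, death), 3-week cycles (21 days), 10-year horizon.
The cycle count is `ceil(10 × 365.25 / 21) = 174`; curve evaluation
converts cycles to months as `21 / 30.4375` (so a cycle is ≈0.690
months). The cohort starts fully progression-free.

**Transition construction.** Each cycle's probabilities are rebuilt from
the two parametric curves as described in the README. Details that the
formulas leave open:

* `S(t-1) = 0` is treated as an absorbed compartment (ratio 0), not a
  division error.
* All computed probabilities are clamped to [0, 1]; clamp events are
  counted on the trace and logged. With the bundled curves no clamping
  occurs at any of the 174 cycles.
* **Empty PD compartment.** When `nPD` is numerically zero (notably at
  cycle 1), `pPTP` is pinned to 0 — its flow is zero anyway — and the
  whole overall-survival decrement is routed through the PFS→death
  channel (`pFTD_eff = max(pFTD, 1 - pSTS)`). Without this, the deaths
  implied by the OS curve in the first cycle would be silently dropped
  and the alive fraction would overshoot `S_os` by the constant factor
  `1/S_os(1)` forever. With it, the partitioned-survival equivalence
  (`nPFS ≡ S_pfs`, alive ≡ `S_os`) holds to 1e-9 at every cycle, for any
  background mortality.
* **Background mortality** defaults to a constant 0.002/year
  (approximately mid-life female general-population mortality; no life
  table is bundled, and the choice is second-order: the `pPTP`
  construction forces total-alive to track `S_os` regardless, so `pFTD`
  only reallocates deaths between the PFS and PD source states).

**Accrual and discounting.** Cycles are indexed k = 0…173; during cycle k
the cohort occupies the state reached after k transitions, and all
per-cycle quantities are discounted by `(1.05)^(-k·21/365.25)` (first
cycle undiscounted). Terminal care attaches to deaths at the cycle they
occur. No half-cycle correction by default; a config flag
(`settings.half_cycle_correction`) switches to the life-table convention.
Adverse-event costs and QALY decrements are incidence-weighted one-off
amounts applied at cycle 1.

## Survival curves and fitting

Parameterizations are listed in `survival.py`; the log-logistic form
`S(t) = 1/(1+(t/scale)^shape)` is chosen so that the median equals the
scale parameter, which is the only mapping consistent with the trial
medians for the bundled fits. "Gamma" is the standard two-parameter
gamma. The Gompertz shape may be negative, giving a survival plateau at
`exp(rate/shape)` — documented rather than forbidden.

Right-censored MLE maximizes `Σ_events log f(t) + Σ_censored log S(t)`.
Positive parameters are optimized on the log scale (log-normal meanlog
and Gompertz shape stay unconstrained). Three moment-derived starting
points per family are each refined with L-BFGS-B; the best optimum is
polished with Nelder-Mead at tolerance 1e-8 on the log-likelihood. The
exponential rate uses its closed form (events / total observed time).
Convergence is reported honestly on the result, never raised away.
Model selection minimizes AIC, breaking ties by BIC and then by the fixed
family order (exponential, weibull, gamma, lognormal, loglogistic,
gompertz). lifelines' univariate fitters serve as an independent
cross-check in the tests, not as the implementation.

**Pseudo-IPD reconstruction.** Digitized KM coordinates are converted to
individual records by assigning integer event counts that reproduce each
step drop; all remaining subjects are administratively censored at the
final curve time. The product-limit estimate of the output therefore
matches the input curve within 1/(2n) at its step points by construction.
Interior censoring is *unidentifiable* without number-at-risk data: when
per-time at-risk counts are supplied, the implied censored subjects are
spread uniformly within each interval; when they are not (the default),
refitting reconstructed data from a trial with heavy in-follow-up
censoring will be biased toward later event times. Coarse digitization
grids likewise round event times upward; the round-trip recovery test
uses a 0.25-month grid and administrative censoring only, which bounds
what it demonstrates about sparsely digitized curves.

## Costing

Reference patient: BSA 1.72 m², weight 65 kg. Pricing is linear in mg
(per-100 mg unit prices, no vial rounding; a whole-vial mode is out of
scope). Regimens:

* **Pembrolizumab** 200 mg flat every 3 weeks, PFS-gated, capped at 35
  treated cycles (~2 years).
* **Chemotherapy backbone** (both arms), PFS-gated, capped at 6 treated
  cycles, as a cohort-share mixture: gemcitabine 1,000 mg/m² d1+d8 with
  carboplatin (weight 0.55; carboplatin as a fixed 625 mg-equivalent —
  AUC 5 × (GFR 100 + 25) — since renal function is not an input),
  nab-paclitaxel 100 mg/m² d1/d8/d15 (0.31), paclitaxel 90 mg/m²
  d1/d8/d15 (0.14). Shares and caps are config fields.
* **Supportive treatment** $359/cycle during active chemotherapy;
  **routine follow-up** $170/cycle in PD; **terminal care** $2,325.75
  one-off at death; adverse-event management costs per event
  (anemia/neutropenia/neutrophil-count-decreased), incidence-weighted.

**Calibration.** The published analysis prints a base-case incremental
cost and an 80%-price-cut scenario cost, which jointly imply (through the
exact identity `ΔCost(d) = ΔCost(0) - d × discounted pembrolizumab
cost`) a discounted pembrolizumab acquisition cost of ≈$86.7k. The
35-cycle pembrolizumab cap and the treatment-gated cost mapping above
were chosen once so the model reproduces that anchor and the printed
incremental cost within a few percent; they are exposed as config
switches, not hard-coded. Uncapped chemotherapy, or supportive/follow-up
accruing across all alive states, inflates the non-pembrolizumab
incremental cost several-fold beyond anything consistent with the
printed scenario table.

**Adverse-event disutilities** are normalized to absolute one-off
decrements. The source table prints one disutility with a positive sign
and one with its base outside its own range; both are treated as
data-entry artifacts. The out-of-range row (neutropenia) samples from
±25% bounds around its absolute base — the table's own fallback rule for
missing ranges — since its printed interval is unusable.

## Sensitivity analyses

From (base, lower, upper), sampling distributions are moment-matched
treating the range as a 95% interval: sd = (upper−lower)/3.92. Costs are
Gamma (mean = base); utilities, disutilities, incidences, the discount
rate (0–0.08) and BSA are Beta on the interval-rescaled variable (BSA
exceeds 1, so it is rescaled to [1.29, 2.15]). Draws are independent;
survival-curve parameters are not sampled (no uncertainty for them is
published; the machinery supports curve paths but the default spec list
excludes them). Specs whose base sits outside its bounds are flagged and
held fixed rather than silently repaired. One-way DSA reruns the full
model at each bound with everything else at base and sorts bars by ICER
swing; the CEAC reports `P(λ·ΔQALY − ΔCost > 0)` on a $0–800k grid. PSA
is bit-reproducible under a fixed seed. Because no sampled parameter
touches the survival curves, cohort traces are computed once per arm and
reused across iterations and DSA bounds (a ~200× speedup; the cache is
bypassed automatically if a spec path targets a curve).

## Synthetic data

The generator draws event times from any supported family, applies
exponential random censoring and an administrative cutoff, and can export
digitized-style KM curves on a grid. It emulates the *shape* of trial
time-to-event data — including the four bundled ground-truth curves — but
not covariate structure, treatment switching, or informative censoring;
passing recovery tests therefore show the fitting/selection machinery is
correct, not that any real trial's published curves were recovered.
Problem sizes used in the tests: n = 2,000 subjects, 50 seeded replicates
per ground-truth family for the end-to-end recovery property, n = 5,000
for single-fit 3-standard-error coverage, and 1,000 PSA replications.

A statistical note on model selection: a "true family wins AIC" property
is only meaningful for non-nested truths. When the truth is exponential,
every two-parameter family that nests it gains ~χ²₁/2 log-likelihood by
chance and AIC picks an extended family in a substantial fraction of
replicates no matter the implementation; the recovery property is
therefore asserted for the two (non-degenerate) bundled families.

## Known limitations and departures

* With the bundled curve parameters, utilities, discounting and horizon,
  the discounted incremental QALY is ≈0.51. This is convention-invariant
  (the continuous-time integral of the discounted weighted survival
  differences gives the same value), yet the published analysis reports
  0.47 — its own tables back-derive to an unrounded 0.4664. The printed
  curve parameters and the printed QALY difference are not mutually
  consistent; this package follows the printed curves. Downstream, the
  model's probability of cost-effectiveness at $200,000/QALY (~0.78) is
  correspondingly higher than the published 55.4%, because the base-case
  net monetary benefit at that threshold scales with the QALY difference.
* In the one-way DSA, the PD-utility bar is small here (the discounted
  incremental PD time is only ≈0.04 years with these curves), ranking
  below the discount-rate bar rather than in the top three as published.
* The CPS≥1 and intention-to-treat subgroups are schema-supported but not
  bundled: their curve parameters are not published.
* Only direct medical costs, grade ≥3 adverse events, and a single
  reference patient are modelled; no treatment-switching adjustment, no
  correlated PSA sampling, no EVPI.
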