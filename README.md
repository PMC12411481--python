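# tnbc-cea

A Markov cohort cost-effectiveness model of first-line **pembrolizumab plus
chemotherapy versus placebo plus chemotherapy** for previously untreated,
locally recurrent inoperable or metastatic **triple-negative breast cancer
(TNBC)**, from the perspective of the Chinese healthcare system. The package
re-implements, as tested and reusable code, a published economic evaluation
built on KEYNOTE-355 survival data for the PD-L1 CPS≥10 subgroup.

It is aimed at health-economics and HTA analysts who want to reproduce,
stress-test, or extend this class of oncology state-transition models:
every stage — curve fitting, trace construction, costing, and uncertainty
analysis — is an importable, separately testable function.

## The model

Three mutually exclusive health states: progression-free survival (PFS),
progressed disease (PD), and death. A cohort starts fully in PFS and moves
between states in 3-week cycles over a 10-year horizon (174 cycles).
Time-dependent transition probabilities are rebuilt each cycle from two
extrapolated parametric survival curves per arm:

```
pFTF(t) = S_pfs(t) / S_pfs(t-1)                      stay progression-free
pFTP(t) = 1 - pFTD - pFTF(t)                          progress
pSTS(t) = S_os(t) / S_os(t-1)                         overall-survival ratio
pPTP(t) = [(nPFS + nPD)·pSTS - nPFS·pFTF - nPFS·pFTP] / nPD
pPTD(t) = 1 - pPTP(t)
```

with `pFTD` the general-population per-cycle mortality. This construction
forces the alive fraction to track `S_os` and the PFS compartment to track
`S_pfs` (a partitioned-survival equivalence the test suite asserts to
1e-9). Discounted costs and QALYs accumulate per cycle at a 5% annual rate
(utilities 0.76 / 0.55 / 0); incremental results are summarized as an ICER
in 2024 US$ per QALY against a willingness-to-pay threshold of
$38,224/QALY (3× China's per-capita GDP).

Around the engine sit:

* **`survival`** — six parametric families (exponential, Weibull, gamma,
  log-normal, log-logistic, Gompertz), right-censored MLE with AIC/BIC
  model selection, Kaplan–Meier estimation, and pseudo-IPD reconstruction
  from digitized KM coordinates.
* **`economics`** — BSA/weight-based drug dosing, state-gated recurring
  costs, adverse-event one-offs, discounting, ICER with dominance flags,
  and price-discount scenarios.
* **`uncertainty`** — one-way DSA (tornado), probabilistic sensitivity
  analysis with Gamma/Beta sampling, CEAC, and scenario batches.
* **`synthetic`** — trial-like simulated time-to-event data with known
  ground truth, so the whole pipeline is testable offline.

## Worked example

The bundled CPS≥10 base case runs in seconds:

```bash
$ tnbc-cea run --out results.csv
dCost=87,525.80 dQALY=0.5113 ICER=171,179.50
```

Pembrolizumab plus chemotherapy accrues an extra **$87,525.80** and
**0.51 QALYs** per patient over ten years, an ICER of **$171,180/QALY** —
about 4.5 times the $38,224/QALY willingness-to-pay threshold, so the
combination is not cost-effective at its list price. Price-cut scenarios
show what negotiation would need to achieve:

```bash
$ tnbc-cea scenario --fractions 0,0.8,0.9,0.95 --out scenario.csv
discount_fraction,delta_cost,delta_qaly,icer
0.0,87525.80,0.5113,171179.50
0.8,17575.02,0.5113,34372.53
0.9,8831.17,0.5113,17271.66
0.95,4459.25,0.5113,8721.23
```

An 80% pembrolizumab price reduction brings the ICER to ~$34,400/QALY,
just under the threshold. The same model can be driven from Python:

```python
from tnbc_cea import default_cps10_config, run_analysis

res = run_analysis(default_cps10_config())
print(res.incremental.icer)       # 171179.50...
print(res.summary())              # per-arm costs, life-years, QALYs
```

Other subcommands: `tnbc-cea fit` (parametric fitting of IPD or digitized
KM input), `owsa` (tornado), `psa` (Monte-Carlo PSA + CEAC), `simulate`
(synthetic trial data). Custom analyses use a YAML config
(`src/tnbc_cea/data/cps10.yaml` is the bundled, schema-validated example).

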