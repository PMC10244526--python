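# cardiopv

Disproportionality analysis of cardiovascular adverse events in FAERS-style
spontaneous-report data.

Spontaneous safety databases (FDA's FAERS and its kin) hold millions of
adverse-event reports but no denominators, so drug safety signals are screened
by *disproportionality*: is an event reported with a target exposure more
often than its share of all other reporting predicts?  `cardiopv` implements a
complete, tested pipeline for the cardio-oncology setting — immune checkpoint
inhibitors (ICIs), angiogenesis inhibitors (AGIs) and their combination — for
pharmacoepidemiologists and methodologists who want the whole chain from raw
`$`-delimited quarterly tables to forest-plot-ready signal tables, plus a
synthetic report generator with exact ground truth for validating every stage.

## What it computes

Reports are cleaned in three stages (keep the latest version of each case;
keep suspect-role drug mentions only; classify exposure by matching suspect
names against a drug-name archive of generics, brands and research codes).
Cardiovascular events are preferred terms (PTs) belonging to any of nine
narrow Standardized MedDRA Queries (SMQs).  For each exposure group and event,
a 2×2 report-count table

|              | target AE        | other AEs | total            |
|--------------|------------------|-----------|------------------|
| target drug  | a (N_observed)   | b         | N_drug = a+b     |
| other drugs  | c                | d         | c+d              |
| total        | N_event = a+c    | b+d       | N_total          |

with N_expected = N_drug·N_event/N_total yields two shrinkage-transformed
statistics sharing one core,

```
ROR = (N_observed + 0.5) / (N_expected + 0.5)        IC = log2(ROR)  [bits]
```

with a Wald 95% interval for the ROR, the power-series credibility bounds

```
IC025 = IC − 3.3·(a+0.5)^(−1/2) − 2.0·(a+0.5)^(−3/2)
IC975 = IC + 2.4·(a+0.5)^(−1/2) − 0.5·(a+0.5)^(−3/2)
```

and the signal rule: **ROR₀₂₅ > 1 or IC₀₂₅ > 0 with at least 3 reports**
(both criteria reported separately).  Outcome severity (death,
life-threatening, hospitalization, …) is profiled per group, overall and
within each SMQ, one category per case by severity precedence.
See `docs/methods.md` for assumptions, conventions and limitations.

## Worked example

Generate a synthetic batch (5,350 cases across the four exposure groups, with
duplicate versions, messy drug names and planted reporting-rate multipliers),
then run the full analysis:

```sh
cardiopv generate demo --seed 7 --n-ici 400 --n-agi 800 \
    --n-combination 150 --n-background 4000
# wrote 7476 report versions for 5350 cases to demo
cardiopv all demo results
# 7476 reports in -> 5350 after dedup -> 5350 with suspect drugs; artifacts in results
```

`results/overall_disprop.tsv` then holds the overall cardiovascular analysis
(each group against the unexposed background):

```
      group    a  n_expected   ror  ror_025  ror_975    ic  ic_025  ic_975  signal_by_ic
  ici_alone  274     179.060 1.529    1.315    1.778 0.612   0.413   0.757          True
  agi_alone  523     370.595 1.411    1.258    1.583 0.496   0.352   0.601          True
combination  115      67.886 1.689    1.347    2.118 0.756   0.447   0.979          True
```

Reading the combination row: its 115 cardiovascular reports are 1.69× the
expected count under proportional reporting (IC = 0.756 bits); the lower
credibility bound IC₀₂₅ = 0.447 > 0 with a ≥ 3, so the overall cardiovascular
signal is flagged — as planted, since the generator's default multipliers
elevate hypertension, embolic and myocarditis-type events in the exposed
groups.  The other artifacts are `smq_disprop.tsv` (per-SMQ signals),
`pt_signals.tsv` (per-PT signals under both criteria), `cohort_summary.tsv`
(baseline tabulation), `outcome_profiles.tsv` (severity per group and SMQ
stratum), `indication_restricted.tsv` (cancer-indication stratum) and
`manifest.json` (config hash plus stage-by-stage record counts, which always
reconcile: in = kept + dropped).

The same steps are available as a library (`cardiopv.synthetic`,
`cardiopv.cohort`, `cardiopv.disprop`, `cardiopv.outcomes`,
`cardiopv.pipeline`), operating on pandas-backed report bundles.

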