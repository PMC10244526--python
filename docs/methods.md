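# Methods

## The problem

Spontaneous adverse-event databases such as FAERS collect safety reports for
marketed drugs without denominators: there is no count of treated patients,
only of reports.  *Disproportionality analysis* (case–noncase analysis) asks
whether an adverse event is reported with a target exposure more often than
its share of all other reporting would predict.  `cardiopv` implements this
for cardiovascular adverse events under three exposure groups defined by
suspect drug classes — immune checkpoint inhibitors (ICIs) alone,
angiogenesis inhibitors (AGIs) alone, and their combination — against the
background of reports with neither class.

## Data model and cleaning

A *case* is one patient's adverse-event history; a case may be submitted
several times (duplicates, follow-ups), each submission being one report
*version*.  Cleaning is three fixed stages, in order:

1. **Deduplication.**  One version per case survives: the maximal version
   under a configurable key, by default (FDA receipt date, report id).  The
   stage is idempotent, and the choice of key is exposed because source data
   conventions differ on what "most recent" means.
2. **Suspect-role filtering.**  Only drug mentions with the *suspect* role
   classify exposure; *concomitant* and *interacting* mentions are removed.
   Reports left with no suspect drug are dropped.
3. **Exposure classification.**  Suspect names are normalized (Unicode
   case-fold, trim, collapse internal whitespace) and matched against a
   drug-name archive of generic names, brand names and research codes.
   The matched class set maps to a group: {ICI} → ICI alone, {AGI} → AGI
   alone, {ICI, AGI} → combination, {} → neither.  No fuzzy spelling
   correction is applied; known misspellings are handled as explicit archive
   aliases, because silent fuzzy matching is not auditable.

Cardiovascular events are defined by membership of a preferred term (PT) in
one of nine narrow Standardized MedDRA Queries (cardiac arrhythmias, cardiac
failure, cardiomyopathy, embolic and thrombotic events, hypertension,
ischaemic heart disease, noninfectious myocarditis/pericarditis, pulmonary
hypertension, torsade de pointes/QT prolongation).  PT→SMQ membership is
licensed MedDRA content, so the map is a user-supplied table; a PT may
belong to several SMQs and then enters each SMQ's analysis independently.

## Counting

The unit entering the 2×2 tables is the *report*: one distinct (case, PT)
pair.  A case with two cardiovascular PTs contributes two reports, which is
why report counts exceed case counts.  At the SMQ level a configuration
switch (`counting_unit`) chooses between:

- `per_pt` (default): every distinct (case, PT) pair counts; and
- `per_smq_once`: a case counts once per SMQ however many member PTs it
  reported, preventing within-case PT multiplicity from inflating a single
  SMQ's signal.

The comparator for c/d is, by default, all reports whose exposure group is
*neither* (the unexposed background); `comparator = rest` instead uses all
reports outside the target group.

## Statistics

From the 2×2 table (a, b, c, d) with N_drug = a+b, N_event = a+c,
N_total = a+b+c+d and N_expected = N_drug·N_event/N_total, two
shrinkage-transformed statistics share one core:

    ROR = (a + 0.5) / (N_expected + 0.5)
    IC  = log2(ROR)            [bits]

The +0.5 shrinkage keeps both defined at a = 0 and pulls small-count
estimates toward the null (|log shrunk| ≤ |log raw| always).  Note this
"ROR" is a shrunk observed-to-expected ratio, not the cross-product odds
ratio (a·d)/(b·c); the classic odds ratio is available separately
(`classic_ror`) for comparison but is never the primary statistic.

Intervals:

- ROR: the Wald odds-ratio interval exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)),
  centred on the shrunk point estimate.  Any zero cell leaves the bounds
  undefined (NaN) — no additional continuity correction is invented beyond
  the shrinkage the point estimate already carries.
- IC: the power-series credibility approximation
  IC₀₂₅ = IC − 3.3·(a+0.5)^(−1/2) − 2.0·(a+0.5)^(−3/2),
  IC₉₇₅ = IC + 2.4·(a+0.5)^(−1/2) − 0.5·(a+0.5)^(−3/2).
  The 3.3 multiplier is wider than the 1.96σ normal half-width, making the
  IC criterion conservative at small counts (observed null false-positive
  rates well under the nominal 2.5%).

**Signal rule.**  A drug–event combination is a potential signal when
ROR₀₂₅ > 1 or IC₀₂₅ > 0 **and** a ≥ 3 reports.  Both criteria are reported
separately; inequalities are strict.  No multiple-testing adjustment is
applied — the rule is a per-combination screening threshold, not an
inferential family — and this is a known caveat of the method.

At a = 2 the IC criterion is unsatisfiable by construction: the interval
penalty 3.3/√2.5 + 2/2.5^1.5 ≈ 2.59 bits exceeds the shrinkage-capped
maximum IC of log2(2.5/0.5) ≈ 2.32 bits.  The report floor is therefore
binding only through the ROR criterion and the explicit a ≥ 3 test.

**Outcome severity.**  A report may carry several seriousness codes; for
tabulation each case receives exactly one category by severity precedence
(death > life-threatening > disability > congenital anomaly >
hospitalization > other serious > unknown), so category counts sum to the
case denominator.  The precedence is a tabulation convention, overridable
in `outcomes`; putting fatal outcomes first means "death %" is never
diluted by co-coded lesser outcomes.  Percentages are reported to one
decimal on the stratum's case denominator.

## Synthetic generator

`cardiopv.synthetic` draws FAERS-like batches with exact ground truth, so
every cleaning stage and statistic is testable without the real database.

- **Cases first, versions second.**  Cases are drawn per exposure group,
  then given 1 + Poisson(0.4) report versions (earlier versions carry a
  reaction-list prefix, emulating follow-ups), so deduplication truth is
  exact by construction.
- **Events.**  Per case, each PT `e` of a configurable universe receives an
  independent Poisson(λ·f_e·ρ_ge) mention count — λ the overall intensity
  (default 2.0 mentions per case), f_e the baseline frequency, ρ_ge the
  group's relative reporting rate (1 = null) — conditioned on at least one
  mention overall; the reaction list is the set of distinct PTs.  This is
  exactly "zero-truncated Poisson PT count + rate-tilted categorical draw",
  and it yields the closed form
  P(e present) = (1 − exp(−λ f_e ρ_ge)) / (1 − exp(−λ Σ f ρ)),
  from which `expected_table` returns *exact* expected 2×2 tables for any
  event, group, comparator and counting unit.  The tests check this closed
  form against an independent term-by-term series enumeration.
- **Drugs and noise.**  Group-defining drugs are suspect; filler drugs take
  mixed roles; with probability 0.05 a decoy ICI/AGI is attached with
  *concomitant* role (classification must ignore it).  Names are rendered
  through archive variants (brands, research codes, listed misspellings)
  plus normalization-recoverable case/whitespace noise.
- **Defaults.**  The default universe has 21 cardiovascular PTs covering
  all nine SMQs (~20% of mention mass) and 11 common non-CV terms; default
  group sizes are 2,000 / 4,000 / 600 / 20,000 (ICI / AGI / combination /
  background) — a desk-scale stream preserving the groups' relative sizes
  rather than the millions of reports of the real database.  Default
  outcome and indication mixes per group follow the published study
  population's percentages where available; default reporting-rate
  multipliers point the same way as the study's findings (myocarditis-type
  events elevated under ICIs, hypertension and embolic events under AGIs,
  with the combination shifting weight from myocarditis toward embolic
  events).

**What the generator does not emulate:** real FAERS marginal PT
frequencies, country/reporter joint structure, cross-manufacturer duplicate
records with *different* case ids, free-text indication noise, or temporal
reporting dynamics.  Passing tests therefore validate the *method and its
implementation* — counting semantics, formulas, calibration — not the
database-level case counts of any particular study, which depend on the
real extract.

## Calibration studies and chosen problem sizes

Two statistical properties are checked end to end:

- **Recovery.**  An injected rate ρ ∈ {2, 4} on one PT must be recovered by
  the shrunk ROR within 5% (mean over 30 fixed-seed replicates).  The
  observed/expected ratio is structurally attenuated below ρ by three
  design-controlled terms: the exposed group's share of the event margin
  (≈ (ρ−1)·s for report share s), within-case saturation of distinct-PT
  counting (≈ λfρ/2), and the +0.5 shrinkage (≈ 0.5(ρ−1)/a).  The study
  dimensions — 8,000 exposed vs 4,000,000 background cases, target baseline
  frequency 0.004, λ = 1.5, giving expected a ≈ 120–430 — were chosen from
  this arithmetic so that the combined attenuation stays within ~3%.
  Realized errors: 0.9% (ρ = 2) and 0.7% (ρ = 4).
- **Null calibration.**  Across 500 PTs at ρ = 1 (20,000 exposed vs
  100,000 background cases), the IC₀₂₅ > 0 criterion must flag ≤ 5%; the
  3.3-multiplier interval makes the realized rate far lower.

The replicate sizes keep the full suite around one to two minutes of
simulation; the large background is generated through a vectorized
event-layer path (`simulate_event_arrays`) that shares the generative law
with the full report simulator.

## Numerical and degenerate-input conventions

- All statistics are defined for any table with N_total > 0; an all-zero
  table raises an undefined-input error, as does an empty comparator.
- Zero cells: point estimates survive via shrinkage; Wald ROR bounds are
  NaN; signal flags are then false by the strict-inequality rule.
- Displayed statistics are rounded to 3 decimals (configurable); internal
  computation is double precision throughout.
- Dedup ties on receipt date are broken by the larger report id;
  zero-padded ids make lexicographic and numeric order agree.
- The indication-restricted analysis matches case-insensitive substrings
  from a configurable term list (default: the seven cancer indications of
  the study population), since indications are free text.

## Known limitations

- Key-based deduplication only: the same patient submitted under different
  case ids (different manufacturers) is not linked.
- The Wald interval around a shrunk point estimate mixes two estimators;
  this mirrors the published method and is kept exactly as specified, with
  the discrepancy documented rather than "fixed".
- No EBGM/MGPS or full Bayesian posterior; only the two statistics above.
- Signal counts are sensitive to the PT universe of the input data; with
  synthetic data they describe the generator's world, not any real drug.
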