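# hfdash

**Heart-failure EHR phenotyping and quality-measure dashboard engine.**

Population-health teams that manage heart failure (HF) across a large
health system need to know, for every patient, *which* HF they have —
because treatment differs by phenotype:

* **HFrEF** — reduced ejection fraction, LVEF ≤ 40%
* **HFmrEF** — mildly reduced, LVEF 41%–49%
* **HFpEF** — preserved, LVEF ≥ 50%

The left ventricular ejection fraction (LVEF) that drives this split is
scattered across the EHR in unstructured text (echocardiography
reports, clinical notes, radiology reports) and one structured
cath-lab registry field, with wildly varying reliability. `hfdash`
implements a rule-based computable phenotype that deals with that
heterogeneity, plus the quality measures (eCQMs) a dashboard reports
on top of it, and a synthetic-cohort simulator so the whole pipeline is
testable with gold labels and no patient data.

## The algorithm

1. **Inclusion.** A patient enters the cohort only with *documented*
   HF: an HF ICD code (ICD-10 `I50.*` or ICD-9 `428.*`) from any
   encounter, or an active HF problem-list entry.
2. **Extraction.** A deterministic pattern extractor pulls every EF
   value from report text — single values, ranges ("EF 50–55%" yields
   both endpoints), decimal fractions ("EF 0.40" → 40) — and flags
   non-cardiac decoys such as gallbladder ejection fractions.
3. **Quality hierarchy.** Every measurement is tiered by source:
   single-value echo text and cath-lab entries sourced from TTE / TEE /
   MRI / CT are *high*; multi-value echo text, clinical notes and
   ventriculography are *medium*; radiology text and nuclear-sourced
   registry values are *excluded* outright.
4. **Selection.** Within a 3-year lookback: a high-tier measurement
   from the past year wins; otherwise the most recent non-excluded
   measurement (high tier preferred on date ties). Same-day
   single-value studies that individually imply both HFrEF and HFpEF →
   verdict *unspecified* (conflict). Pooled multi-value sets: any
   value > 75% → *unspecified* (implausible); spread ≤ 10 points →
   average of the extremes; spread > 10 → the high value alone.
5. **Classification.** The effective LVEF maps to HFrEF / HFmrEF /
   HFpEF; missing, conflicting or implausible evidence maps to
   *unspecified*.

The legacy baseline (`--version v1`) — lowest LVEF from *any* source in
3 years, two-class split, ICD-only fallback — is included because its
failure mode (low-biased nuclear and radiology outliers dragging
preserved-EF patients into HFrEF) is exactly what the hierarchy fixes,
and the package's evaluation module quantifies that improvement.

On top of the phenotypes, the KPI engine scores guideline-directed
medical therapy (GDMT) use and target dosing, harmful-medication
exposure (e.g. diltiazem flags an HFrEF patient but not an HFpEF
patient), and high-risk status (≥ 2 HF admissions plus cardiology care
in the past year), rolled up provider → facility → network → national
with green/yellow/red coloring and a static HTML dashboard render.

## Worked example

```sh
hfdash simulate --preset paper_like --seed 7 --n-patients 200 --out demo
hfdash classify --in demo --as-of 2023-06-30 --out demo/phenotypes.csv
hfdash evaluate --in demo --as-of 2023-06-30 --out demo/evaluation.csv
```

The simulator writes a gold-labeled noisy cohort; `classify` reports
`classified 200 patients (178 included)` — the 22 others lack HF
documentation. `evaluate` runs both algorithm generations against the
gold labels and prints one-vs-rest metrics per class:

```
version  class  TP  FP  TN  FN  sensitivity  specificity   accuracy        ppv        npv
     v1  HFrEF  75  22  81   0   100.000000    78.640777  87.640449  77.319588 100.000000
     v1  HFpEF  65  16  86  11    85.526316    84.313725  84.831461  80.246914  88.659794
     v2  HFrEF  71   0  94   0   100.000000   100.000000 100.000000 100.000000 100.000000
     v2  HFpEF  70   1  94   0   100.000000    98.947368  99.393939  98.591549 100.000000
```

(abridged; the full table includes HFmrEF and delta rows). Read it as:
the legacy rule calls 97 patients HFrEF where only 75 truly are —
perfect sensitivity, poor precision — while the hierarchy-based
algorithm removes essentially all of those false positives. Per-patient
audit trails land in `phenotypes.csv`:

```
patient_id,algorithm_version,included,phenotype,effective_lvef,rule_fired,evidence_date,evidence_provenance
P00000,v2,true,HFrEF,17,high_quality_within_priority_window;single_value,2023-04-12,nlp_echo
```

`hfdash kpi` and `hfdash report` then produce the score tables and the
self-contained HTML dashboard.

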