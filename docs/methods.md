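# Methods

## Problem and model

`hfdash` implements a rule-based (not statistical) computable phenotype
for heart failure. There is nothing to fit: the scientific content is a
deterministic decision cascade over dated, quality-tiered left
ventricular ejection fraction (LVEF) measurements, and the package's
job is to implement that cascade exactly, make its every branch
auditable, and quantify — on synthetic data with known truth — how it
behaves relative to the legacy lowest-value rule it replaced.

### Inclusion

A patient is phenotyped only with documented HF: any encounter
diagnosis matching the HF code set on or before the as-of date, or an
active problem-list HF entry. The default code set is ICD-10 `I50.*`
plus ICD-9 `428.*`; both vocabularies are accepted because a 3-year
lookback can span the coding transition. "Active" is taken as a
boolean in the input data, not inferred. Symptomatic (stage C/D) HF is
operationalized *as* documented HF; the package makes no attempt to
stage patients A/B.

### Source-quality hierarchy

Tier is a total function of (provenance, modality, number of values):

| provenance | condition | tier |
|---|---|---|
| echo-report text | 1 value | high |
| echo-report text | >1 value | medium |
| clinical-note text | any | medium |
| radiology-report text | any | excluded |
| cath-lab registry | TTE, TEE, MRI, CT | high |
| cath-lab registry | ventriculography | medium |
| cath-lab registry | nuclear | excluded |

Cardiac CT registry entries are read as high tier, literally per the
source table. Unknown combinations raise (`fail closed`) rather than
receive a guessed tier. Text mentions in non-cardiac contexts
(gallbladder ejection fractions) are dropped before tiering; excluded-
tier items are kept and marked for audit but can never influence a
phenotype (a test mutates them and asserts identical output).

### Selection cascade (v2)

With config defaults `lookback_years=3`, `high_quality_priority_years=1`,
`multi_value_avg_threshold=10`, `implausible_value_threshold=75`:

1. keep non-excluded items in `[as_of − 3y, as_of]`; empty →
   `unspecified_no_data`;
2. high-tier item within `[as_of − 1y, as_of]` → candidates are the
   high-tier items on the most recent such date; otherwise candidates
   are the items on the most recent date in the lookback, with medium
   dropped when a high-tier item shares that date;
3. conflict: distinct single-valued candidates on the chosen date
   individually implying both LVEF ≤ 40 and LVEF ≥ 50 →
   `unspecified_conflict`;
4. pool candidate values; one value → use it; several → any value
   > 75 → `unspecified_implausible`, else spread ≤ 10 → mean of max
   and min, spread > 10 → max.

Classification bands: ≤ 40 HFrEF, the open interval (40, 50) HFmrEF
(so an averaged 40.5 or 49.5 is HFmrEF), ≥ 50 HFpEF.

Design choices made where the rules were genuinely open:

* **Windows** are calendar-anniversary based and inclusive at the old
  boundary; Feb 29 anniversaries map to Feb 28. Boundary behavior is
  pinned by tests (an item exactly 3 years old is in; one day older is
  out).
* **Conflict scope.** The conflict rule is applied to same-date
  candidates only, because the cascade otherwise yields a single date;
  and only to the reduced-vs-preserved pair. Same-date HFrEF-vs-HFmrEF
  disagreement flows through multi-value pooling instead.
* **The > 75% rule** applies only inside multi-value resolution, where
  it was defined; a lone single-value LVEF of 80 classifies as HFpEF.
* **Date ties** between high and medium tier outside the priority
  window: high wins — quality preference is the design's animating
  principle.
* **≥ 3 pooled values:** "high and low" are read as max and min.
* Intra-day ordering of studies is not modeled.

### Legacy baseline (v1)

Minimum over every value of every item — all tiers, excluded included —
in the lookback window; ≤ 40 → HFrEF, > 40 → HFpEF; no multi-value or
conflict logic. With no LVEF at all, ICD codes alone decide: systolic-
HF code families (`I50.2x`, `I50.4x`, `428.2x`, `428.4x`) → HFrEF,
diastolic (`I50.3x`, `428.3x`) → HFpEF, otherwise unspecified. That
fallback mapping is an assumption exposed in `HfCodeConfig`, because
the legacy rule is only documented as "ICD codes alone".

### Text extraction

A deterministic regex extractor stands in for a production NLP system.
It recognizes LVEF/EF/ejection-fraction phrases followed by a value, a
range (hyphen, en-dash, "to"; both endpoints returned), or a decimal
fraction in (0, 1] (rescaled ×100 and rounded to 6 decimals so
`0.29 → 29` exactly). Qualitative wording ("normal LV systolic
function") yields nothing — no word-to-number map is invented. A
40-character window before the EF phrase is checked for non-cardiac
contexts (gallbladder, right ventricle). Values outside (0, 100] after
normalization are discarded with a warning. Patterns are YAML-
extensible; negation and sectionizing are out of scope. Extraction is
a pure function of (text, patterns), so its tests demand exact — not
approximate — round-trips against a fuzz bank of 200 generated
reports.

## Evaluation

Each phenotype is scored one-vs-rest: sensitivity 100·TP/(TP+FN),
specificity 100·TN/(TN+FP), accuracy 100·(TP+TN)/total, PPV
100·TP/(TP+FP), NPV 100·TN/(TN+FN); zero denominators leave a metric
undefined (None), never zero. By default only patients an algorithm
actually classified enter its confusion counts (unspecified predictions
are dropped); `population="all_included"` counts them as negative for
every class. Formulas are cross-checked against scikit-learn's
confusion matrix on random label sets in the test suite; scikit-learn
is never the implementation.

## Synthetic cohorts

The generator emulates the documented failure modes of the real data
sources, with all randomness flowing from one seed:

* true phenotype per patient from a prevalence map (defaults 0.40 /
  0.15 / 0.45 for HFrEF / HFmrEF / HFpEF), true LVEF uniform on an
  integer band **2 points inside** the class boundaries (15–38, 43–47,
  52–73) so that noise-free recovery must be exact and boundary
  semantics are tested separately, on purpose;
* 1–5 studies per patient over 3 years from a source mix (echo 0.45,
  note 0.15, radiology 0.20, registry 0.20);
* echo reports carry the true LVEF; with probability 0.30 they state a
  symmetric range of even spread 2–20 around it (spread ≤ 10 averages
  back to truth; larger spreads bias the v2 estimate up by up to 10);
* nuclear values (registry entries sourced "nuclear", and the cardiac
  radiology reports) get additive Gaussian error, mean −10, sd 15,
  clipped to [5, 95] — the bias is the package's own choice of
  magnitude, since only the *existence* of nuclear inaccuracy is
  documented;
* 15% of radiology reports instead state a gallbladder EF of 80–98%;
* coding noise: 10% of patients lack all HF documentation; 15% of
  documented patients carry a code family contradicting their true
  phenotype (this only affects the legacy ICD-only fallback); 50% get
  an active problem-list entry;
* GDMT orders, harmful medications, admissions and encounters are
  generated at fixed rates purely to exercise the KPI engine.

The `clean` preset turns every noise process off (one recent single-
value echo per patient, perfect coding); the `paper_like` preset is
the defaults above. What passing tests show: the pipeline's logic is
exact, and the hierarchy's advantage over the lowest-value rule is
directionally robust under these noise processes. What they do not
show: performance on real clinical text (real reports are far messier
than the template bank), real coding behavior, or real source mixes —
the generator's rates are illustrative, not estimates of any system's
data.

## Numerical and degenerate-input choices

* All dates are ISO calendar dates; day resolution throughout.
* Multi-value averaging uses the arithmetic mean of the two extremes
  (not of all values) — that is what the rule says.
* KPI percentages are 100·numerator/denominator with exact integer
  counts; denominator 0 renders as "—" and colors as "none".
  Provider/facility/network counts are conserved to the national row
  by construction and by test.
* Lower-is-better KPIs (high-risk status, harmful medications) mirror
  the color thresholds (green ≤ 20% under the default 80/60 cut
  points); thresholds are config-only.
* Cohort files are written with sorted rows and RFC-4180 quoting so
  write → read → write is byte-identical; report free text lives in
  JSON-lines because embedded newlines survive JSON encoding
  trivially.

## Problem sizes

The shipped checks use 500 patients for noise-free recovery, 2000 for
the noisy comparison, 1000 random evidence sets for oracle
equivalence, and 200 fuzzed reports for extraction — sizes at which
every directional margin observed is stable across seeds and the whole
suite runs in seconds.

## Known limitations

* The extractor is a desk-scale stand-in; it does not handle negation,
  hedging, templated section headers, or historical-value mentions.
* No ACC/AHA stage A/B identification, NYHA class, or outcome
  modeling.
* GDMT class membership and target doses ship as guideline-derived
  defaults in config; they are not assertions about any deployed
  system's measure definitions.
* The legacy baseline's ICD-only fallback mapping is an assumption
  (documented above), and real-world legacy behavior may have
  differed.
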