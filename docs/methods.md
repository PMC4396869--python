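# Methods

## Model and scope

`insulaid` operationalises a family of *objective insulin-initiation
aids*: deterministic functions of routinely collected glycemic data that
characterise whether a patient's hyperglycemia is predominantly fasting,
predominantly postprandial, or mixed, and map that characterisation to a
first- and second-choice starting regimen. The underlying physiological
reasoning is simple: fasting glucose reflects hepatic glucose output and
responds to basal insulin; postprandial excursions reflect prandial
insulin deficit and respond to rapid-acting insulin, alone or as the
rapid fraction of a premixed (biphasic) preparation.

The engine deliberately does **not** produce a single merged
recommendation. The individual tables have different blind spots — PPGE
and PFI ignore absolute severity, the FPG:HbA1c ratio ignores
postprandial data entirely — and no validated rule exists for combining
them. The unit of output is therefore *per-table recommendation plus a
concordance label*, with discordance explicitly flagged for clinician
review. Post-challenge and post-load glucose (OGTT, mixed-meal tests) are
out of scope: artificially induced glycemic loads are not an appropriate
basis for routine insulin selection, and no operation in this package
accepts them. Insulin dose calculation and titration are likewise out of
scope.

## Index definitions and numerical conventions

All glucose arithmetic is unit-aware. `mg%` is treated as an exact
synonym of mg/dl, and the mg/dl↔mmol/l conversion uses the clinical
convention of 18.0 (a named, config-overridable constant) rather than the
molar-mass 18.016, because the published cutoff pairs this package
reproduces are rounded clinical values. Glucose outside 20–1000 mg/dl
logs a warning but is never rejected. HbA1c must lie in (0, 25)% NGSP;
no IFCC conversion is provided.

* **PPGE = PPG − FPG**, in the working unit. Negative excursions
  (postprandial below fasting) are legal, retained, and annotated — they
  classify into the lowest (basal) band with a data-quality warning.
* **PFI = (PPG − FPG)/FPG**, dimensionless and scale-invariant:
  PFI(k·FPG, k·PPG) = PFI(FPG, PPG). This invariance *is* the index's
  known blindness to severity, and is verified as a property test.
* **FPG:HbA1c ratio** on either of two scales, recorded in the result:
  the mmol scale (cutoff 1.3 = 7.8/6.0) or the mg% scale (cutoff
  20 = 126/6.3). The two anchors are mutually inconsistent — 7.8 mmol/l
  is 140.4 mg/dl, not 126 — so the two scale representations of one
  patient can fall on opposite sides of their cutoffs. Both cutoffs are
  implemented as printed; when they disagree the assessment attaches a
  warning rather than resolving the ambiguity.
* **1,5-AG:HbA1c ratio** is computed and reported but drives no decision
  band: no cutoffs for it have been proposed.

The reference PPG is, by default, the highest meal-tagged reading
(`MAX_PEAK`) — the peak-based rule is also what fixes injection timing
(once-daily premixed insulin accompanies the meal with the highest
peak). A `MEAN` policy is available for users who prefer the overall
postprandial burden. Meal ties break deterministically in day order,
breakfast first. Readings stamped outside 0.5–3 h post-meal (around the
recommended 1–2 h window) are annotated but never excluded. Index values
are kept at full precision; the 2-decimal rounding in reports is display
only, and all cutoff comparisons use unrounded values.

## Decision tables and boundary policy

Tables are data (`AidTable` = ordered bands with open/closed interval
flags), constructed from configurable cutoffs and validated at build time
to be pairwise disjoint and jointly exhaustive over the whole real line,
so every finite value maps to exactly one band. Boundary policy:

* AID-1/AID-2 print ">upper", "lower–upper", "<lower": the hyphenated
  middle band owns both endpoints (so PPGE 74 and PFI 0.4/0.6 classify
  into the middle band), and the outer inequalities are strict.
* AID-3's source prints both "≥" and "≤" at its cutoff. The exact cutoff
  value is assigned to the fasting-type (basal) row — consistent with the
  cohort study that used ≥1.3 as the fasting-type criterion — and any
  classification within 1e-9 of the cutoff carries a boundary-ambiguity
  note.
* The PFI upper threshold is the printed 0.6, a one-decimal rounding of
  74/126 ≈ 0.587. The printed value is authoritative; the derivation is
  reproduced in tests, not recomputed at run time.

The sequential HbA1c → 1,5-AG assessment requires two thresholds that
have no published default — the HbA1c treatment target and the 1,5-AG
"low" threshold — so both are mandatory configuration; with 1,5-AG data
present but thresholds unset, the step is skipped with an explanatory
note. Above-target HbA1c with normal 1,5-AG yields basal-targeting
advice; with low 1,5-AG, prandial-targeting advice (noting the preference
for a 50:50 over a 30:70/25:75 biphasic). HbA1c above 10% (configurable)
adds a severity note — very high values empirically prompt basal-bolus
regimens — but never alters any table output, since no threshold table
for HbA1c alone exists.

Concordance labeling is a reporting convention of this package (flagged
as such in the JSON output): FULL when all applicable tables' first
choices agree; SINGLE when only one table is applicable; PARTIAL when a
strict subset of tables shares a first choice *or* one table's second
choice matches another's first; DISCORDANT otherwise. The subset clause
is deliberate: with three applicable tables, two agreeing on the first
choice is materially different from three-way disagreement, and labeling
it DISCORDANT would overstate the conflict.

## Cohort ingestion

The interchange format is a flat SMBG CSV (UTF-8, comma-separated,
header required, decimal point only): one measurement per row with
patient id, measurement type (FASTING/POSTPRANDIAL/HBA1C/AG), optional
meal tag, value, unit string, optional hours-post-meal and ISO date.
Malformed rows are collected into a line-numbered error report and never
silently dropped; a missing required column is a schema error naming the
column (CLI exit code 2). Repeated same-type measurements collapse by
the configured policy — MEAN (default) or LATEST by date, with
order-independent tie-breaks so that input row order can never change a
result. All glucose is normalized to the working unit (default mg/dl) at
ingestion.

## Synthetic cohorts

The generator emulates the three hyperglycemia phenotypes a clinician
encounters, with transparent (not physiological) draws: FPG from a
truncated normal, per-meal PPG = FPG + an independent truncated-normal
excursion, HbA1c linearly linked to FPG (slope 0.02 %/(mg/dl), Gaussian
noise, clipped to the valid assay range), and 1,5-AG from a
phenotype-typical truncated normal. Default parameterisation (mg/dl, %):

| Phenotype | FPG mean (sd) | excursion mean (sd) | HbA1c mean | 1,5-AG mean (sd) |
|---|---|---|---|---|
| fasting-type | 200 (20) | 25 (10) | 9.0 | 12 (2) |
| postprandial-type | 115 (10) | 110 (25) | 7.8 | 4 (1.5) |
| overall | 180 (20) | 80 (20) | 9.5 | 6 (2) |

No quantitative definition of these phenotypes exists in the literature;
the parameters are illustrative values chosen once to place each
phenotype's indices well inside the bands a clinician would expect
(fasting-type: PFI ≈ 0.125, mg-scale ratio ≈ 22; postprandial-type:
PFI ≈ 0.96, ratio ≈ 15), with enough dispersion that boundary bands are
also exercised. The HbA1c–FPG link coefficients are synthetic. Truncated
normals (resample-until-positive) were chosen over lognormals for
transparency. Identical spec + seed reproduces a byte-identical cohort
(numpy `default_rng`).

What passing synthetic tests show — and do not show: they demonstrate
that the engine's classification geometry is correct (a cohort built to
be fasting-type is overwhelmingly classified fasting-type), that every
decision path is reachable, and that the pipeline is deterministic. They
say nothing about real-world prevalence, measurement noise of SMBG
meters, day-to-day variability, or the clinical validity of the cutoffs
themselves — the aids are empirical proposals whose validation requires
prospective studies. The concordance study (default n = 50–200 per
phenotype in the test suite, chosen to keep the suite fast while making
the ≥80% recovery assertions statistically comfortable) quantifies how
often the three tables agree within each phenotype; the observed
discordance in the "overall" phenotype is expected, since its indices sit
near several cutoffs at once.

## Known limitations

* The mg-scale and mmol-scale FPG:HbA1c cutoffs are mutually
  inconsistent at source; the engine surfaces, but cannot resolve, the
  disagreement band (mg ratio ≥ 20 while mmol ratio < 1.3).
* PPGE doubles as a per-patient excursion and as a difference of
  diagnostic thresholds (200 − 126, where 200 mg% is strictly a post-load
  criterion); the arithmetic is identical and the engine computes it
  either way, but the epistemic mismatch is inherited from the source
  tables.
* The concordance label and the synthetic phenotype parameters are
  constructs of this package, not validated clinical instruments.
* HL7/FHIR ingestion, glucometer export formats and dose titration are
  not implemented.
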