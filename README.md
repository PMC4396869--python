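# insulaid

Objective, rule-based decision support for **choosing an initial insulin
regimen** in type 2 diabetes. Guidelines disagree on whether to start with
basal or premixed insulin, and in practice the choice is often subjective.
`insulaid` implements a set of simple, auditable indices computed from
routinely available glycemic data, and classifies them through
configurable threshold tables ("Aids for Insulin Decision", AID) that map
each index to a first- and second-choice starting regimen. It is aimed at
clinical-informatics researchers and decision-support developers who want
the rules as tested, data-driven code rather than as a table in a PDF.

## The indices

For fasting plasma glucose *FPG*, a reference postprandial glucose *PPG*
(by default the meal with the highest reading), glycated hemoglobin
*HbA1c* (NGSP %), and serum 1,5-anhydroglucitol *1,5-AG*:

| Index | Formula | Scale |
|---|---|---|
| Postprandial glucose excursion (PPGE) | PPG − FPG | mg% (= mg/dl) |
| Prandial:fasting index (PFI) | (PPG − FPG) / FPG | dimensionless |
| Fasting:HbA1c ratio | FPG / HbA1c | mg% per % (or mmol/l per %) |
| 1,5-AG:HbA1c ratio | 1,5-AG / HbA1c | informational only |

The decision tables, with cutoffs derived from diagnostic limits
(e.g. 74 = 200 − 126 mg%, the diabetes PPG and FPG criteria;
20 = 126 / 6.3):

* **AID-1** (PPGE, mg%): >74 → rapid acting / premixed 50:50;
  40–74 → premixed 30:70 / premixed 50:50; <40 → basal / premixed 30:70.
* **AID-2** (PFI): same ladder with cutoffs 0.6 / 0.4.
* **AID-3** (FPG:HbA1c): ≥20 (mg scale; 1.3 on the mmol scale) → basal /
  premixed with dinner (fasting-type hyperglycemia); below → premixed /
  premixed with breakfast (postprandial-type).

A sequential HbA1c → 1,5-AG assessment separates basal-targeting from
prandial-targeting therapy in patients above their HbA1c target, and the
meal with the highest postprandial peak is reported as the injection
timing for once-daily premixed regimens. The engine **never merges the
tables into one answer**: no combiner has been validated, so it reports
every applicable table's output plus a concordance label
(FULL / PARTIAL / DISCORDANT / SINGLE) and flags disagreement for
clinician review.

## Worked example

```sh
insulaid assess --fpg 126 --ppg 200 --meal lunch --hba1c 6.3
```

prints

```
Patient cli-patient
-------------------
  PPGE       74.00 mg/dl
  PFI        0.59 dimensionless
  FPG_HBA1C  20.00 mg% per %
  AG_HBA1C   not applicable (1,5-AG missing)
  AID-1 [40-74 mg%]: 1) Premixed insulin (30:70); 2) Premixed insulin (50:50); give with lunch
  AID-2 [0.4-0.6]: 1) Premixed insulin (30:70); 2) Premixed insulin (50:50); give with lunch
  AID-3 [>=20]: 1) Basal insulin; 2) Premixed insulin with dinner; give with lunch
    note: boundary ambiguity: ratio equals the 20 cutoff; assigned to the fasting-type (basal) row by policy
  Agreement: PARTIAL (3 aid(s) applicable)
  warning: FPG:HbA1c scale disagreement: mg-scale ratio 20.00 vs cutoff 20 and mmol-scale ratio 1.11 vs cutoff 1.3 fall on opposite sides; the published cutoffs are not exactly unit-consistent — review manually
```

This patient sits exactly on the diagnostic anchors: the excursion is
74 mg% (boundary of the middle AID-1 band, which owns its endpoints), the
PFI of 0.59 falls in the intermediate band, and the fasting ratio of
exactly 20 classifies — by explicit boundary policy, with an ambiguity
note — as fasting-type. Two tables point to premixed 30:70 and one to
basal, hence PARTIAL agreement. The final warning is real: the published
mg-scale and mmol-scale cutoffs are not related by the 18.0 conversion
factor, so a patient can fall on opposite sides of the two; the engine
surfaces this rather than silently picking a side.

The same engine runs on cohorts (`insulaid batch cohort.csv -o report.json`),
on seeded synthetic cohorts emulating fasting-type, postprandial-type and
overall hyperglycemia (`insulaid synth --phenotype fasting --n 200 --seed 42
-o cohort.csv`), and prints its active tables for audit (`insulaid tables`).
Every cutoff is configurable through a YAML/JSON file. The same operations
are available as a library (`insulaid.assess`, `insulaid.concordance_study`,
...).

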