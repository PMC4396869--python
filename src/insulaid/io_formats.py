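"""Cohort CSV ingestion and structured report rendering.

The interchange format is a flat SMBG (self-monitored blood glucose) CSV,
one measurement per row::

    patient_id,measurement_type,meal_tag,value,unit,hours_post_meal,date
    p01,FASTING,,200,mg/dl,,2024-01-05
    p01,POSTPRANDIAL,LUNCH,300,mg/dl,1.5,2024-01-05
    p01,HBA1C,,8.6,%,,
    p01,AG,,6.2,ug/ml,,

``measurement_type`` is one of FASTING / POSTPRANDIAL / HBA1C / AG
(case-insensitive).  POSTPRANDIAL rows without a meal tag default to
OTHER.  Malformed rows are collected into an error report with their line
numbers — never silently dropped.

Reports serialise every index at full precision alongside 2-decimal
display strings; classification always uses the unrounded values.
"""

from __future__ import annotations

import csv
import enum
import json
from dataclasses import dataclass, field
from datetime import date as _date
from pathlib import Path
from typing import Optional

from .config import Aggregation, EngineConfig
from .decision import ConcordanceSummary, Recommendation, SequentialAgResult
from .indices import GlycemicProfile, IndexResult, MealTag, PpgPolicy, PpgReading
from .units import AnhydroglucitolValue, GlucoseValue, HbA1cValue, Unit, ValidationError

REPORT_SCHEMA_VERSION = 1

CSV_COLUMNS = ["patient_id", "measurement_type", "meal_tag", "value", "unit",
               "hours_post_meal", "date"]
_REQUIRED_COLUMNS = {"patient_id", "measurement_type", "value", "unit"}


class SchemaError(ValidationError):
    """The file as a whole is unusable (missing columns, no header...)."""


class MeasurementType(enum.Enum):
    FASTING = "FASTING"
    POSTPRANDIAL = "POSTPRANDIAL"
    HBA1C = "HBA1C"
    AG = "AG"


@dataclass(frozen=True)
class SmbgRecord:
    """One parsed CSV row."""

    patient_id: str
    measurement_type: MeasurementType
    value: float
    unit: str
    meal_tag: Optional[MealTag] = None
    hours_post_meal: Optional[float] = None
    date: Optional[_date] = None


@dataclass(frozen=True)
class RowError:
    line: int
    message: str


@dataclass
class CohortParseResult:
    profiles: list[GlycemicProfile]
    errors: list[RowError] = field(default_factory=list)


def _parse_row(row: dict) -> SmbgRecord:
    pid = (row.get("patient_id") or "").strip()
    if not pid:
        raise ValidationError("empty patient_id")
    try:
        mtype = MeasurementType[(row.get("measurement_type") or "").strip().upper()]
    except KeyError:
        raise ValidationError(
            f"unknown measurement_type: {row.get('measurement_type')!r}"
        ) from None
    try:
        value = float(row.get("value") or "")
    except ValueError:
        raise ValidationError(f"non-numeric value: {row.get('value')!r}") from None
    unit = (row.get("unit") or "").strip()
    meal = None
    if mtype is MeasurementType.POSTPRANDIAL:
        raw_meal = (row.get("meal_tag") or "").strip()
        meal = MealTag.parse(raw_meal) if raw_meal else MealTag.OTHER
    if mtype in (MeasurementType.FASTING, MeasurementType.POSTPRANDIAL):
        Unit.parse(unit)  # rejects unknown glucose unit strings early
    if mtype is MeasurementType.HBA1C and unit not in ("%", ""):
        raise ValidationError(f"HbA1c rows must use unit '%', got {unit!r}")
    hours = None
    raw_hours = (row.get("hours_post_meal") or "").strip()
    if raw_hours:
        try:
            hours = float(raw_hours)
        except ValueError:
            raise ValidationError(f"non-numeric hours_post_meal: {raw_hours!r}") from None
    d = None
    raw_date = (row.get("date") or "").strip()
    if raw_date:
        try:
            d = _date.fromisoformat(raw_date)
        except ValueError:
            raise ValidationError(f"bad ISO date: {raw_date!r}") from None
    return SmbgRecord(pid, mtype, value, unit or "%", meal, hours, d)


def _aggregate(records: list[SmbgRecord], policy: Aggregation) -> SmbgRecord:
    """Collapse repeated same-type (and same-meal) records to one.

    MEAN averages values (order-independent).  LATEST takes the most
    recent date — undated records sort earliest, and ties resolve to the
    highest value so that input row order never matters.
    """
    if len(records) == 1:
        return records[0]
    if policy is Aggregation.LATEST:
        return max(records, key=lambda r: (r.date or _date.min, r.value))
    mean = sum(r.value for r in records) / len(records)
    base = records[0]
    return SmbgRecord(base.patient_id, base.measurement_type, mean, base.unit,
                      base.meal_tag, base.hours_post_meal, None)


def _profile_from_records(
    pid: str, records: list[SmbgRecord], cfg: EngineConfig
) -> GlycemicProfile:
    working = cfg.working_unit
    fasting = [r for r in records if r.measurement_type is MeasurementType.FASTING]
    post = [r for r in records if r.measurement_type is MeasurementType.POSTPRANDIAL]
    a1c = [r for r in records if r.measurement_type is MeasurementType.HBA1C]
    ag = [r for r in records if r.measurement_type is MeasurementType.AG]

    def to_glucose(r: SmbgRecord) -> GlucoseValue:
        return GlucoseValue(r.value, Unit.parse(r.unit)).to(working, cfg.mg_per_mmol)

    fpg = None
    if fasting:
        normalized = [
            SmbgRecord(r.patient_id, r.measurement_type, to_glucose(r).value,
                       working.value, r.meal_tag, r.hours_post_meal, r.date)
            for r in sorted(fasting, key=lambda r: (r.date or _date.min, r.value))
        ]
        fpg = GlucoseValue(_aggregate(normalized, cfg.aggregation).value, working)

    readings: list[PpgReading] = []
    by_meal: dict[MealTag, list[SmbgRecord]] = {}
    for r in post:
        by_meal.setdefault(r.meal_tag, []).append(r)
    for meal in sorted(by_meal):
        group = [
            SmbgRecord(r.patient_id, r.measurement_type, to_glucose(r).value,
                       working.value, r.meal_tag, r.hours_post_meal, r.date)
            for r in sorted(by_meal[meal], key=lambda r: (r.date or _date.min, r.value))
        ]
        if cfg.aggregation is Aggregation.LATEST:
            chosen = _aggregate(group, Aggregation.LATEST)
        elif cfg.ppg_policy is PpgPolicy.MEAN:
            chosen = _aggregate(group, Aggregation.MEAN)
        else:  # peak-based policies keep the per-meal maximum
            chosen = max(group, key=lambda r: r.value)
        readings.append(
            PpgReading(meal, GlucoseValue(chosen.value, working), chosen.hours_post_meal)
        )

    hba1c = None
    if a1c:
        hba1c = HbA1cValue(_aggregate(sorted(a1c, key=lambda r: (r.date or _date.min, r.value)),
                                      cfg.aggregation).value)
    ag_value = None
    if ag:
        chosen = _aggregate(sorted(ag, key=lambda r: (r.date or _date.min, r.value)),
                            cfg.aggregation)
        ag_value = AnhydroglucitolValue(chosen.value, chosen.unit if chosen.unit != "%" else "ug/ml")
    return GlycemicProfile(pid, fpg, readings, hba1c, ag_value)


def read_cohort_csv(path: str | Path, config: Optional[EngineConfig] = None) -> CohortParseResult:
    """Parse an SMBG cohort CSV into per-patient profiles.

    Rows group by ``patient_id``; repeated measurements collapse per the
    configured aggregation policy.  Row-level problems land in
    ``result.errors`` with 1-based line numbers; a missing required column
    raises :class:`SchemaError` naming it.
    """
    cfg = config or EngineConfig()
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, header row required")
        header = {h.strip().lower() for h in reader.fieldnames}
        missing = _REQUIRED_COLUMNS - header
        if missing:
            raise SchemaError(f"{path}: missing required column(s): {', '.join(sorted(missing))}")
        records: dict[str, list[SmbgRecord]] = {}
        errors: list[RowError] = []
        for line_no, row in enumerate(reader, start=2):
            row = {(k or "").strip().lower(): v for k, v in row.items()}
            try:
                rec = _parse_row(row)
            except ValidationError as exc:
                errors.append(RowError(line_no, str(exc)))
                continue
            records.setdefault(rec.patient_id, []).append(rec)
    profiles = [
        _profile_from_records(pid, recs, cfg) for pid, recs in sorted(records.items())
    ]
    return CohortParseResult(profiles=profiles, errors=errors)


def write_cohort_csv(profiles: list[GlycemicProfile], path: str | Path) -> None:
    """Write profiles back to the flat SMBG CSV format."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for p in profiles:
            if p.fpg is not None:
                writer.writerow([p.patient_id, "FASTING", "", f"{p.fpg.value:.10g}",
                                 p.fpg.unit.value, "", ""])
            for r in p.ppg_readings:
                writer.writerow([
                    p.patient_id, "POSTPRANDIAL", r.meal.name, f"{r.reading.value:.10g}",
                    r.reading.unit.value,
                    "" if r.hours_post_meal is None else f"{r.hours_post_meal:g}", "",
                ])
            if p.hba1c is not None:
                writer.writerow([p.patient_id, "HBA1C", "", f"{p.hba1c.percent:.10g}", "%", "", ""])
            if p.ag is not None:
                writer.writerow([p.patient_id, "AG", "", f"{p.ag.value:.10g}", p.ag.unit, "", ""])


# -- report rendering --------------------------------------------------------


def _index_to_dict(r: IndexResult) -> dict:
    d = {
        "index": r.index_name.value,
        "applicable": r.applicable,
        "scale": r.scale,
        "inputs": r.inputs_used,
        "notes": list(r.notes),
    }
    if r.applicable:
        d["value"] = r.value
        d["display"] = f"{r.value:.2f}"
    else:
        d["reason"] = r.reason
    return d


def _recommendation_to_dict(rec: Recommendation) -> dict:
    return {
        "aid": rec.aid_name.value,
        "band": rec.band_label,
        "choice1": rec.choice1.value,
        "choice2": rec.choice2.value,
        "rationale": rec.rationale,
        "index_value": rec.index_value,
        "index_display": f"{rec.index_value:.2f}",
        "timing_meal": rec.timing_meal.name if rec.timing_meal else None,
        "notes": list(rec.notes),
    }


def _sequential_to_dict(seq: Optional[SequentialAgResult]) -> Optional[dict]:
    if seq is None:
        return None
    return {
        "regimen": seq.regimen.value if seq.regimen else None,
        "controlled": seq.controlled,
        "notes": list(seq.notes),
    }


def summary_to_dict(s: ConcordanceSummary) -> dict:
    return {
        "patient_id": s.patient_id,
        "indices": [_index_to_dict(r) for r in s.indices],
        "recommendations": [_recommendation_to_dict(s.per_aid[a]) for a in sorted(
            s.per_aid, key=lambda a: a.value)],
        "n_applicable": s.n_applicable,
        "agreement": s.agreement.value,
        "agreement_note": "agreement label is a reporting convention of this tool, "
                          "not a validated clinical category",
        "timing_meal": s.timing_meal.name if s.timing_meal else None,
        "sequential_ag": _sequential_to_dict(s.sequential_ag),
        "notes": list(s.notes),
    }


class ReportFormat(enum.Enum):
    JSON = "json"
    TEXT = "text"


def write_report(
    summaries: list[ConcordanceSummary], format: ReportFormat = ReportFormat.JSON
) -> str:
    """Render assessment summaries as a JSON document or a plain-text report.

    The JSON form is round-trippable: :func:`parse_report` recovers every
    machine-readable field.  The text form shows indices at 2 decimals,
    per-aid choices, the timing meal, and every warning emitted.
    """
    if format is ReportFormat.JSON:
        doc = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "n_patients": len(summaries),
            "patients": [summary_to_dict(s) for s in summaries],
        }
        return json.dumps(doc, indent=2)
    lines: list[str] = []
    for s in summaries:
        lines.append(f"Patient {s.patient_id}")
        lines.append("-" * (8 + len(s.patient_id)))
        for r in s.indices:
            if r.applicable:
                lines.append(f"  {r.index_name.value:<10} {r.value:.2f} {r.scale}")
            else:
                lines.append(f"  {r.index_name.value:<10} not applicable ({r.reason})")
        for aid in sorted(s.per_aid, key=lambda a: a.value):
            rec = s.per_aid[aid]
            timing = f"; give with {rec.timing_meal.name.lower()}" if rec.timing_meal else ""
            lines.append(
                f"  {aid.value} [{rec.band_label}]: 1) {rec.choice1.value}; "
                f"2) {rec.choice2.value}{timing}"
            )
            for note in rec.notes:
                lines.append(f"    note: {note}")
        if s.sequential_ag is not None:
            seq = s.sequential_ag
            verdict = seq.regimen.value if seq.regimen else "controlled, no change advised"
            lines.append(f"  Sequential HbA1c/1,5-AG: {verdict}")
            for note in seq.notes:
                lines.append(f"    note: {note}")
        lines.append(f"  Agreement: {s.agreement.value} ({s.n_applicable} aid(s) applicable)")
        for note in s.notes:
            lines.append(f"  warning: {note}")
        lines.append("")
    if not summaries:
        lines.append("No patients assessed.")
    return "\n".join(lines)


def parse_report(text: str) -> dict:
    """Parse and structurally validate a JSON report produced by this tool."""
    doc = json.loads(text)
    if not isinstance(doc, dict):
        raise SchemaError("report must be a JSON object")
    for key in ("schema_version", "n_patients", "patients"):
        if key not in doc:
            raise SchemaError(f"report missing key {key!r}")
    if doc["schema_version"] != REPORT_SCHEMA_VERSION:
        raise SchemaError(f"unsupported report schema version {doc['schema_version']!r}")
    if not isinstance(doc["patients"], list) or len(doc["patients"]) != doc["n_patients"]:
        raise SchemaError("n_patients does not match the patients array")
    for entry in doc["patients"]:
        for key in ("patient_id", "indices", "recommendations", "agreement", "n_applicable"):
            if key not in entry:
                raise SchemaError(f"patient entry missing key {key!r}")
    return doc
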