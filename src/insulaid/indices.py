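"""Glycemic indices computed from a patient's fasting and postprandial data.

Four indices summarise where a patient's hyperglycemia comes from:

* **PPGE** — postprandial glucose excursion, PPG − FPG, in the working
  glucose unit.  Measures the prandial contribution in absolute terms.
* **PFI** — prandial:fasting index, (PPG − FPG) / FPG, dimensionless.
  Scale-free: it conveys the *relative* prandial contribution but not the
  severity of hyperglycemia (PFI is identical for FPG 200/PPG 300 and
  FPG 100/PPG 150).
* **FPG:HbA1c ratio** — fasting glucose over HbA1c%, on either the mmol/l
  or the mg% scale.  High values indicate fasting-type hyperglycemia.
* **1,5-AG:HbA1c ratio** — informational only; no decision cutoffs exist.

Each computation returns an :class:`IndexResult`.  An index a profile
cannot support (e.g. no postprandial reading, no HbA1c) yields an
*inapplicable* result carrying the reason — inapplicability is data, not
an error.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .units import (
    MG_PER_MMOL,
    AnhydroglucitolValue,
    GlucoseValue,
    HbA1cValue,
    Unit,
    ValidationError,
    convert_glucose,
)

#: IDF-recommended post-meal measurement window, hours.
IDF_PPG_WINDOW_H: tuple[float, float] = (1.0, 2.0)
#: Readings outside this wider window are annotated (never excluded).
PPG_ANNOTATION_WINDOW_H: tuple[float, float] = (0.5, 3.0)


class MealTag(enum.IntEnum):
    """Meal of the day; integer order is the tie-break day order."""

    BREAKFAST = 0
    LUNCH = 1
    DINNER = 2
    OTHER = 3

    @classmethod
    def parse(cls, text: str) -> "MealTag":
        try:
            return cls[text.strip().upper()]
        except KeyError:
            raise ValidationError(f"unknown meal tag: {text!r}") from None


class PpgPolicy(enum.Enum):
    """How the reference postprandial reading is chosen from a profile."""

    MAX_PEAK = "max_peak"
    MEAN = "mean"
    PER_MEAL = "per_meal"


class IndexName(enum.Enum):
    PPGE = "PPGE"
    PFI = "PFI"
    FPG_HBA1C = "FPG_HBA1C"
    AG_HBA1C = "AG_HBA1C"


class RatioScale(enum.Enum):
    """Scale of the FPG:HbA1c ratio; the decision cutoff depends on it."""

    MMOL_SCALE = "mmol/l per %"
    MG_SCALE = "mg% per %"


@dataclass(frozen=True)
class PpgReading:
    """One meal-tagged postprandial glucose reading."""

    meal: MealTag
    reading: GlucoseValue
    hours_post_meal: Optional[float] = None


@dataclass
class GlycemicProfile:
    """One patient's glycemic snapshot: the input to every index.

    ``fpg`` may be None only when the profile is used exclusively for the
    sequential A1C/1,5-AG assessment.  ``ppg_readings`` may be empty —
    PPGE/PFI are then inapplicable, not zero.
    """

    patient_id: str
    fpg: Optional[GlucoseValue] = None
    ppg_readings: list[PpgReading] = field(default_factory=list)
    hba1c: Optional[HbA1cValue] = None
    ag: Optional[AnhydroglucitolValue] = None

    def normalized(self, working_unit: Unit, mg_per_mmol: float = MG_PER_MMOL) -> "GlycemicProfile":
        """Return a copy with every glucose value in ``working_unit``."""
        fpg = self.fpg.to(working_unit, mg_per_mmol) if self.fpg else None
        readings = [
            PpgReading(r.meal, r.reading.to(working_unit, mg_per_mmol), r.hours_post_meal)
            for r in self.ppg_readings
        ]
        return GlycemicProfile(self.patient_id, fpg, readings, self.hba1c, self.ag)

    def timing_notes(self) -> list[str]:
        """Annotations for readings outside the plausible post-meal window."""
        lo, hi = PPG_ANNOTATION_WINDOW_H
        notes = []
        for r in self.ppg_readings:
            if r.hours_post_meal is not None and not (lo <= r.hours_post_meal <= hi):
                notes.append(
                    f"{r.meal.name.lower()} reading taken {r.hours_post_meal:g} h post-meal, "
                    f"outside the recommended 1-2 h window"
                )
        return notes


@dataclass
class IndexResult:
    """A named index value, or the reason it could not be computed.

    Exactly one of ``value`` / ``reason`` is populated:
    ``applicable`` is True iff ``value`` is present.
    """

    index_name: IndexName
    value: Optional[float] = None
    scale: str = "dimensionless"
    inputs_used: dict = field(default_factory=dict)
    applicable: bool = True
    reason: Optional[str] = None
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.applicable != (self.value is not None):
            raise ValueError("IndexResult: applicable must mirror presence of value")
        if not self.applicable and not self.reason:
            raise ValueError("inapplicable IndexResult requires a reason")


def _inapplicable(name: IndexName, reason: str, scale: str = "dimensionless") -> IndexResult:
    return IndexResult(name, value=None, scale=scale, applicable=False, reason=reason)


def select_reference_ppg(
    profile: GlycemicProfile, policy: PpgPolicy = PpgPolicy.MAX_PEAK
):
    """Pick the postprandial reading the indices are computed from.

    MAX_PEAK returns the highest reading and its meal (the decision-relevant
    choice: injections accompany the meal with the highest peak); ties break
    by day order, breakfast first.  MEAN returns the arithmetic mean tagged
    OTHER.  PER_MEAL returns ``{meal: max reading}`` for the timing logic.

    Raises :class:`~insulaid.units.ValidationError` if the profile has no
    postprandial readings.
    """
    if not profile.ppg_readings:
        raise ValidationError("no postprandial readings in profile")
    unit = profile.ppg_readings[0].reading.unit
    readings = [
        PpgReading(r.meal, r.reading.to(unit), r.hours_post_meal) for r in profile.ppg_readings
    ]
    if policy is PpgPolicy.PER_MEAL:
        per_meal: dict[MealTag, GlucoseValue] = {}
        for r in readings:
            cur = per_meal.get(r.meal)
            if cur is None or r.reading.value > cur.value:
                per_meal[r.meal] = r.reading
        return per_meal
    if policy is PpgPolicy.MEAN:
        mean = sum(r.reading.value for r in readings) / len(readings)
        return GlucoseValue(mean, unit), MealTag.OTHER
    # MAX_PEAK: highest value; ties resolved by day order (IntEnum order).
    best = max(readings, key=lambda r: (r.reading.value, -r.meal))
    return best.reading, best.meal


def ppge(fpg: GlucoseValue, ppg: GlucoseValue, mg_per_mmol: float = MG_PER_MMOL) -> IndexResult:
    """Postprandial glucose excursion: PPG − FPG in FPG's unit.

    A negative excursion (postprandial below fasting) is legal — it is
    retained and annotated, never clipped to zero.
    """
    if fpg is None:
        return _inapplicable(IndexName.PPGE, "FPG missing")
    if ppg is None:
        return _inapplicable(IndexName.PPGE, "no postprandial reading")
    ppg = convert_glucose(ppg, fpg.unit, mg_per_mmol)
    value = ppg.value - fpg.value
    result = IndexResult(
        IndexName.PPGE,
        value=value,
        scale=fpg.unit.value,
        inputs_used={"fpg": fpg.value, "ppg": ppg.value, "unit": fpg.unit.value},
    )
    if value < 0:
        result.notes.append("negative excursion: postprandial reading below fasting")
    return result


def pfi(fpg: GlucoseValue, ppg: GlucoseValue, mg_per_mmol: float = MG_PER_MMOL) -> IndexResult:
    """Prandial:fasting index: (PPG − FPG) / FPG, dimensionless.

    Unit-invariant because the unit cancels; undefined for FPG = 0.
    """
    if fpg is None:
        return _inapplicable(IndexName.PFI, "FPG missing")
    if ppg is None:
        return _inapplicable(IndexName.PFI, "no postprandial reading")
    ppg = convert_glucose(ppg, fpg.unit, mg_per_mmol)
    if fpg.value == 0:
        return _inapplicable(IndexName.PFI, "division by zero: FPG is 0")
    value = (ppg.value - fpg.value) / fpg.value
    result = IndexResult(
        IndexName.PFI,
        value=value,
        scale="dimensionless",
        inputs_used={"fpg": fpg.value, "ppg": ppg.value, "unit": fpg.unit.value},
    )
    if value < 0:
        result.notes.append("negative index: postprandial reading below fasting")
    return result


def fpg_hba1c_ratio(
    fpg: GlucoseValue,
    hba1c: Optional[HbA1cValue],
    scale: RatioScale = RatioScale.MG_SCALE,
    mg_per_mmol: float = MG_PER_MMOL,
) -> IndexResult:
    """FPG divided by HbA1c%, on the requested scale.

    The scale is recorded in the result so the decision layer can pick the
    matching cutoff (1.3 on the mmol scale, 20 on the mg% scale).
    """
    if fpg is None:
        return _inapplicable(IndexName.FPG_HBA1C, "FPG missing", scale.value)
    if hba1c is None:
        return _inapplicable(IndexName.FPG_HBA1C, "HbA1c missing", scale.value)
    numerator = (
        fpg.as_mmol_l(mg_per_mmol) if scale is RatioScale.MMOL_SCALE else fpg.as_mg_dl(mg_per_mmol)
    )
    return IndexResult(
        IndexName.FPG_HBA1C,
        value=numerator / hba1c.percent,
        scale=scale.value,
        inputs_used={"fpg": numerator, "hba1c_percent": hba1c.percent, "scale": scale.value},
    )


def ag_hba1c_ratio(
    ag: Optional[AnhydroglucitolValue], hba1c: Optional[HbA1cValue]
) -> IndexResult:
    """1,5-AG divided by HbA1c%.  Informational: no decision cutoffs exist."""
    if ag is None:
        return _inapplicable(IndexName.AG_HBA1C, "1,5-AG missing", "ug/ml per %")
    if hba1c is None:
        return _inapplicable(IndexName.AG_HBA1C, "HbA1c missing", "ug/ml per %")
    return IndexResult(
        IndexName.AG_HBA1C,
        value=ag.value / hba1c.percent,
        scale=f"{ag.unit} per %",
        inputs_used={"ag": ag.value, "hba1c_percent": hba1c.percent},
    )


def compute_all(profile: GlycemicProfile, config=None) -> list[IndexResult]:
    """Compute every index the profile supports; inapplicable ones carry the
    missing prerequisite by name.

    Always returns four results in the fixed order PPGE, PFI, FPG:HbA1c,
    AG:HbA1c.
    """
    from .config import EngineConfig  # local import to avoid a cycle

    cfg = config or EngineConfig()
    prof = profile.normalized(cfg.working_unit, cfg.mg_per_mmol) if profile.fpg else profile

    timing_notes = prof.timing_notes()
    if prof.ppg_readings:
        ref = select_reference_ppg(prof, cfg.ppg_policy if cfg.ppg_policy is not PpgPolicy.PER_MEAL
                                   else PpgPolicy.MAX_PEAK)
        ref_ppg, _ = ref
    else:
        ref_ppg = None

    r_ppge = ppge(prof.fpg, ref_ppg, cfg.mg_per_mmol)
    r_pfi = pfi(prof.fpg, ref_ppg, cfg.mg_per_mmol)
    r_ratio = (
        fpg_hba1c_ratio(prof.fpg, prof.hba1c, cfg.aid3_scale, cfg.mg_per_mmol)
        if prof.fpg is not None
        else _inapplicable(IndexName.FPG_HBA1C, "FPG missing", cfg.aid3_scale.value)
    )
    r_ag = ag_hba1c_ratio(prof.ag, prof.hba1c)
    for r in (r_ppge, r_pfi):
        if r.applicable:
            r.notes.extend(timing_notes)
    return [r_ppge, r_pfi, r_ratio, r_ag]
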