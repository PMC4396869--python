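"""Rule-based insulin-initiation decision engine.

Three published threshold tables ("Aids for Insulin Decision") map one
glycemic index each onto a first- and second-choice starting regimen:

* **AID-1** over PPGE (mg%): >74 → rapid acting / premixed 50:50;
  40–74 → premixed 30:70 / premixed 50:50; <40 → basal / premixed 30:70.
* **AID-2** over PFI: the same regimen ladder with cutoffs 0.6 / 0.4.
* **AID-3** over FPG:HbA1c: at or above the cutoff (1.3 mmol-scale,
  20 mg-scale) → basal / premixed with dinner (fasting-type
  hyperglycemia); below → premixed / premixed with breakfast
  (postprandial-type).

Boundary policy: the hyphenated middle band of AID-1/AID-2 owns both of
its endpoints (">74" and "<40" are strict, as printed).  AID-3's source
prints both "≥" and "≤" at the cutoff; the exact cutoff value is assigned
to the fasting-type (basal) row and any classification within 1e-9 of the
cutoff carries a boundary-ambiguity note.

The engine never merges the tables into a single answer: no combiner has
been validated.  :func:`assess` reports every applicable table's output
plus a concordance label, and flags discordance for clinician review.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

from .config import ConfigError, EngineConfig
from .indices import (
    GlycemicProfile,
    IndexName,
    IndexResult,
    MealTag,
    PpgPolicy,
    RatioScale,
    compute_all,
    fpg_hba1c_ratio,
    select_reference_ppg,
)
from .units import AnhydroglucitolValue, HbA1cValue, ValidationError

#: Width of the boundary-ambiguity annotation band around the AID-3 cutoff.
BOUNDARY_EPS = 1e-9


class Regimen(enum.Enum):
    """Insulin regimens appearing in the decision tables.

    The first number of a premixed (biphasic) ratio is the rapid-acting
    fraction; 50:50 carries more prandial cover than 30:70.
    """

    RAPID_ACTING = "Rapid acting insulin"
    PREMIXED_50_50 = "Premixed insulin (50:50)"
    PREMIXED_30_70 = "Premixed insulin (30:70)"
    PREMIXED = "Premixed insulin"
    BASAL = "Basal insulin"
    PREMIXED_WITH_DINNER = "Premixed insulin with dinner"
    PREMIXED_WITH_BREAKFAST = "Premixed insulin with breakfast"
    BASAL_TARGETING = "Therapy targeting basal glucose"
    PRANDIAL_TARGETING = "Therapy targeting prandial glucose"


#: Regimens with a prandial component: timing advice applies to these.
_PRANDIAL_REGIMENS = {
    Regimen.RAPID_ACTING,
    Regimen.PREMIXED_50_50,
    Regimen.PREMIXED_30_70,
    Regimen.PREMIXED,
    Regimen.PREMIXED_WITH_DINNER,
    Regimen.PREMIXED_WITH_BREAKFAST,
}


class Rank(enum.Enum):
    CHOICE_1 = 1
    CHOICE_2 = 2


class AidName(enum.Enum):
    AID1 = "AID-1"
    AID2 = "AID-2"
    AID3 = "AID-3"


class Agreement(enum.Enum):
    FULL = "FULL"
    PARTIAL = "PARTIAL"
    DISCORDANT = "DISCORDANT"
    SINGLE = "SINGLE"


@dataclass(frozen=True)
class Band:
    """One decision-table row: a half-open/closed interval and two choices."""

    lower: float
    upper: float
    lower_closed: bool
    upper_closed: bool
    label: str
    choice1: Regimen
    choice2: Regimen
    rationale: str

    def __post_init__(self) -> None:
        if self.choice1 is self.choice2:
            raise ConfigError("band choices must differ")

    def contains(self, value: float) -> bool:
        above = value > self.lower or (self.lower_closed and value == self.lower)
        below = value < self.upper or (self.upper_closed and value == self.upper)
        return above and below


@dataclass(frozen=True)
class AidTable:
    """An ordered, exhaustive, disjoint set of decision bands."""

    name: AidName
    index_required: IndexName
    scale: str
    bands: tuple[Band, ...]

    def __post_init__(self) -> None:
        ordered = sorted(self.bands, key=lambda b: b.lower)
        for low, high in zip(ordered, ordered[1:]):
            if low.upper != high.lower:
                raise ConfigError(
                    f"{self.name.value}: gap or overlap between bands "
                    f"{low.label!r} and {high.label!r}"
                )
            if low.upper_closed == high.lower_closed:
                raise ConfigError(
                    f"{self.name.value}: boundary {low.upper} must belong to exactly one band"
                )
        if ordered[0].lower != float("-inf") or ordered[-1].upper != float("inf"):
            raise ConfigError(f"{self.name.value}: bands must cover the whole line")

    def band_for(self, value: float) -> Band:
        for band in self.bands:
            if band.contains(value):
                return band
        raise AssertionError(f"partition violated for value {value}")  # pragma: no cover


@dataclass
class Recommendation:
    """One table's verdict for one patient."""

    aid_name: AidName
    band_label: str
    choice1: Regimen
    choice2: Regimen
    rationale: str
    index_value: float
    timing_meal: Optional[MealTag] = None
    notes: list[str] = field(default_factory=list)


@dataclass
class SequentialAgResult:
    """Outcome of the sequential HbA1c → 1,5-AG assessment."""

    regimen: Optional[Regimen]  # BASAL_TARGETING / PRANDIAL_TARGETING / None
    controlled: bool
    notes: list[str] = field(default_factory=list)


@dataclass
class ConcordanceSummary:
    """Per-patient roll-up: every index, every applicable table, agreement."""

    patient_id: str
    indices: list[IndexResult]
    per_aid: dict[AidName, Recommendation]
    n_applicable: int
    agreement: Agreement
    timing_meal: Optional[MealTag] = None
    sequential_ag: Optional[SequentialAgResult] = None
    notes: list[str] = field(default_factory=list)


class InsufficientDataError(ValidationError):
    """The profile supports no decision table at all."""


_LADDER_RATIONALE = {
    "high": "High prandial contribution implies need for rapid acting insulin",
    "mid": "Intermediate prandial contribution",
    "low": "Low prandial contribution; fasting component dominates",
}


def default_tables(config: Optional[EngineConfig] = None) -> list[AidTable]:
    """Build the three decision tables from the configured cutoffs.

    With default configuration the output reproduces the published tables
    verbatim.  Cutoffs that break the partition invariant raise
    :class:`~insulaid.config.ConfigError`.
    """
    cfg = config or EngineConfig()
    inf = float("inf")

    def ladder(name: AidName, index: IndexName, scale: str, lo: float, hi: float,
               unit_suffix: str) -> AidTable:
        return AidTable(
            name=name,
            index_required=index,
            scale=scale,
            bands=(
                Band(hi, inf, False, False, f">{hi:g}{unit_suffix}",
                     Regimen.RAPID_ACTING, Regimen.PREMIXED_50_50,
                     _LADDER_RATIONALE["high"]),
                Band(lo, hi, True, True, f"{lo:g}-{hi:g}{unit_suffix}",
                     Regimen.PREMIXED_30_70, Regimen.PREMIXED_50_50,
                     _LADDER_RATIONALE["mid"]),
                Band(-inf, lo, False, False, f"<{lo:g}{unit_suffix}",
                     Regimen.BASAL, Regimen.PREMIXED_30_70,
                     _LADDER_RATIONALE["low"]),
            ),
        )

    aid1 = ladder(AidName.AID1, IndexName.PPGE, "mg/dl",
                  cfg.aid1_lower, cfg.aid1_upper, " mg%")
    aid2 = ladder(AidName.AID2, IndexName.PFI, "dimensionless",
                  cfg.aid2_lower, cfg.aid2_upper, "")

    cutoff = (
        cfg.aid3_cutoff_mmol if cfg.aid3_scale is RatioScale.MMOL_SCALE else cfg.aid3_cutoff_mg
    )
    aid3 = AidTable(
        name=AidName.AID3,
        index_required=IndexName.FPG_HBA1C,
        scale=cfg.aid3_scale.value,
        bands=(
            Band(cutoff, inf, True, False, f">={cutoff:g}",
                 Regimen.BASAL, Regimen.PREMIXED_WITH_DINNER,
                 "Higher ratio means fasting type hyperglycemia"),
            Band(-inf, cutoff, False, False, f"<{cutoff:g}",
                 Regimen.PREMIXED, Regimen.PREMIXED_WITH_BREAKFAST,
                 "Lower ratio means postprandial type hyperglycemia"),
        ),
    )
    return [aid1, aid2, aid3]


def classify(index: IndexResult, table: AidTable) -> Recommendation:
    """Locate an index value in its table and return the banded choices.

    Values that undershoot the index's physical domain (negative excursions,
    a non-positive ratio) still classify — into the lowest band — but carry
    a data-quality note.  AID-3 classifications within ``BOUNDARY_EPS`` of
    the cutoff carry a boundary-ambiguity note.
    """
    if not index.applicable:
        raise ValidationError(
            f"cannot classify inapplicable index {index.index_name.value}: {index.reason}"
        )
    if index.index_name is not table.index_required:
        raise ValidationError(
            f"{table.name.value} requires {table.index_required.value}, got {index.index_name.value}"
        )
    if index.scale != table.scale:
        raise ValidationError(
            f"{table.name.value} scale mismatch: table {table.scale!r} vs index {index.scale!r}"
        )
    value = index.value
    band = table.band_for(value)
    rec = Recommendation(
        aid_name=table.name,
        band_label=band.label,
        choice1=band.choice1,
        choice2=band.choice2,
        rationale=band.rationale,
        index_value=value,
        notes=list(index.notes),
    )
    if table.name in (AidName.AID1, AidName.AID2) and value < 0:
        rec.notes.append("data-quality warning: negative excursion classified into lowest band")
    if table.name is AidName.AID3:
        if value <= 0:
            rec.notes.append("data-quality warning: non-positive ratio")
        cutoff = table.bands[0].lower
        if abs(value - cutoff) <= BOUNDARY_EPS:
            rec.notes.append(
                f"boundary ambiguity: ratio equals the {cutoff:g} cutoff; "
                "assigned to the fasting-type (basal) row by policy"
            )
    return rec


def sequential_ag_assessment(
    hba1c: Optional[HbA1cValue],
    ag: Optional[AnhydroglucitolValue],
    a1c_target: float,
    a1c_controlled_range: tuple[float, float] = (6.5, 8.0),
    ag_low_threshold: float = 10.0,
) -> SequentialAgResult:
    """Sequential HbA1c → 1,5-AG assessment of the prandial contribution.

    HbA1c first screens for patients above target; 1,5-AG then separates
    those whose elevation is basal (AG normal: excursions are not high, so
    basal-targeting therapy is more useful) from those with postprandial
    elevations (AG low: prefer a prandial component, typically a 50:50
    biphasic over 30:70/25:75).  At or below target, no change is advised.
    """
    if hba1c is None:
        raise ValidationError("sequential assessment requires HbA1c")
    if ag is None:
        raise ValidationError("sequential assessment requires a 1,5-AG value")
    notes: list[str] = []
    lo, hi = a1c_controlled_range
    if lo <= hba1c.percent <= hi:
        notes.append(
            f"HbA1c {hba1c.percent:g}% is in the moderately/well-controlled window "
            f"({lo:g}-{hi:g}%) where the sequential assay strategy is described"
        )
    if hba1c.percent <= a1c_target:
        notes.append(f"HbA1c {hba1c.percent:g}% at or below target {a1c_target:g}%: no change advised")
        return SequentialAgResult(regimen=None, controlled=True, notes=notes)
    if ag.value >= ag_low_threshold:
        notes.append("1,5-AG normal: postprandial excursions not high; target basal glucose")
        return SequentialAgResult(regimen=Regimen.BASAL_TARGETING, controlled=False, notes=notes)
    notes.append(
        "1,5-AG low: postprandial glucose elevations; prefer a prandial component "
        "(50:50 biphasic over 30:70 or 25:75)"
    )
    return SequentialAgResult(regimen=Regimen.PRANDIAL_TARGETING, controlled=False, notes=notes)


def timing_recommendation(profile: GlycemicProfile) -> Optional[MealTag]:
    """Meal whose postprandial peak is highest: once-daily premixed insulin
    (or the bolus of a basal-plus regime) accompanies that meal.

    Ties break by day order (breakfast first); None without readings.
    """
    if not profile.ppg_readings:
        return None
    per_meal = select_reference_ppg(profile, PpgPolicy.PER_MEAL)
    return min(per_meal, key=lambda meal: (-per_meal[meal].value, meal))


def _label_agreement(recs: dict[AidName, Recommendation]) -> Agreement:
    """FULL: all choice-1 regimens identical.  SINGLE: one applicable table.
    PARTIAL: a strict subset shares choice 1, or some table's choice 2
    matches another's choice 1.  DISCORDANT otherwise.  (The label is an
    artifact of this engine, not a validated clinical category.)
    """
    if len(recs) == 1:
        return Agreement.SINGLE
    choice1 = [r.choice1 for r in recs.values()]
    if len(set(choice1)) == 1:
        return Agreement.FULL
    if len(choice1) != len(set(choice1)):
        return Agreement.PARTIAL
    for a in recs.values():
        for b in recs.values():
            if a is not b and a.choice2 is b.choice1:
                return Agreement.PARTIAL
    return Agreement.DISCORDANT


def _adapt_scale(result: IndexResult, table: AidTable, cfg: EngineConfig) -> IndexResult:
    """Re-express a glucose-denominated index in the table's unit.

    The PPGE table is denominated in mg%; a profile assessed with a mmol/l
    working unit yields a mmol/l excursion, which converts linearly.
    Non-glucose scale mismatches are left for :func:`classify` to reject.
    """
    glucose_scales = {"mg/dl", "mmol/l"}
    if result.scale == table.scale or not (
        result.scale in glucose_scales and table.scale in glucose_scales
    ):
        return result
    factor = cfg.mg_per_mmol if result.scale == "mmol/l" else 1.0 / cfg.mg_per_mmol
    return IndexResult(
        index_name=result.index_name,
        value=result.value * factor,
        scale=table.scale,
        inputs_used=dict(result.inputs_used),
        applicable=True,
        notes=list(result.notes),
    )


def assess(profile: GlycemicProfile, config: Optional[EngineConfig] = None) -> ConcordanceSummary:
    """Run every applicable decision aid on one patient.

    Computes all indices, classifies through each applicable table,
    attaches the injection-timing meal and the sequential 1,5-AG result
    when the inputs (and required thresholds) exist, and labels cross-table
    agreement.  Raises :class:`InsufficientDataError` when no table is
    computable.
    """
    cfg = config or EngineConfig()
    indices = compute_all(profile, cfg)
    by_name = {r.index_name: r for r in indices}
    tables = {t.index_required: t for t in default_tables(cfg)}

    timing = timing_recommendation(profile)
    per_aid: dict[AidName, Recommendation] = {}
    for index_name in (IndexName.PPGE, IndexName.PFI, IndexName.FPG_HBA1C):
        result = by_name[index_name]
        if not result.applicable:
            continue
        rec = classify(_adapt_scale(result, tables[index_name], cfg), tables[index_name])
        if timing is not None and (
            rec.choice1 in _PRANDIAL_REGIMENS or rec.choice2 in _PRANDIAL_REGIMENS
        ):
            rec.timing_meal = timing
        per_aid[rec.aid_name] = rec

    if not per_aid:
        raise InsufficientDataError(
            "no decision aid is computable for patient "
            f"{profile.patient_id!r}: need FPG plus a postprandial reading "
            "(PPGE/PFI tables) or FPG plus HbA1c (FPG:HbA1c table)"
        )

    notes: list[str] = []

    # HbA1c severity context: very high values empirically prompt basal-bolus,
    # but no threshold table exists, so this never alters the AID outputs.
    if profile.hba1c is not None and profile.hba1c.percent > cfg.hba1c_severity_note:
        notes.append(
            f"HbA1c {profile.hba1c.percent:g}% exceeds {cfg.hba1c_severity_note:g}%: "
            "very high overall burden; basal-bolus regimens are often chosen "
            "empirically in this range (context only, not a table output)"
        )

    # Cross-scale FPG:HbA1c check: the mg-scale (20) and mmol-scale (1.3)
    # cutoffs are not related by exactly 18.0, so the two representations of
    # one patient can disagree; surface it, never silently resolve it.
    if profile.fpg is not None and profile.hba1c is not None:
        r_mg = fpg_hba1c_ratio(profile.fpg, profile.hba1c, RatioScale.MG_SCALE, cfg.mg_per_mmol)
        r_mmol = fpg_hba1c_ratio(profile.fpg, profile.hba1c, RatioScale.MMOL_SCALE, cfg.mg_per_mmol)
        side_mg = r_mg.value >= cfg.aid3_cutoff_mg
        side_mmol = r_mmol.value >= cfg.aid3_cutoff_mmol
        if side_mg != side_mmol:
            notes.append(
                f"FPG:HbA1c scale disagreement: mg-scale ratio {r_mg.value:.2f} vs cutoff "
                f"{cfg.aid3_cutoff_mg:g} and mmol-scale ratio {r_mmol.value:.2f} vs cutoff "
                f"{cfg.aid3_cutoff_mmol:g} fall on opposite sides; the published cutoffs are "
                "not exactly unit-consistent — review manually"
            )

    sequential: Optional[SequentialAgResult] = None
    if profile.hba1c is not None and profile.ag is not None:
        if cfg.a1c_target is None or cfg.ag_low_threshold is None:
            notes.append(
                "1,5-AG present but sequential assessment skipped: set a1c_target "
                "and ag_low_threshold in the configuration to enable it"
            )
        else:
            sequential = sequential_ag_assessment(
                profile.hba1c, profile.ag, cfg.a1c_target,
                cfg.a1c_controlled_range, cfg.ag_low_threshold,
            )

    return ConcordanceSummary(
        patient_id=profile.patient_id,
        indices=indices,
        per_aid=per_aid,
        n_applicable=len(per_aid),
        agreement=_label_agreement(per_aid),
        timing_meal=timing,
        sequential_ag=sequential,
        notes=notes,
    )
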