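"""Unit-aware glucose, HbA1c and 1,5-anhydroglucitol value types.

Glucose concentrations circulate in two unit systems in clinical practice:
mg/dl (written ``mg%`` in much of the older literature — the two are exact
synonyms) and mmol/l.  Every arithmetic operation downstream of this module
goes through :class:`GlucoseValue` so that a formula can never silently mix
the two scales.

The conversion constant is the clinical convention 18.0 mg/dl per mmol/l
(not the molar-mass value 18.016): published cutoff pairs such as
7.8 mmol/l ≈ 140 mg/dl are rounded clinical values and the convention keeps
round-trips exact.  The constant is named and overridable.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field

logger = logging.getLogger("insulaid")

#: Clinical conversion convention: glucose mg/dl = mmol/l x 18.0.
MG_PER_MMOL: float = 18.0

#: Sanity window for glucose concentrations, in mg/dl.  Values outside it
#: are logged as suspicious but never rejected: the engine must not refuse
#: plausible extreme hyperglycemia.
GLUCOSE_SANITY_RANGE_MG_DL: tuple[float, float] = (20.0, 1000.0)


class ValidationError(ValueError):
    """A physiologically or numerically invalid input value."""


class Unit(enum.Enum):
    """Glucose concentration unit.  ``mg%`` is an alias of mg/dl."""

    MG_DL = "mg/dl"
    MMOL_L = "mmol/l"

    @classmethod
    def parse(cls, text: str) -> "Unit":
        """Parse a case-insensitive unit string (``mg/dl``, ``mg%``, ``mmol/l``)."""
        key = text.strip().lower()
        aliases = {
            "mg/dl": cls.MG_DL,
            "mg/dl.": cls.MG_DL,
            "mg%": cls.MG_DL,
            "mgdl": cls.MG_DL,
            "mmol/l": cls.MMOL_L,
            "mmoll": cls.MMOL_L,
            "mmol": cls.MMOL_L,
        }
        try:
            return aliases[key]
        except KeyError:
            raise ValidationError(f"unknown glucose unit: {text!r}") from None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def _require_finite_nonneg(value: float, what: str) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValidationError(f"{what} must be finite, got {value!r}")
    if value < 0:
        raise ValidationError(f"{what} must be non-negative, got {value!r}")
    return value


@dataclass(frozen=True)
class GlucoseValue:
    """A glucose concentration with an explicit unit.

    Parameters
    ----------
    value
        Non-negative, finite concentration.
    unit
        :class:`Unit` member (default mg/dl).
    """

    value: float
    unit: Unit = Unit.MG_DL

    def __post_init__(self) -> None:
        object.__setattr__(self, "value", _require_finite_nonneg(self.value, "glucose"))
        if not isinstance(self.unit, Unit):
            object.__setattr__(self, "unit", Unit.parse(str(self.unit)))
        lo, hi = GLUCOSE_SANITY_RANGE_MG_DL
        as_mg = self.value if self.unit is Unit.MG_DL else self.value * MG_PER_MMOL
        if self.value > 0 and not (lo <= as_mg <= hi):
            logger.warning(
                "glucose value %.6g %s is outside the sanity range %g-%g mg/dl",
                self.value, self.unit.value, lo, hi,
            )

    def to(self, target_unit: Unit, mg_per_mmol: float = MG_PER_MMOL) -> "GlucoseValue":
        return convert_glucose(self, target_unit, mg_per_mmol=mg_per_mmol)

    def as_mg_dl(self, mg_per_mmol: float = MG_PER_MMOL) -> float:
        return self.to(Unit.MG_DL, mg_per_mmol).value

    def as_mmol_l(self, mg_per_mmol: float = MG_PER_MMOL) -> float:
        return self.to(Unit.MMOL_L, mg_per_mmol).value


def convert_glucose(
    g: GlucoseValue, target_unit: Unit, mg_per_mmol: float = MG_PER_MMOL
) -> GlucoseValue:
    """Express ``g`` in ``target_unit``.

    Conversion is linear through a single constant; converting to the unit
    the value already carries is the identity (the same object's value is
    returned unchanged, so round-trips are exact for same-unit hops and
    within floating-point rounding otherwise).
    """
    if not isinstance(target_unit, Unit):
        target_unit = Unit.parse(str(target_unit))
    if g.unit is target_unit:
        return g
    if g.unit is Unit.MG_DL and target_unit is Unit.MMOL_L:
        return GlucoseValue(g.value / mg_per_mmol, Unit.MMOL_L)
    return GlucoseValue(g.value * mg_per_mmol, Unit.MG_DL)


@dataclass(frozen=True)
class HbA1cValue:
    """Glycated hemoglobin as an NGSP percentage (e.g. 6.3).

    Values must lie in (0, 25)%: anything outside is a data error, not a
    plausible assay result.
    """

    percent: float

    def __post_init__(self) -> None:
        p = float(self.percent)
        if not math.isfinite(p) or not (0.0 < p < 25.0):
            raise ValidationError(f"HbA1c percent out of range (0, 25): {self.percent!r}")
        object.__setattr__(self, "percent", p)


@dataclass(frozen=True)
class AnhydroglucitolValue:
    """Serum 1,5-anhydroglucitol concentration.

    1,5-AG falls as glycemia exceeds the renal glucose threshold, so low
    values flag recent postprandial excursions.  The unit is a fixed label
    (conventionally ug/ml); no conversion is defined.
    """

    value: float
    unit: str = "ug/ml"
    _notes: tuple = field(default=(), repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "value", _require_finite_nonneg(self.value, "1,5-AG"))
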