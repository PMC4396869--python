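"""Seeded synthetic cohorts for the three hyperglycemia phenotypes.

Clinicians encounter a spectrum of "hyperglycemia personalities":
predominant fasting hyperglycemia, predominant postprandial
hyperglycemia, and overall (mixed) hyperglycemia.  This module generates
patient profiles under parameterised versions of those three phenotypes
so every decision path can be exercised without any external dataset.

The generative model is deliberately transparent, not physiological:

* FPG ~ truncated normal (resampled until positive), mg/dl;
* each meal's PPG = FPG + an independent truncated-normal excursion;
* HbA1c is linked linearly to FPG with Gaussian noise (the link
  coefficients are synthetic — no joint FPG/HbA1c distribution has been
  published for these phenotypes);
* 1,5-AG ~ truncated normal around a phenotype-typical level (low in the
  postprandial phenotype, normal in the fasting phenotype).

Identical spec + seed reproduce a byte-identical cohort.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import EngineConfig
from .decision import Agreement, AidName, assess
from .indices import GlycemicProfile, MealTag, PpgReading
from .units import AnhydroglucitolValue, GlucoseValue, HbA1cValue, Unit, ValidationError


class Phenotype(enum.Enum):
    FASTING_TYPE = "fasting"
    POSTPRANDIAL_TYPE = "postprandial"
    OVERALL = "overall"

    @classmethod
    def parse(cls, text: str) -> "Phenotype":
        key = text.strip().lower()
        for member in cls:
            if key in (member.value, member.name.lower()):
                return member
        raise ValidationError(f"unknown phenotype: {text!r}")


#: Default generative parameters per phenotype:
#: (fpg_mean, fpg_sd, excursion_mean, excursion_sd, hba1c_mean, ag_mean, ag_sd)
_DEFAULTS = {
    Phenotype.FASTING_TYPE: (200.0, 20.0, 25.0, 10.0, 9.0, 12.0, 2.0),
    Phenotype.POSTPRANDIAL_TYPE: (115.0, 10.0, 110.0, 25.0, 7.8, 4.0, 1.5),
    Phenotype.OVERALL: (180.0, 20.0, 80.0, 20.0, 9.5, 6.0, 2.0),
}

_MEALS = (MealTag.BREAKFAST, MealTag.LUNCH, MealTag.DINNER)


@dataclass(frozen=True)
class PhenotypeSpec:
    """Generative parameters for one synthetic phenotype cohort.

    Means and standard deviations are in mg/dl for glucose quantities and
    NGSP % for HbA1c.  ``per_meal_excursion`` optionally overrides the
    common excursion (mean, sd) per meal.  ``include_hba1c`` and
    ``include_ag`` are inclusion probabilities in [0, 1].
    """

    phenotype: Phenotype
    fpg_mean: float
    fpg_sd: float
    excursion_mean: float
    excursion_sd: float
    hba1c_mean: float
    hba1c_sd: float = 0.4
    #: Synthetic HbA1c–FPG link slope, % per mg/dl.
    hba1c_fpg_slope: float = 0.02
    ag_mean: float = 8.0
    ag_sd: float = 2.0
    include_hba1c: float = 1.0
    include_ag: float = 0.25
    per_meal_excursion: Optional[dict[MealTag, tuple[float, float]]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fpg_sd", "excursion_sd", "hba1c_sd", "ag_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.fpg_mean <= 0:
            raise ValidationError("fpg_mean must be positive")
        for name in ("include_hba1c", "include_ag"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValidationError(f"{name} must be a probability in [0, 1]")

    @classmethod
    def default(cls, phenotype: Phenotype, seed: int = 0, **overrides) -> "PhenotypeSpec":
        """The stock parameterisation of a phenotype (see module docstring)."""
        fpg_m, fpg_s, exc_m, exc_s, a1c_m, ag_m, ag_s = _DEFAULTS[phenotype]
        spec = cls(
            phenotype=phenotype,
            fpg_mean=fpg_m, fpg_sd=fpg_s,
            excursion_mean=exc_m, excursion_sd=exc_s,
            hba1c_mean=a1c_m,
            ag_mean=ag_m, ag_sd=ag_s,
            seed=seed,
        )
        return replace(spec, **overrides) if overrides else spec


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, low: float) -> float:
    """One normal draw resampled until strictly above ``low``."""
    if sd == 0:
        if mean <= low:
            raise ValidationError(f"degenerate draw: constant {mean} not above {low}")
        return mean
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > low:
            return x
    raise ValidationError(f"truncated-normal resampling failed for N({mean}, {sd}) > {low}")


def generate_cohort(spec: PhenotypeSpec, n: int) -> list[GlycemicProfile]:
    """Draw ``n`` patient profiles from a phenotype spec.

    Deterministic: the same spec (including its seed) always produces the
    identical cohort.  All glucose values are in mg/dl.
    """
    if n < 1:
        raise ValidationError("cohort size must be >= 1")
    rng = np.random.default_rng(spec.seed)
    profiles: list[GlycemicProfile] = []
    for i in range(n):
        fpg = _trunc_normal(rng, spec.fpg_mean, spec.fpg_sd, 0.0)
        readings = []
        for meal in _MEALS:
            exc_m, exc_s = (
                spec.per_meal_excursion.get(meal, (spec.excursion_mean, spec.excursion_sd))
                if spec.per_meal_excursion
                else (spec.excursion_mean, spec.excursion_sd)
            )
            excursion = rng.normal(exc_m, exc_s)
            ppg = max(fpg + excursion, 1.0)  # glucose stays positive
            readings.append(PpgReading(meal, GlucoseValue(ppg, Unit.MG_DL), hours_post_meal=1.5))
        hba1c = None
        if rng.random() < spec.include_hba1c:
            pct = spec.hba1c_mean + spec.hba1c_fpg_slope * (fpg - spec.fpg_mean) + rng.normal(
                0.0, spec.hba1c_sd
            )
            hba1c = HbA1cValue(float(np.clip(pct, 3.5, 20.0)))
        ag = None
        if rng.random() < spec.include_ag:
            ag = AnhydroglucitolValue(_trunc_normal(rng, spec.ag_mean, spec.ag_sd, 0.0))
        profiles.append(
            GlycemicProfile(
                patient_id=f"{spec.phenotype.value}-{i:04d}",
                fpg=GlucoseValue(fpg, Unit.MG_DL),
                ppg_readings=readings,
                hba1c=hba1c,
                ag=ag,
            )
        )
    return profiles


@dataclass
class ConcordanceStudy:
    """Aggregate decision behaviour of one or more synthetic cohorts.

    ``band_frequencies`` — per phenotype and decision aid, the fraction of
    patients whose first-choice regimen fell in each band (fractions sum
    to 1 within each phenotype x aid group).
    ``agreement_rates`` — per phenotype, the FULL/PARTIAL/DISCORDANT/SINGLE
    fractions.
    """

    band_frequencies: pd.DataFrame
    agreement_rates: pd.DataFrame
    n_per_phenotype: dict[str, int] = field(default_factory=dict)


def concordance_study(
    specs: Sequence[PhenotypeSpec], n: int, config: Optional[EngineConfig] = None
) -> ConcordanceStudy:
    """Assess ``n`` synthetic patients per spec and tabulate the outcomes.

    Quantifies how often the decision aids agree within each phenotype —
    single indices viewed in isolation can mislead, and this table shows
    where the tables pull in different directions.
    """
    if not specs:
        raise ValidationError("at least one phenotype spec is required")
    cfg = config or EngineConfig()
    band_rows, agree_rows, counts = [], [], {}
    for spec in specs:
        cohort = generate_cohort(spec, n)
        counts[spec.phenotype.value] = len(cohort)
        band_counts: dict[tuple[str, str], int] = {}
        aid_totals: dict[str, int] = {}
        agree_counts: dict[str, int] = {a.value: 0 for a in Agreement}
        for profile in cohort:
            summary = assess(profile, cfg)
            agree_counts[summary.agreement.value] += 1
            for aid, rec in summary.per_aid.items():
                key = (aid.value, rec.choice1.value)
                band_counts[key] = band_counts.get(key, 0) + 1
                aid_totals[aid.value] = aid_totals.get(aid.value, 0) + 1
        for (aid, regimen), count in sorted(band_counts.items()):
            band_rows.append(
                {
                    "phenotype": spec.phenotype.value,
                    "aid": aid,
                    "choice1": regimen,
                    "frequency": count / aid_totals[aid],
                }
            )
        for label, count in agree_counts.items():
            agree_rows.append(
                {
                    "phenotype": spec.phenotype.value,
                    "agreement": label,
                    "rate": count / len(cohort),
                }
            )
    return ConcordanceStudy(
        band_frequencies=pd.DataFrame(band_rows),
        agreement_rates=pd.DataFrame(agree_rows),
        n_per_phenotype=counts,
    )
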