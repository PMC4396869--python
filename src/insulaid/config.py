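"""Engine configuration: working units, decision cutoffs, policies.

Defaults reproduce the published decision tables exactly (PPGE bands at
40/74 mg%, PFI bands at 0.4/0.6, FPG:HbA1c cutoff 20 on the mg% scale or
1.3 on the mmol scale).  Every cutoff is data, not code: load alternative
values from a YAML or JSON file with :meth:`EngineConfig.from_file`.

Two sequential-assessment thresholds deliberately have **no default**: the
HbA1c treatment target and the 1,5-AG "low" threshold are practice
decisions with no published consensus value, so they must be supplied
explicitly before the sequential A1C→1,5-AG logic runs.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Optional

import yaml

from .indices import PpgPolicy, RatioScale
from .units import MG_PER_MMOL, Unit


class ConfigError(ValueError):
    """An invalid or inconsistent configuration."""


class Aggregation(enum.Enum):
    """How repeated measurements of the same type are collapsed."""

    MEAN = "mean"
    LATEST = "latest"


@dataclass(frozen=True)
class EngineConfig:
    #: Unit every glucose value is normalized to before index computation.
    working_unit: Unit = Unit.MG_DL
    #: Glucose conversion constant, mg/dl per mmol/l.
    mg_per_mmol: float = MG_PER_MMOL
    #: Reference-PPG selection; MAX_PEAK follows the peak-based rule.
    ppg_policy: PpgPolicy = PpgPolicy.MAX_PEAK
    #: Collapse rule for repeated same-type records in cohort CSVs.
    aggregation: Aggregation = Aggregation.MEAN

    #: PPGE decision-table cutoffs, mg% (prediabetes- and diabetes-derived).
    aid1_lower: float = 40.0
    aid1_upper: float = 74.0
    #: PFI decision-table cutoffs, dimensionless.
    aid2_lower: float = 0.4
    aid2_upper: float = 0.6
    #: Scale used for the FPG:HbA1c decision table.
    aid3_scale: RatioScale = RatioScale.MG_SCALE
    #: FPG:HbA1c cutoff on the mmol/l scale (7.8 mmol/l / 6.0%).
    aid3_cutoff_mmol: float = 1.3
    #: FPG:HbA1c cutoff on the mg% scale (126 mg% / 6.3%).
    aid3_cutoff_mg: float = 20.0

    #: HbA1c treatment target (%); required for the sequential assessment.
    a1c_target: Optional[float] = None
    #: HbA1c window in which the sequential assay strategy is described
    #: (moderately or well controlled patients).
    a1c_controlled_range: tuple[float, float] = (6.5, 8.0)
    #: 1,5-AG below this is "low"; required for the sequential assessment.
    ag_low_threshold: Optional[float] = None

    #: HbA1c above this adds a free-text severity note to reports (never
    #: alters any decision-table output).
    hba1c_severity_note: float = 10.0

    def __post_init__(self) -> None:
        if not self.aid1_lower < self.aid1_upper:
            raise ConfigError("aid1 cutoffs must satisfy lower < upper")
        if not self.aid2_lower < self.aid2_upper:
            raise ConfigError("aid2 cutoffs must satisfy lower < upper")
        if self.aid3_cutoff_mmol <= 0 or self.aid3_cutoff_mg <= 0:
            raise ConfigError("aid3 cutoffs must be positive")
        if self.mg_per_mmol <= 0:
            raise ConfigError("mg_per_mmol must be positive")
        lo, hi = self.a1c_controlled_range
        if not lo < hi:
            raise ConfigError("a1c_controlled_range must be (low, high) with low < high")

    # -- (de)serialization ---------------------------------------------------

    _ENUM_FIELDS = {
        "working_unit": Unit.parse,
        "ppg_policy": lambda s: PpgPolicy(str(s).lower()),
        "aggregation": lambda s: Aggregation(str(s).lower()),
        "aid3_scale": lambda s: RatioScale[str(s).upper()],
    }

    @classmethod
    def from_dict(cls, data: dict) -> "EngineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for key, raw in data.items():
            if key in cls._ENUM_FIELDS and isinstance(raw, str):
                try:
                    kwargs[key] = cls._ENUM_FIELDS[key](raw)
                except (KeyError, ValueError) as exc:
                    raise ConfigError(f"bad value for {key}: {raw!r}") from exc
            elif key == "a1c_controlled_range":
                kwargs[key] = tuple(float(v) for v in raw)
            else:
                kwargs[key] = raw
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "EngineConfig":
        """Load overrides from a YAML or JSON file; unset keys keep defaults."""
        path = Path(path)
        text = path.read_text()
        try:
            data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        except (json.JSONDecodeError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot parse config file {path}: {exc}") from exc
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, enum.Enum):
                v = v.name.lower() if f.name == "aid3_scale" else v.value
            elif isinstance(v, tuple):
                v = list(v)
            out[f.name] = v
        return out

    def with_overrides(self, **kwargs) -> "EngineConfig":
        return replace(self, **kwargs)
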