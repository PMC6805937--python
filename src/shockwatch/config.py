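"""Feature dictionary, clinical plausibility ranges, and run configuration.

The model's input variables follow the vitals, labs and demographics named
by the Sepsis-2-era screening criteria (SIRS, organ dysfunction, fluid
resuscitation) plus common ICU context measurements, about 30 features in
total.  The clinical ranges shipped here are plausibility bounds used to
discard physiologically impossible recordings; they are configuration, not
ground truth, and can be overridden from a YAML file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import yaml


@dataclass(frozen=True)
class FeatureSpec:
    """One model feature: unit, plausibility bounds, and kind.

    ``kind`` is one of ``vital`` (charted roughly hourly), ``lab`` (drawn
    every few hours), ``event`` (raw timestamped records such as fluid
    boluses, consumed by window derivation rather than the grid), ``derived``
    (trailing-window quantities computed from events), ``static``
    (per-admission constants broadcast over hours) or ``flag`` (binary).
    """

    name: str
    unit: str
    lower: float
    upper: float
    is_binary: bool = False
    kind: str = "vital"

    def in_range(self, value: float) -> bool:
        return self.lower <= value <= self.upper


def _f(name, unit, lower, upper, kind="vital", is_binary=False) -> FeatureSpec:
    return FeatureSpec(name, unit, lower, upper, is_binary, kind)


#: Default feature dictionary.  Bounds are inclusive: a value exactly at a
#: bound is retained by the outlier filter.
DEFAULT_FEATURES: tuple[FeatureSpec, ...] = (
    # vitals
    _f("heart_rate", "beats/min", 20, 300),
    _f("sbp", "mmHg", 30, 300),
    _f("dbp", "mmHg", 10, 200),
    _f("map", "mmHg", 20, 250),
    _f("respiratory_rate", "breaths/min", 2, 80),
    _f("temperature", "degC", 25, 45),
    _f("spo2", "%", 40, 100),
    _f("gcs", "points", 3, 15),
    # labs
    _f("wbc", "cells/uL", 100, 200_000, kind="lab"),
    _f("lactate", "mmol/L", 0.1, 30, kind="lab"),
    _f("creatinine", "mg/dL", 0.1, 30, kind="lab"),
    _f("bilirubin", "mg/dL", 0.05, 60, kind="lab"),
    _f("platelets", "count/uL", 1_000, 2_000_000, kind="lab"),
    _f("inr", "ratio", 0.2, 20, kind="lab"),
    _f("paco2", "mmHg", 5, 150, kind="lab"),
    _f("pao2", "mmHg", 20, 700, kind="lab"),
    _f("pao2_fio2", "mmHg", 20, 700, kind="lab"),
    _f("bun", "mg/dL", 1, 250, kind="lab"),
    _f("glucose", "mg/dL", 10, 2_000, kind="lab"),
    _f("sodium", "mmol/L", 100, 185, kind="lab"),
    _f("potassium", "mmol/L", 1.0, 12, kind="lab"),
    _f("bicarbonate", "mmol/L", 2, 60, kind="lab"),
    _f("hemoglobin", "g/dL", 2, 25, kind="lab"),
    _f("ph", "pH", 6.5, 8.0, kind="lab"),
    # raw event streams (not grid columns; consumed by window derivation)
    _f("fluid_bolus", "mL", 0, 10_000, kind="event"),
    _f("urine_output", "mL", 0, 4_000, kind="event"),
    # trailing-window quantities derived from the event streams
    _f("fluids_24h", "mL", 0, 100_000, kind="derived"),
    _f("fluids_total", "mL", 0, 1_000_000, kind="derived"),
    _f("urine_output_2h", "mL/kg", 0, 100, kind="derived"),
    # per-admission statics
    _f("age", "years", 0, 130, kind="static"),
    _f("weight", "kg", 20, 350, kind="static"),
    # chronic-condition flags (ICD-9 derived in real extracts)
    _f("flag_chronic_renal", "bool", 0, 1, is_binary=True, kind="flag"),
    _f("flag_chronic_liver", "bool", 0, 1, is_binary=True, kind="flag"),
    _f("flag_pneumonia", "bool", 0, 1, is_binary=True, kind="flag"),
)


class ClinicalRangeTable:
    """Lookup of :class:`FeatureSpec` by name with schema validation."""

    def __init__(self, features: Iterable[FeatureSpec] = DEFAULT_FEATURES):
        self._by_name: dict[str, FeatureSpec] = {}
        for spec in features:
            if spec.name in self._by_name:
                raise ValueError(f"duplicate feature {spec.name!r}")
            if not spec.is_binary and not spec.lower < spec.upper:
                raise ValueError(
                    f"feature {spec.name!r}: lower bound must be < upper bound"
                )
            self._by_name[spec.name] = spec

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> FeatureSpec:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(
                f"feature {name!r} has no clinical-range entry; add it to the "
                "range table configuration"
            ) from None

    def __iter__(self):
        return iter(self._by_name.values())

    def __len__(self) -> int:
        return len(self._by_name)

    @property
    def names(self) -> list[str]:
        return list(self._by_name)

    def grid_features(self) -> list[str]:
        """Features that form columns of the hourly grid (model inputs)."""
        return [s.name for s in self if s.kind in
                ("vital", "lab", "derived", "static", "flag")]

    def binary_features(self) -> list[str]:
        return [s.name for s in self if s.is_binary]

    def event_features(self) -> list[str]:
        return [s.name for s in self if s.kind == "event"]

    # -- serialisation --------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        rows = [
            {"name": s.name, "unit": s.unit, "lower": s.lower,
             "upper": s.upper, "is_binary": s.is_binary, "kind": s.kind}
            for s in self
        ]
        Path(path).write_text(yaml.safe_dump({"features": rows}, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ClinicalRangeTable":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(FeatureSpec(**row) for row in doc["features"])


def default_ranges() -> ClinicalRangeTable:
    return ClinicalRangeTable(DEFAULT_FEATURES)


@dataclass
class EvalConfig:
    """Evaluation-protocol settings: six-fold CV with a 5% validation
    holdout, percentile-bootstrap CIs over fold metrics, and an alarm
    threshold chosen on validation data at a target sensitivity."""

    k_folds: int = 6
    val_frac: float = 0.05
    n_boot: int = 1000
    ci_level: float = 0.95
    target_sensitivity: float = 0.85
    preonset_window: int = 48
    stratify_tolerance: float = 0.05  # max |fold − global| positive fraction

    def __post_init__(self):
        if not 0 < self.val_frac < 1:
            raise ValueError("val_frac must be in (0, 1)")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")


def derive_seed(seed: int, stream: str) -> int:
    """Stable named substream below 2**31, so every stochastic component
    (generator, folds, training, bootstrap) is independently reproducible
    from one global seed."""
    import zlib

    return (seed * 1_000_003 + zlib.crc32(stream.encode())) % (2**31 - 1)
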