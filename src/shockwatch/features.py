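"""Event-table to model-ready hourly grid: filtering, binning, imputation,
standardization.

The raw input is a long-format event table with columns
``admission_id, feature, time_hours, value``.  The pipeline

1. drops admissions younger than 15 years at admission (pediatric sepsis
   definitions differ);
2. removes events outside the clinical plausibility range for their
   feature (bounds inclusive: boundary values are retained);
3. bins events to the closest whole hour after admission (ties at .5 round
   half up), averaging multiple events that land in one bin;
4. imputes missing hours by zero-order hold (the most recent observed
   value within the same admission), then fills hours before a feature's
   first observation with the population mean;
5. standardizes non-binary features to (x − x̄)/s, where x̄ and s are the
   population mean and standard deviation computed over *observed* values
   of a stated admission set (training folds only, to avoid leakage).

Trailing-window quantities (fluids over 24 h, cumulative fluids, urine
output per kg over 2 h) are derived from raw event times *before* binning,
because their window semantics are physical rather than grid artifacts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .config import ClinicalRangeTable, default_ranges
from .labeling import AdmissionMeta

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ["admission_id", "feature", "time_hours", "value"]


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table lacks columns {missing}")
    if len(events) and (events["time_hours"] < 0).any():
        bad = events.loc[events["time_hours"] < 0].iloc[0]
        raise ValueError(
            f"negative event time {bad['time_hours']} for admission "
            f"{bad['admission_id']}"
        )
    return events


@dataclass
class HourlyGrid:
    """Hours-by-features matrix for one admission plus an observation mask.

    ``values`` is indexed by hour since admission (0..L−1).  ``mask`` is
    True where the value came from a raw event in that hour bin; derived,
    static and flag columns are marked observed everywhere.  Before
    imputation, unobserved cells are NaN.
    """

    admission_id: str
    values: pd.DataFrame
    mask: pd.DataFrame

    def __post_init__(self):
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")

    @property
    def n_hours(self) -> int:
        return len(self.values)

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)

    def copy(self) -> "HourlyGrid":
        return HourlyGrid(self.admission_id, self.values.copy(), self.mask.copy())

    def is_dense(self) -> bool:
        return bool(np.isfinite(self.values.to_numpy(dtype=float)).all())

    def to_csv(self, path: str | Path, mask_path: str | Path | None = None) -> None:
        self.values.rename_axis("hour").to_csv(path)
        if mask_path is not None:
            self.mask.rename_axis("hour").to_csv(mask_path)


@dataclass
class PopulationStats:
    """Per-feature mean and sample SD over observed values of a stated
    admission set (recorded in ``scope`` for provenance)."""

    mean: pd.Series
    std: pd.Series
    scope: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "std": self.std})


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_age(
    events: pd.DataFrame,
    metas: Sequence[AdmissionMeta],
    min_age: float = 15.0,
) -> tuple[pd.DataFrame, list[AdmissionMeta]]:
    """Retain admissions with age >= ``min_age`` years at admission."""
    for m in metas:
        if m.age is None or not math.isfinite(m.age):
            raise ValueError(f"{m.admission_id}: age missing")
    kept = [m for m in metas if m.age >= min_age]
    removed = len(metas) - len(kept)
    if removed:
        logger.info("filter_age: removed %d admission(s) under %g y",
                    removed, min_age)
    keep_ids = {m.admission_id for m in kept}
    return events[events["admission_id"].isin(keep_ids)].copy(), kept


def remove_outliers(
    events: pd.DataFrame, ranges: ClinicalRangeTable
) -> pd.DataFrame:
    """Drop events outside their feature's clinical range (bounds inclusive)."""
    validate_events(events)
    if len(events) == 0:
        return events.copy()
    unknown = set(events["feature"]) - set(ranges.names)
    if unknown:
        raise KeyError(
            f"features without a clinical-range entry: {sorted(unknown)}"
        )
    lower = events["feature"].map({s.name: s.lower for s in ranges})
    upper = events["feature"].map({s.name: s.upper for s in ranges})
    ok = (events["value"] >= lower) & (events["value"] <= upper)
    dropped = events.loc[~ok]
    if len(dropped):
        per_feat = dropped.groupby("feature").size()
        logger.info("remove_outliers: dropped %d event(s): %s",
                    len(dropped), per_feat.to_dict())
    return events.loc[ok].copy()


# ---------------------------------------------------------------------------
# binning and window derivation
# ---------------------------------------------------------------------------

def nearest_hour(t: np.ndarray | float) -> np.ndarray | int:
    """Closest whole hour; ties at .5 round half up (2.5 h → hour 3)."""
    return np.floor(np.asarray(t, dtype=float) + 0.5).astype(int)


def bin_hourly(
    events: pd.DataFrame,
    stay_length: int,
    ranges: Optional[ClinicalRangeTable] = None,
) -> HourlyGrid:
    """Bin one admission's events to an hours-by-features grid.

    Multiple events of a feature in one bin are averaged.  Only charted
    features (vitals and labs) become grid columns; raw event streams such
    as fluid boluses are consumed by :func:`derive_trailing_windows`.
    Events rounding past the last hour are assigned to it.
    """
    validate_events(events)
    ranges = ranges or default_ranges()
    ids = events["admission_id"].unique()
    if len(ids) > 1:
        raise ValueError(f"bin_hourly expects one admission, got {len(ids)}")
    admission_id = str(ids[0]) if len(ids) else "empty"
    columns = [s.name for s in ranges if s.kind in ("vital", "lab")]
    index = pd.RangeIndex(stay_length)
    charted = events[events["feature"].isin(columns)]
    hours = np.clip(nearest_hour(charted["time_hours"]), 0, stay_length - 1)
    agg = (
        charted.assign(hour=hours)
        .groupby(["hour", "feature"])["value"]
        .mean()
        .unstack()
    )
    values = agg.reindex(index=index, columns=columns)
    mask = values.notna()
    return HourlyGrid(admission_id, values.astype(float), mask)


def derive_trailing_windows(
    events: pd.DataFrame, stay_length: int, weight: float
) -> pd.DataFrame:
    """Per-hour fluid and urine window quantities from raw event times.

    For hour ``h``: ``fluids_24h`` sums boluses in ``(h−24, h]`` mL;
    ``fluids_total`` sums boluses in ``[0, h]``; ``urine_output_2h`` sums
    urine volumes in ``(h−2, h]`` divided by body weight (mL/kg).
    """
    if weight <= 0:
        raise ValueError("weight must be positive")
    hours = np.arange(stay_length)
    out = pd.DataFrame(
        0.0, index=pd.RangeIndex(stay_length),
        columns=["fluids_24h", "fluids_total", "urine_output_2h"],
    )
    for feat, cols in (("fluid_bolus", ("fluids_24h", "fluids_total")),
                       ("urine_output", ("urine_output_2h",))):
        ev = events[events["feature"] == feat]
        t = ev["time_hours"].to_numpy(dtype=float)
        v = ev["value"].to_numpy(dtype=float)
        for h in hours:
            in_past = t <= h
            if feat == "fluid_bolus":
                out.loc[h, "fluids_total"] = v[in_past].sum()
                out.loc[h, "fluids_24h"] = v[in_past & (t > h - 24)].sum()
            else:
                out.loc[h, "urine_output_2h"] = v[in_past & (t > h - 2)].sum() / weight
    return out


def build_admission_grid(
    events: pd.DataFrame,
    meta: AdmissionMeta,
    ranges: Optional[ClinicalRangeTable] = None,
    stay_length: Optional[int] = None,
) -> HourlyGrid:
    """Full per-admission grid: binned charted features, derived windows,
    broadcast statics, and chronic-condition flags."""
    ranges = ranges or default_ranges()
    ev = events[events["admission_id"] == meta.admission_id]
    if stay_length is None:
        stay_length = meta.stay_hours
    if stay_length is None:
        if len(ev) == 0:
            raise ValueError(f"{meta.admission_id}: no events, no stay length")
        stay_length = int(np.max(nearest_hour(ev["time_hours"]))) + 1
    grid = bin_hourly(ev, stay_length, ranges)
    grid.admission_id = meta.admission_id
    windows = derive_trailing_windows(ev, stay_length, meta.weight)
    statics = pd.DataFrame(
        {
            "age": meta.age,
            "weight": meta.weight,
            "flag_chronic_renal": float(meta.flag_chronic_renal),
            "flag_chronic_liver": float(meta.flag_chronic_liver),
            "flag_pneumonia": float(meta.flag_pneumonia),
        },
        index=grid.values.index,
    )
    values = pd.concat([grid.values, windows, statics], axis=1)
    extra_mask = pd.DataFrame(
        True, index=grid.values.index,
        columns=list(windows.columns) + list(statics.columns),
    )
    mask = pd.concat([grid.mask, extra_mask], axis=1)
    order = [c for c in ranges.grid_features() if c in values.columns]
    return HourlyGrid(meta.admission_id, values[order], mask[order])


def build_grids(
    events: pd.DataFrame,
    metas: Sequence[AdmissionMeta],
    ranges: Optional[ClinicalRangeTable] = None,
    min_age: float = 15.0,
    stay_lengths: Optional[dict[str, int]] = None,
) -> tuple[list[HourlyGrid], list[AdmissionMeta]]:
    """Age filter + outlier removal + per-admission grid construction."""
    ranges = ranges or default_ranges()
    events, metas = filter_age(events, metas, min_age)
    events = remove_outliers(events, ranges)
    grids = []
    for meta in metas:
        sl = (stay_lengths or {}).get(meta.admission_id)
        grids.append(build_admission_grid(events, meta, ranges, sl))
    return grids, list(metas)


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def impute_zoh(grid: HourlyGrid) -> HourlyGrid:
    """Zero-order hold: carry each feature's most recent observed value
    forward within the admission.  Hours before a feature's first
    observation stay absent (the population mean fills them later).
    Idempotent; never crosses admission boundaries (grids are per-admission).
    """
    out = grid.copy()
    values = out.values.copy()
    values[~out.mask] = np.nan
    out.values = values.ffill()
    return out


def compute_population_stats(
    grids: Iterable[HourlyGrid], scope: Optional[Sequence[str]] = None
) -> PopulationStats:
    """Mean and sample SD (ddof=1) per feature over observed values only,
    restricted to the admissions in ``scope`` (default: all given)."""
    scope_set = set(scope) if scope is not None else None
    frames = []
    ids = []
    for g in grids:
        if scope_set is not None and g.admission_id not in scope_set:
            continue
        ids.append(g.admission_id)
        frames.append(g.values.where(g.mask))
    if not frames:
        raise ValueError("empty admission scope for population stats")
    stacked = pd.concat(frames, axis=0)
    counts = stacked.notna().sum()
    if (counts == 0).any():
        missing = list(counts.index[counts == 0])
        raise ValueError(
            f"no observed values in scope for feature(s) {missing}"
        )
    mean = stacked.mean()
    std = stacked.std(ddof=1).fillna(0.0)
    return PopulationStats(mean, std, tuple(ids))


def impute_population_mean(
    grid: HourlyGrid, stats: PopulationStats
) -> HourlyGrid:
    """Fill any remaining absent values with the population mean, making
    the grid dense.  Applied after :func:`impute_zoh`, this touches only
    hours before a feature's first observation (or features never observed
    in the admission)."""
    missing = [c for c in grid.features if c not in stats.mean.index]
    if missing:
        raise KeyError(f"population stats lack feature(s) {missing}")
    out = grid.copy()
    out.values = out.values.fillna(stats.mean)
    return out


def impute(grid: HourlyGrid, stats: PopulationStats) -> HourlyGrid:
    """ZOH then population-mean fallback; result is dense."""
    return impute_population_mean(impute_zoh(grid), stats)


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def standardize(
    grid: HourlyGrid,
    stats: PopulationStats,
    ranges: Optional[ClinicalRangeTable] = None,
) -> HourlyGrid:
    """Map each non-binary feature to (x − x̄)/s; binary features pass
    through unchanged.  Requires a dense grid and s > 0."""
    ranges = ranges or default_ranges()
    if not grid.is_dense():
        raise ValueError(f"{grid.admission_id}: grid must be dense")
    binary = set(ranges.binary_features())
    out = grid.copy()
    for col in out.features:
        if col in binary:
            continue
        s = stats.std.get(col)
        if s is None or not np.isfinite(s):
            raise KeyError(f"no population stats for feature {col!r}")
        if s <= 0:
            raise ValueError(
                f"feature {col!r} has zero population SD; cannot standardize"
            )
        out.values[col] = (out.values[col] - stats.mean[col]) / s
    return out


def unstandardize(
    grid: HourlyGrid,
    stats: PopulationStats,
    ranges: Optional[ClinicalRangeTable] = None,
) -> HourlyGrid:
    """Inverse of :func:`standardize` (floating tolerance)."""
    ranges = ranges or default_ranges()
    binary = set(ranges.binary_features())
    out = grid.copy()
    for col in out.features:
        if col not in binary:
            out.values[col] = out.values[col] * stats.std[col] + stats.mean[col]
    return out
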