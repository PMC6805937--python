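"""Synthetic ICU cohort generator.

Emits long-format event tables (vitals, labs, fluid boluses, urine output)
plus per-admission metadata, with a controllable number of admissions whose
trajectories deteriorate into septic shock under the hourly Sepsis-2 rules.
Positive trajectories are built compositionally, mirroring the nesting of
the criteria: first at least two SIRS criteria concurrent with an
infection-suspicion interval, then an organ-dysfunction criterion
(lactate), then systolic hypotension once cumulative fluids cross the
resuscitation-adequacy rule — so every labeling sub-rule is reachable on
generated data.  Every admission is self-checked through the labeling
module; an admission whose realized label disagrees with its intended
outcome is resampled a bounded number of times.

The dynamics are deliberately minimal stand-ins (baseline + AR(1) noise +
linear deterioration ramps); they satisfy the criteria and give the model a
learnable, monotone pre-onset signal, but make no claim of physiological
realism beyond that.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .config import ClinicalRangeTable, default_ranges, derive_seed
from .features import build_admission_grid, impute, PopulationStats
from .labeling import AdmissionMeta, label_admission


class CohortGenerationError(RuntimeError):
    """Raised when an admission cannot satisfy its intended label."""


@dataclass
class CohortConfig:
    """Study-condition knobs for the generator.

    ``shock_fraction`` is realized by count (round(n * fraction) positives),
    not by Bernoulli draws.  ``missingness_rate`` is the per-feature-hour
    probability that a scheduled measurement is not charted (MCAR);
    ``lab_block_hours`` > 1 instead draws labs only every k hours, a
    block-missingness regime under which zero-order hold behaves
    differently.  ``ramp_hours`` is the length of the linear deterioration
    ramp that precedes septic-shock onset in positive admissions.
    """

    n_admissions: int = 100
    shock_fraction: float = 0.2
    stay_length_range: tuple[int, int] = (36, 96)
    missingness_rate: float = 0.3
    lab_block_hours: int = 1  # 1 = MCAR labs; k>1 = labs every k hours
    ramp_hours: int = 36
    outlier_rate: float = 0.0
    infection_in_negatives: float = 0.3  # fraction of negatives w/ intervals
    max_retries: int = 20
    seed: int = 0
    #: per-feature deterioration targets reached at onset (physical units)
    deterioration_targets: dict[str, float] = field(default_factory=lambda: {
        "temperature": 39.2, "heart_rate": 115.0, "respiratory_rate": 26.0,
        "wbc": 15_500.0, "lactate": 3.2, "sbp": 82.0, "pao2_fio2": 230.0,
    })

    def __post_init__(self):
        if not 0.0 <= self.shock_fraction <= 1.0:
            raise ValueError("shock_fraction must be in [0, 1]")
        if self.stay_length_range[0] < 8:
            raise ValueError("stay_length_range min must be >= 8 h "
                             "(labeling windows need history)")
        if not 0.0 <= self.missingness_rate < 1.0:
            raise ValueError("missingness_rate must be in [0, 1)")


#: baseline physiology: (mean, between-admission SD, within-admission SD)
_BASELINES: dict[str, tuple[float, float, float]] = {
    "heart_rate": (78, 6, 4), "sbp": (118, 7, 5), "dbp": (70, 6, 4),
    "map": (86, 6, 4), "respiratory_rate": (16, 1.5, 1.2),
    "temperature": (36.8, 0.2, 0.15), "spo2": (97, 1.0, 0.8),
    "gcs": (14.6, 0.3, 0.2),
    "wbc": (8_000, 1_200, 700), "lactate": (1.2, 0.2, 0.15),
    "creatinine": (1.0, 0.15, 0.08), "bilirubin": (0.8, 0.15, 0.08),
    "platelets": (250_000, 35_000, 12_000), "inr": (1.1, 0.08, 0.04),
    "paco2": (40, 2.0, 1.5), "pao2": (95, 6, 5), "pao2_fio2": (400, 30, 20),
    "bun": (15, 3, 1.5), "glucose": (110, 15, 10), "sodium": (140, 2, 1),
    "potassium": (4.0, 0.3, 0.15), "bicarbonate": (24, 1.5, 0.8),
    "hemoglobin": (13, 1.0, 0.3), "ph": (7.40, 0.02, 0.015),
}

_VITALS = ["heart_rate", "sbp", "dbp", "map", "respiratory_rate",
           "temperature", "spo2", "gcs"]
_LABS = [f for f in _BASELINES if f not in _VITALS]
_SIRS_FEATURES = ["temperature", "heart_rate", "respiratory_rate",
                  "paco2", "wbc"]
#: safe mid-normal values forced during negatives' infection intervals so
#: no SIRS criterion can fire there
_SAFE_SIRS = {"temperature": 37.0, "heart_rate": 80.0,
              "respiratory_rate": 16.0, "paco2": 40.0, "wbc": 8_000.0}


def baseline_stats(ranges: Optional[ClinicalRangeTable] = None) -> PopulationStats:
    """Population stats at the generator's baseline physiology; used as the
    fallback for the generator's internal label self-check."""
    ranges = ranges or default_ranges()
    mean, std = {}, {}
    for name in ranges.grid_features():
        if name in _BASELINES:
            m, sb, sw = _BASELINES[name]
            mean[name], std[name] = m, float(np.hypot(sb, sw))
        elif name in ("fluids_24h", "fluids_total"):
            mean[name], std[name] = 0.0, 1.0
        elif name == "urine_output_2h":
            mean[name], std[name] = 1.8, 0.5
        elif name == "age":
            mean[name], std[name] = 62.0, 16.0
        elif name == "weight":
            mean[name], std[name] = 80.0, 16.0
        else:  # flags
            mean[name], std[name] = 0.0, 1.0
    return PopulationStats(pd.Series(mean), pd.Series(std), ("baseline",))


def _ar1(rng, n, sd, rho=0.8):
    x = np.empty(n)
    x[0] = rng.normal(0, sd)
    innov_sd = sd * np.sqrt(1 - rho**2)
    for t in range(1, n):
        x[t] = rho * x[t - 1] + rng.normal(0, innov_sd)
    return x


def _simulate_admission(rng, config, admission_id, positive, ranges):
    """One admission's raw events and metadata (pre self-check)."""
    lo, hi = config.stay_length_range
    stay = int(rng.integers(lo, hi + 1))
    age = float(np.clip(rng.normal(62, 16), 18, 95))
    weight = float(np.clip(rng.normal(80, 16), 50, 140))
    meta = AdmissionMeta(
        admission_id=admission_id, age=age, weight=weight,
        flag_chronic_renal=bool(rng.random() < 0.08),
        flag_chronic_liver=bool(rng.random() < 0.06),
        flag_pneumonia=bool(rng.random() < 0.10),
        outcome_label=positive, stay_hours=stay,
    )

    hours = np.arange(stay)
    # latent hourly trajectory per feature
    traj = {}
    for name, (m, sb, sw) in _BASELINES.items():
        traj[name] = m + rng.normal(0, sb) + _ar1(rng, stay, sw)

    onset = None
    forced: dict[tuple[str, int], float] = {}
    if positive:
        onset = int(rng.integers(12, stay - 2))
        ramp_start = max(0, onset - config.ramp_hours)
        meta.infection_suspected = [(float(ramp_start), float(stay))]
        span = max(onset - ramp_start, 1)
        for name, target in config.deterioration_targets.items():
            base = _BASELINES[name][0]
            for h in range(ramp_start, stay):
                frac = min((h - ramp_start) / span, 1.0)
                traj[name][h] = base + frac * (target - base) \
                    + rng.normal(0, _BASELINES[name][2] * 0.5)
        # hypotension only from onset; pre-onset SBP stays >= 92 so the
        # shock rule cannot fire early
        traj["sbp"][ramp_start:onset] = np.maximum(
            traj["sbp"][ramp_start:onset], 92.0)
        traj["sbp"][onset:] = config.deterioration_targets["sbp"] \
            + rng.normal(0, 1.5, stay - onset)
        for name in _SIRS_FEATURES + ["sbp", "lactate"]:
            for h in range(onset, min(onset + 4, stay)):
                forced[(name, h)] = float(traj[name][h])
        # guarantee the gate values exactly at onset
        forced[("temperature", onset)] = 39.2
        forced[("heart_rate", onset)] = 115.0
        forced[("sbp", onset)] = 82.0
        forced[("lactate", onset)] = 3.2
    elif rng.random() < config.infection_in_negatives:
        a = float(rng.integers(0, stay - 8))
        b = float(min(stay, a + rng.integers(6, 24)))
        meta.infection_suspected = [(a, b)]
        # clamp every SIRS input to mid-normal inside the interval so
        # sepsis (hence shock) cannot occur
        for h in range(int(a), int(np.ceil(b))):
            for name, v in _SAFE_SIRS.items():
                forced[(name, h)] = v
        traj["sbp"][int(a):int(np.ceil(b))] = np.maximum(
            traj["sbp"][int(a):int(np.ceil(b))], 100.0)

    rows = []

    def emit(feature, hour, value, jitter=0.0):
        spec = ranges[feature]
        value = float(np.clip(value, spec.lower, spec.upper))
        t = max(0.0, float(hour) + jitter)
        rows.append((admission_id, feature, round(t, 3), round(value, 4)))

    observe = rng.random((stay, len(_VITALS) + len(_LABS))) \
        >= config.missingness_rate
    feat_idx = {f: i for i, f in enumerate(_VITALS + _LABS)}
    for h in hours:
        for name in _VITALS + _LABS:
            if (name, int(h)) in forced:
                emit(name, h, forced[(name, int(h))],
                     jitter=float(rng.uniform(-0.3, 0.3)))
                continue
            if name in _LABS and config.lab_block_hours > 1:
                if h % config.lab_block_hours != 0:
                    continue
            if h > 0 and not observe[h, feat_idx[name]]:
                continue  # hour 0 always charted (admission workup)
            emit(name, h, traj[name][h],
                 jitter=float(rng.uniform(-0.3, 0.3)))

    # urine output: hourly volumes, oliguric after onset in positives
    for h in hours:
        if h == 0:
            continue
        vol = max(5.0, rng.normal(weight * 1.0, 15.0))
        if positive and onset is not None and h >= onset:
            vol = max(2.0, rng.normal(weight * 0.2, 5.0))
        if rng.random() >= config.missingness_rate or (positive and h >= (onset or 0)):
            emit("urine_output", h, vol, jitter=-0.25)

    # fluids: positives get a resuscitation series crossing the adequacy
    # rule before onset; negatives only small maintenance boluses that
    # stay under both adequacy branches (total < 900 <= 20 mL/kg at the
    # minimum generated weight of 50 kg)
    if positive and onset is not None:
        for dh, vol in ((6, 500.0), (4, 500.0), (2, 500.0)):
            h = max(1, onset - dh)
            emit("fluid_bolus", h, vol, jitter=-0.5)
    else:
        n_bolus = int(rng.integers(0, 3))
        for _ in range(n_bolus):
            h = int(rng.integers(1, stay))
            emit("fluid_bolus", h, float(rng.uniform(100, 250)), jitter=-0.5)

    events = pd.DataFrame(
        rows, columns=["admission_id", "feature", "time_hours", "value"])
    return events, meta, onset


def generate_admission(rng_seed, config, admission_id, positive,
                       ranges, fallback_stats):
    """Simulate one admission and verify its label through the rule module,
    resampling up to ``config.max_retries`` times on disagreement."""
    for attempt in range(config.max_retries):
        rng = np.random.default_rng([rng_seed, attempt])
        events, meta, onset = _simulate_admission(
            rng, config, admission_id, positive, ranges)
        grid = build_admission_grid(events, meta, ranges)
        series = label_admission(impute(grid, fallback_stats), meta)
        if series.ever_shock == positive:
            return events, meta, (series.onset_hour if positive else None)
    which = "septic-shock criteria unreachable" if positive else \
        "negative admission keeps satisfying septic-shock criteria"
    raise CohortGenerationError(
        f"{admission_id}: {which} after {config.max_retries} attempts"
    )


def generate_cohort(
    config: CohortConfig,
    ranges: Optional[ClinicalRangeTable] = None,
) -> tuple[pd.DataFrame, list[AdmissionMeta]]:
    """Generate a cohort; deterministic given ``config.seed``.

    Returns the long event table and the metadata list.  Exactly
    ``round(n_admissions * shock_fraction)`` admissions are engineered to
    reach septic shock under the hourly rules; the rest never do.
    """
    ranges = ranges or default_ranges()
    stats = baseline_stats(ranges)
    n = config.n_admissions
    n_pos = int(round(n * config.shock_fraction))
    rng = np.random.default_rng(derive_seed(config.seed, "cohort"))
    positive_slots = set(rng.permutation(n)[:n_pos].tolist())

    tables, metas = [], []
    for i in range(n):
        admission_id = f"adm{i:05d}"
        events, meta, onset = generate_admission(
            derive_seed(config.seed, f"admission-{i}"), config,
            admission_id, i in positive_slots, ranges, stats)
        tables.append(events)
        metas.append(meta)
    events = pd.concat(tables, ignore_index=True)
    if config.outlier_rate > 0:
        events, _ = inject_outliers(
            events, config.outlier_rate, ranges,
            derive_seed(config.seed, "outliers"))
    return events, metas


def inject_outliers(
    events: pd.DataFrame,
    rate: float,
    ranges: Optional[ClinicalRangeTable] = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Index]:
    """Push a random ``rate`` fraction of charted events strictly outside
    their clinical range.  Returns the modified table and the row labels of
    the corrupted events (so a round-trip with the outlier filter can be
    verified)."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must be in [0, 1)")
    ranges = ranges or default_ranges()
    out = events.copy()
    if rate == 0.0 or len(events) == 0:
        return out, pd.Index([])
    chartable = [s.name for s in ranges if s.kind in ("vital", "lab")]
    eligible = out.index[out["feature"].isin(chartable)]
    rng = np.random.default_rng(seed)
    n_flag = int(np.floor(rate * len(eligible)))
    flagged = pd.Index(rng.choice(eligible, size=n_flag, replace=False))
    for idx in flagged:
        spec = ranges[out.at[idx, "feature"]]
        span = spec.upper - spec.lower
        if rng.random() < 0.5:
            out.at[idx, "value"] = spec.upper + span * 0.1
        else:
            out.at[idx, "value"] = spec.lower - span * 0.1
    return out, flagged


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def write_cohort_csv(
    events: pd.DataFrame,
    metas: list[AdmissionMeta],
    events_path: str | Path,
    meta_path: str | Path,
) -> None:
    """Write the event table and metadata as the canonical long-CSV dialect
    (UTF-8, '.' decimal); infection intervals serialized as
    ``start-end`` pairs joined by ';'."""
    events.to_csv(events_path, index=False)
    pd.DataFrame(
        {
            "admission_id": [m.admission_id for m in metas],
            "age": [m.age for m in metas],
            "weight": [m.weight for m in metas],
            "stay_hours": [m.stay_hours for m in metas],
            "infection_suspected": [
                ";".join(f"{a:g}-{b:g}" for a, b in m.infection_suspected)
                for m in metas
            ],
            "flag_chronic_renal": [int(m.flag_chronic_renal) for m in metas],
            "flag_chronic_liver": [int(m.flag_chronic_liver) for m in metas],
            "flag_pneumonia": [int(m.flag_pneumonia) for m in metas],
            "outcome_label": [
                "" if m.outcome_label is None else int(m.outcome_label)
                for m in metas
            ],
        }
    ).to_csv(meta_path, index=False)


def read_cohort_csv(
    events_path: str | Path, meta_path: str | Path
) -> tuple[pd.DataFrame, list[AdmissionMeta]]:
    events = pd.read_csv(events_path)
    validate = events  # schema check
    from .features import validate_events
    validate_events(validate)
    mdf = pd.read_csv(meta_path, keep_default_na=False)
    metas = []
    for _, row in mdf.iterrows():
        intervals = []
        if str(row.get("infection_suspected", "")):
            for chunk in str(row["infection_suspected"]).split(";"):
                a, _, b = chunk.partition("-")
                intervals.append((float(a), float(b)))
        outcome = row.get("outcome_label", "")
        metas.append(AdmissionMeta(
            admission_id=str(row["admission_id"]),
            age=float(row["age"]), weight=float(row["weight"]),
            infection_suspected=intervals,
            flag_chronic_renal=bool(int(row["flag_chronic_renal"])),
            flag_chronic_liver=bool(int(row["flag_chronic_liver"])),
            flag_pneumonia=bool(int(row["flag_pneumonia"])),
            outcome_label=None if outcome == "" else bool(int(outcome)),
            stay_hours=int(row["stay_hours"]) if str(row["stay_hours"]) else None,
        ))
    return events, metas
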