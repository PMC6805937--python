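"""Hourly Sepsis-2 state labeling: SIRS, organ dysfunction, septic shock.

Each admission-hour is assigned one of four ordered states —
``negative < sepsis < severe_sepsis < septic_shock`` — by the rule set of
the SIRS-era screening definitions:

* **sepsis**: at least two SIRS criteria concurrent with suspected infection;
* **severe sepsis**: sepsis plus at least one sepsis-related organ
  dysfunction;
* **septic shock**: severe sepsis plus hypotension (systolic blood pressure
  below 90 mmHg) despite adequate fluid resuscitation (at least 20 mL/kg
  over the trailing 24 hours, or at least 1,200 mL in total).

All thresholds are applied to physical-unit values on the imputed hourly
grid; "concurrent" means within the same hour bin.  Comparisons are strict
or inclusive exactly as the criteria print them (``>`` strict, ``≥``
inclusive): SBP of exactly 90 mmHg is not hypotension.

Infection suspicion is an input — a set of half-open hour intervals per
admission — not something this module infers; real-data adapters may
populate it from antibiotic/culture heuristics upstream.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd


class SepsisState(enum.IntEnum):
    """Ordered severity states; the integer order is the clinical order."""

    NEGATIVE = 0
    SEPSIS = 1
    SEVERE_SEPSIS = 2
    SEPTIC_SHOCK = 3

    def __str__(self) -> str:  # CSV-friendly name
        return self.name.lower()


@dataclass
class AdmissionMeta:
    """Per-admission metadata needed by the rules and the model."""

    admission_id: str
    age: float
    weight: float
    #: half-open ``[start, end)`` hour intervals with suspected infection
    infection_suspected: list[tuple[float, float]] = field(default_factory=list)
    flag_chronic_renal: bool = False
    flag_chronic_liver: bool = False
    flag_pneumonia: bool = False
    #: intended outcome when generated synthetically; None for real data
    outcome_label: Optional[bool] = None
    #: stay length in whole hours; inferred from events when absent
    stay_hours: Optional[int] = None

    def __post_init__(self):
        if self.age <= 0:
            raise ValueError(f"{self.admission_id}: age must be positive")
        if self.weight <= 0:
            raise ValueError(f"{self.admission_id}: weight must be positive")
        ivs = sorted(self.infection_suspected)
        for (a0, b0), (a1, b1) in zip(ivs, ivs[1:]):
            if a1 < b0:
                raise ValueError(
                    f"{self.admission_id}: overlapping infection intervals"
                )
        self.infection_suspected = ivs

    def infection_at(self, hour: float) -> bool:
        return any(a <= hour < b for a, b in self.infection_suspected)


@dataclass
class HourlyObservation:
    """One imputed hour of the variables the rules read (physical units)."""

    temperature: float  # degC
    heart_rate: float  # beats/min
    respiratory_rate: float  # breaths/min
    paco2: float  # mmHg
    wbc: float  # cells/uL
    sbp: float  # mmHg
    lactate: float  # mmol/L
    urine_output_2h: float  # mL/kg over trailing 2 h
    creatinine: float  # mg/dL
    bilirubin: float  # mg/dL
    platelets: float  # count/uL
    inr: float  # ratio
    pao2_fio2: float  # mmHg ratio
    fluids_24h: float  # mL over trailing 24 h
    fluids_total: float  # mL cumulative since admission


@dataclass
class SepsisStateSeries:
    """Per-hour states for one admission plus the derived shock onset."""

    admission_id: str
    states: list[SepsisState]

    @property
    def onset_hour(self) -> Optional[int]:
        """First hour with state ``septic_shock``, or None."""
        for h, s in enumerate(self.states):
            if s == SepsisState.SEPTIC_SHOCK:
                return h
        return None

    @property
    def ever_shock(self) -> bool:
        return self.onset_hour is not None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "admission_id": self.admission_id,
                "hour": np.arange(len(self.states)),
                "state": [str(s) for s in self.states],
            }
        )


# ---------------------------------------------------------------------------
# rule primitives
# ---------------------------------------------------------------------------

def count_sirs(obs: HourlyObservation) -> int:
    """Number of satisfied SIRS criteria, 0–4.

    Criteria: temperature <36 or >38 degC; heart rate >90/min; respiratory
    rate >20/min or PaCO2 <32 mmHg; WBC <4,000 or >12,000 cells/uL.  A
    criterion counts once even if both of its sub-conditions hold.
    """
    n = 0
    n += obs.temperature < 36.0 or obs.temperature > 38.0
    n += obs.heart_rate > 90.0
    n += obs.respiratory_rate > 20.0 or obs.paco2 < 32.0
    n += obs.wbc < 4_000.0 or obs.wbc > 12_000.0
    return int(n)


def is_sepsis(obs: HourlyObservation, infection_suspected: bool) -> bool:
    """Sepsis: at least two SIRS criteria plus suspected infection."""
    return infection_suspected and count_sirs(obs) >= 2


def fluid_adequate(fluids_24h: float, fluids_total: float, weight: float) -> bool:
    """Adequate fluid resuscitation: ≥20 mL/kg over the trailing 24 h, or a
    total ≥1,200 mL.  Both bounds inclusive."""
    if weight <= 0:
        raise ValueError("weight must be positive")
    return fluids_24h / weight >= 20.0 or fluids_total >= 1_200.0


def organ_dysfunction(
    obs: HourlyObservation, meta: AdmissionMeta, fluids_adequate: bool
) -> bool:
    """Any sepsis-related organ dysfunction.

    Sub-criteria: SBP <90 mmHg; lactate >2.0 mmol/L; urine output <0.5 mL/kg
    over the trailing 2 h despite adequate fluids; creatinine >2.0 mg/dL
    absent chronic renal disease; bilirubin >2.0 mg/dL absent chronic liver
    disease; platelets <100,000/uL; INR >1.5; PaO2/FiO2 <200 with pneumonia;
    PaO2/FiO2 <250 without pneumonia.
    """
    return (
        obs.sbp < 90.0
        or obs.lactate > 2.0
        or (obs.urine_output_2h < 0.5 and fluids_adequate)
        or (obs.creatinine > 2.0 and not meta.flag_chronic_renal)
        or (obs.bilirubin > 2.0 and not meta.flag_chronic_liver)
        or obs.platelets < 100_000.0
        or obs.inr > 1.5
        or (obs.pao2_fio2 < 200.0 and meta.flag_pneumonia)
        or (obs.pao2_fio2 < 250.0 and not meta.flag_pneumonia)
    )


def label_hour(
    obs: HourlyObservation, meta: AdmissionMeta, infection_suspected: bool
) -> SepsisState:
    """Highest applicable state for one imputed hour."""
    if not is_sepsis(obs, infection_suspected):
        return SepsisState.NEGATIVE
    adequate = fluid_adequate(obs.fluids_24h, obs.fluids_total, meta.weight)
    if not organ_dysfunction(obs, meta, adequate):
        return SepsisState.SEPSIS
    if obs.sbp < 90.0 and adequate:
        return SepsisState.SEPTIC_SHOCK
    return SepsisState.SEVERE_SEPSIS


# ---------------------------------------------------------------------------
# admission-level labeling
# ---------------------------------------------------------------------------

_OBS_FIELDS = list(HourlyObservation.__dataclass_fields__)


def label_admission(grid: "HourlyGrid", meta: AdmissionMeta) -> SepsisStateSeries:
    """Label every hour of a fully imputed grid.

    The grid must contain all variables the rules read, in physical units,
    including the trailing-window quantities (``urine_output_2h``,
    ``fluids_24h``, ``fluids_total``).
    """
    values = grid.values
    if len(values) == 0:
        raise ValueError(f"{grid.admission_id}: empty grid")
    missing = [f for f in _OBS_FIELDS if f not in values.columns]
    if missing:
        raise ValueError(
            f"{grid.admission_id}: grid lacks rule variables {missing}"
        )
    sub = values[_OBS_FIELDS]
    if not np.isfinite(sub.to_numpy(dtype=float)).all():
        raise ValueError(f"{grid.admission_id}: grid not fully imputed")
    states = []
    for hour, row in zip(values.index, sub.itertuples(index=False)):
        obs = HourlyObservation(*row)
        states.append(label_hour(obs, meta, meta.infection_at(float(hour))))
    return SepsisStateSeries(grid.admission_id, states)


def label_cohort(
    grids: Sequence["HourlyGrid"], metas: Sequence[AdmissionMeta]
) -> list[SepsisStateSeries]:
    meta_by_id = {m.admission_id: m for m in metas}
    return [label_admission(g, meta_by_id[g.admission_id]) for g in grids]


def write_states_csv(series: Sequence[SepsisStateSeries], path: str | Path) -> None:
    """Long CSV ``admission_id,hour,state`` for a set of labeled admissions."""
    pd.concat([s.to_frame() for s in series]).to_csv(path, index=False)


def write_onsets_csv(series: Sequence[SepsisStateSeries], path: str | Path) -> None:
    pd.DataFrame(
        {
            "admission_id": [s.admission_id for s in series],
            "onset_hour": [s.onset_hour for s in series],
        }
    ).to_csv(path, index=False)
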