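import numpy as np
import pandas as pd
import pytest

import shockwatch as sw


@pytest.fixture(scope="session")
def ranges():
    return sw.default_ranges()


@pytest.fixture(scope="session")
def small_cohort():
    """20 admissions, half engineered to reach septic shock (seed 7)."""
    config = sw.CohortConfig(n_admissions=20, shock_fraction=0.5, seed=7)
    events, metas = sw.generate_cohort(config)
    return config, events, metas


@pytest.fixture(scope="session")
def small_cohort_labeled(small_cohort, ranges):
    """Grids, population stats and rule-based state series for the small
    cohort."""
    _, events, metas = small_cohort
    grids, metas = sw.build_grids(events, metas, ranges)
    stats = sw.compute_population_stats(grids)
    meta_by_id = {m.admission_id: m for m in metas}
    series = {
        g.admission_id: sw.label_admission(sw.impute(g, stats),
                                           meta_by_id[g.admission_id])
        for g in grids
    }
    return grids, metas, stats, series


def normal_observation(**overrides) -> sw.HourlyObservation:
    """A fully normal hour: no criterion fires anywhere."""
    base = dict(
        temperature=37.0, heart_rate=80.0, respiratory_rate=16.0,
        paco2=40.0, wbc=9_000.0, sbp=120.0, lactate=1.0,
        urine_output_2h=2.0, creatinine=1.0, bilirubin=0.8,
        platelets=250_000.0, inr=1.1, pao2_fio2=400.0,
        fluids_24h=0.0, fluids_total=0.0,
    )
    base.update(overrides)
    return sw.HourlyObservation(**base)


def plain_meta(**overrides) -> sw.AdmissionMeta:
    base = dict(admission_id="a0", age=60.0, weight=80.0)
    base.update(overrides)
    return sw.AdmissionMeta(**base)


@pytest.fixture
def normal_obs():
    return normal_observation


@pytest.fixture
def meta_factory():
    return plain_meta


def random_observation(rng: np.random.Generator) -> sw.HourlyObservation:
    """Observation with every field drawn wide enough to land on either
    side of its rule threshold."""
    return sw.HourlyObservation(
        temperature=rng.uniform(34, 41),
        heart_rate=rng.uniform(50, 140),
        respiratory_rate=rng.uniform(8, 35),
        paco2=rng.uniform(20, 60),
        wbc=rng.uniform(1_000, 20_000),
        sbp=rng.uniform(60, 160),
        lactate=rng.uniform(0.3, 5),
        urine_output_2h=rng.uniform(0, 3),
        creatinine=rng.uniform(0.3, 5),
        bilirubin=rng.uniform(0.2, 5),
        platelets=rng.uniform(20_000, 500_000),
        inr=rng.uniform(0.8, 3),
        pao2_fio2=rng.uniform(100, 500),
        fluids_24h=rng.uniform(0, 4_000),
        fluids_total=rng.uniform(0, 3_000),
    )


def flat_rule_oracle(obs: sw.HourlyObservation, meta: sw.AdmissionMeta,
                     infection: bool) -> sw.SepsisState:
    """Independent one-expression restatement of the hourly criteria,
    kept deliberately separate from the production rule code."""
    sirs = (
        int(obs.temperature < 36 or obs.temperature > 38)
        + int(obs.heart_rate > 90)
        + int(obs.respiratory_rate > 20 or obs.paco2 < 32)
        + int(obs.wbc < 4000 or obs.wbc > 12000)
    )
    adequate = (obs.fluids_24h / meta.weight >= 20) or (obs.fluids_total >= 1200)
    dysfunction = (
        obs.sbp < 90 or obs.lactate > 2.0
        or (obs.urine_output_2h < 0.5 and adequate)
        or (obs.creatinine > 2.0 and not meta.flag_chronic_renal)
        or (obs.bilirubin > 2.0 and not meta.flag_chronic_liver)
        or obs.platelets < 100_000 or obs.inr > 1.5
        or (obs.pao2_fio2 < 200 and meta.flag_pneumonia)
        or (obs.pao2_fio2 < 250 and not meta.flag_pneumonia)
    )
    if not (infection and sirs >= 2):
        return sw.SepsisState.NEGATIVE
    if not dysfunction:
        return sw.SepsisState.SEPSIS
    if obs.sbp < 90 and adequate:
        return sw.SepsisState.SEPTIC_SHOCK
    return sw.SepsisState.SEVERE_SEPSIS


def make_grid(values: dict[str, list], admission_id="g0",
              mask: dict[str, list] | None = None) -> sw.HourlyGrid:
    """Small grid literal for pipeline tests."""
    vdf = pd.DataFrame(values, dtype=float)
    if mask is None:
        mdf = vdf.notna()
    else:
        mdf = pd.DataFrame(mask).astype(bool)
    return sw.HourlyGrid(admission_id, vdf, mdf)
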