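"""Shared fixtures.

``cohort20k`` is the expensive session fixture behind the statistical
acceptance checks: a 20,000-patient synthetic draw at generator defaults
(fixed seed), pushed through exclusions, features, the six-stratum split,
model training on Cohort I and calibration on Cohort II.  Everything else
uses small purpose-built populations.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from edrisk.calibration import PPVCalibrator
from edrisk.cohorts import apply_exclusions, split_cohorts, stratify_six_subgroups
from edrisk.features import build_pivot_table, variance_filter
from edrisk.model import EDRiskModel
from edrisk.pipeline import compute_windows
from edrisk.synth import SyntheticConfig, generate_population

INDEX_DATE = dt.date(2013, 1, 1)
OBS_WINDOW, OUT_WINDOW = compute_windows(INDEX_DATE, 365, 180)


def make_history(patient_id="P1", age=40, gender="F", encounters=None):
    from edrisk.synth import PatientHistory
    h = PatientHistory(patient_id, age, gender, 45000.0, 2,
                       encounters or [])
    h.sort_encounters()
    return h


def ed_visit(pid, date, disposition="routine", dx="845.00"):
    from edrisk.synth import EncounterRecord
    return EncounterRecord(pid, date, "ED", encounter_type_code="ED",
                           disposition=disposition, primary_dx=dx)


@pytest.fixture(scope="session")
def small_population():
    """2,000 patients at generator defaults; enough for structural checks."""
    return generate_population(SyntheticConfig(n_patients=2000, seed=3))


@pytest.fixture(scope="session")
def small_matrix(small_population):
    kept, _ = apply_exclusions(small_population)
    return build_pivot_table(kept, OBS_WINDOW, OUT_WINDOW)


@pytest.fixture(scope="session")
def cohort20k():
    """The 20k-patient stated-world pipeline used by acceptance checks."""
    cfg = SyntheticConfig(n_patients=20000, seed=1)
    histories = generate_population(cfg)
    kept, _ = apply_exclusions(histories)
    matrix = variance_filter(
        build_pivot_table(kept, OBS_WINDOW, OUT_WINDOW), 40)
    strata = stratify_six_subgroups(matrix)
    split = split_cohorts(strata, matrix.outcome, seed=2)
    m1 = matrix.subset_rows(split.cohort_ids("I"))
    m2 = matrix.subset_rows(split.cohort_ids("II"))
    m3 = matrix.subset_rows(split.cohort_ids("III"))
    model = EDRiskModel(random_state=3).fit_matrix(m1)
    calibrator = PPVCalibrator(min_cell=50).fit(
        model.predict_score(m2.values), m2.outcome.to_numpy())
    truth = pd.Series({h.patient_id: h.truth_hazard for h in kept})
    return {
        "histories": kept,
        "matrix": matrix,
        "strata": strata,
        "split": split,
        "m1": m1, "m2": m2, "m3": m3,
        "model": model,
        "calibrator": calibrator,
        "scores3": model.predict_score(m3.values),
        "truth_hazard": truth,
    }


@pytest.fixture(scope="session")
def planted_subgroup():
    """Synthetic subgroup where exactly 5 planted features carry all signal.

    20 noise features, 5 informative; outcome from a logistic on the 5.
    """
    rng = np.random.default_rng(11)
    n, p_noise = 3000, 20
    informative = [f"signal_{i}" for i in range(5)]
    noise = [f"noise_{i}" for i in range(p_noise)]
    Xs = rng.poisson(1.0, size=(n, 5)).astype(float)
    Xn = rng.poisson(1.0, size=(n, p_noise)).astype(float)
    lp = -3.2 + Xs @ np.array([1.2, 1.0, 0.9, 0.8, 0.7])
    y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(int)
    X = pd.DataFrame(np.hstack([Xs, Xn]), columns=informative + noise)
    return X, y, informative
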