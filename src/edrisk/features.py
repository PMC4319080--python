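"""Patient-level feature engineering: the pivot table.

Turns encounter-level records into one numeric row per patient: counts for
encounter types, diagnoses, labs, radiology and medications; indicators for
age group, gender and chronic-condition categories; zip-level socioeconomic
proxies.  Count/indicator features are computed only from observation-window
records; the outcome label and time-to-first-ED come only from the outcome
window (temporal hygiene — no leakage across the index date).

The variance criterion ranks features by variance after per-column min-max
scaling to [0, 1], so counts and indicators compete on one scale; the two
empirical routing features (``prior_ed_count``, ``chronic_flag``) are always
retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from . import vocab
from .synth import PatientHistory

__all__ = [
    "FeatureMatrix",
    "build_pivot_table",
    "flag_chronic",
    "assign_age_group",
    "variance_filter",
    "VarianceThresholdFilter",
    "EMPIRICAL_FEATURES",
]

EMPIRICAL_FEATURES = ("prior_ed_count", "chronic_flag")

_AGE_EDGES = (0, 19, 35, 50)  # lower edges, inclusive


def assign_age_group(age_years: float) -> str:
    """Bin an age in years into one of four exclusive groups.

    Boundaries are inclusive on the lower edge: 0-18, 19-34, 35-49, 50+.
    """
    if age_years < 0:
        raise ValueError(f"age must be non-negative, got {age_years!r}")
    if age_years < 19:
        return "0-18"
    if age_years < 35:
        return "19-34"
    if age_years < 50:
        return "35-49"
    return "50+"


def flag_chronic(dx_code: str) -> str:
    """Dichotomize a diagnosis code as ``chronic`` or ``non_chronic``.

    Codes absent from the bundled lookup default to ``non_chronic`` with a
    warning (conservative: does not inflate the chronic stratum).
    """
    entry = vocab.DIAGNOSIS_LOOKUP.get(dx_code)
    if entry is None:
        warnings.warn(
            f"diagnosis code {dx_code!r} not in chronic-condition lookup; "
            "defaulting to non_chronic", stacklevel=2)
        return "non_chronic"
    return "chronic" if entry[1] else "non_chronic"


def _dx_family(dx_code: str) -> str:
    entry = vocab.DIAGNOSIS_LOOKUP.get(dx_code)
    return entry[0] if entry is not None else "other"


@dataclass
class FeatureMatrix:
    """Patient x feature table with outcome bookkeeping.

    ``values`` holds one numeric row per patient (absence encoded as 0);
    ``feature_meta`` maps each column to its category; ``outcome`` is the
    binary any-ED-visit-in-outcome-window label; ``time_to_event`` is days
    to the first outcome-window ED visit, censored at the outcome horizon
    (``event_observed`` == 0).
    """

    values: pd.DataFrame
    feature_meta: pd.DataFrame
    outcome: pd.Series
    time_to_event: pd.Series
    event_observed: pd.Series
    outcome_ed_count: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError("feature names must be unique")
        if self.values.isna().any().any():
            raise ValueError("feature matrix must have no missing values")

    @property
    def patient_ids(self) -> pd.Index:
        return self.values.index

    @property
    def prior_ed_count(self) -> pd.Series:
        return self.values["prior_ed_count"]

    @property
    def chronic_flag(self) -> pd.Series:
        return self.values["chronic_flag"]

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def subset_rows(self, patient_ids: Sequence[str]) -> "FeatureMatrix":
        idx = pd.Index(patient_ids)
        return FeatureMatrix(
            self.values.loc[idx], self.feature_meta,
            self.outcome.loc[idx], self.time_to_event.loc[idx],
            self.event_observed.loc[idx],
            None if self.outcome_ed_count is None
            else self.outcome_ed_count.loc[idx],
        )

    def subset_columns(self, names: Sequence[str]) -> "FeatureMatrix":
        names = list(names)
        meta = self.feature_meta[self.feature_meta["name"].isin(names)]
        return FeatureMatrix(
            self.values[names], meta.reset_index(drop=True),
            self.outcome, self.time_to_event, self.event_observed,
            self.outcome_ed_count,
        )

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        wide = self.values.copy()
        wide["outcome"] = self.outcome
        wide["time_to_event"] = self.time_to_event
        wide["event_observed"] = self.event_observed
        if self.outcome_ed_count is not None:
            wide["outcome_ed_count"] = self.outcome_ed_count
        wide.to_csv(directory / "pivot_table.csv", index_label="patient_id")
        self.feature_meta.to_csv(directory / "feature_meta.csv", index=False)

    @classmethod
    def load(cls, directory: str | Path) -> "FeatureMatrix":
        directory = Path(directory)
        wide = pd.read_csv(directory / "pivot_table.csv",
                           index_col="patient_id")
        meta = pd.read_csv(directory / "feature_meta.csv")
        outcome = wide.pop("outcome")
        tte = wide.pop("time_to_event")
        obs = wide.pop("event_observed")
        ed_count = (wide.pop("outcome_ed_count")
                    if "outcome_ed_count" in wide.columns else None)
        return cls(wide, meta, outcome, tte, obs, ed_count)


def _window_contains(window: tuple, d) -> bool:
    return window[0] <= d <= window[1]


def build_pivot_table(
    histories: Iterable[PatientHistory],
    observation_window: tuple,
    outcome_window: tuple,
) -> FeatureMatrix:
    """Aggregate encounter records into the patient-level pivot table.

    Parameters
    ----------
    histories : iterable of PatientHistory
    observation_window, outcome_window : (start_date, end_date)
        Inclusive date pairs.  The outcome window must start strictly after
        the observation window ends.

    Returns
    -------
    FeatureMatrix with one row per patient.  Patients with zero
    observation-window records are retained with all-zero features (the
    new-patient case).
    """
    obs_start, obs_end = observation_window
    out_start, out_end = outcome_window
    if obs_start > obs_end or out_start > out_end:
        raise ValueError("window start must not be after window end")
    if out_start <= obs_end:
        raise ValueError(
            "outcome window must start strictly after the observation "
            "window ends (windows overlap or are out of order)")
    horizon = (out_end - out_start).days + 1

    histories = list(histories)
    pids = [h.patient_id for h in histories]

    demo_rows = []
    count_rows: list[dict[str, float]] = []
    outcome_rows = []
    for h in histories:
        counts: dict[str, float] = {}
        chronic_fams: set[str] = set()
        n_chronic_dx = 0
        prior_ed = 0
        first_event: int | None = None
        n_out_ed = 0
        for e in h.encounters:
            if _window_contains(observation_window, e.date):
                if e.kind in ("ED", "inpatient", "outpatient"):
                    if e.disposition == "transfer_from_ed":
                        continue  # merged duplicate of a same-day ED visit
                    key = f"enc_type_{e.encounter_type_code}"
                    counts[key] = counts.get(key, 0) + 1
                    if e.kind == "ED":
                        prior_ed += 1
                    dxs = []
                    if e.primary_dx:
                        counts_key = f"pdx_{e.primary_dx}"
                        counts[counts_key] = counts.get(counts_key, 0) + 1
                        dxs.append(e.primary_dx)
                    for s in e.secondary_dx:
                        k2 = f"sdx_{s}"
                        counts[k2] = counts.get(k2, 0) + 1
                        dxs.append(s)
                    for dx in dxs:
                        if flag_chronic_quiet(dx):
                            n_chronic_dx += 1
                            chronic_fams.add(_dx_family(dx))
                elif e.kind == "lab":
                    k = f"lab_{e.detail['lab_name']}"
                    counts[k] = counts.get(k, 0) + 1
                    if e.detail.get("result") == "abnormal":
                        counts["lab_abnormal_total"] = (
                            counts.get("lab_abnormal_total", 0) + 1)
                elif e.kind == "radiology":
                    k = f"rad_{e.detail['modality']}"
                    counts[k] = counts.get(k, 0) + 1
                elif e.kind == "medication":
                    k = f"med_{e.detail['medication_class']}"
                    counts[k] = counts.get(k, 0) + 1
                    counts["n_medications"] = counts.get("n_medications", 0) + 1
            elif _window_contains(outcome_window, e.date):
                if e.kind == "ED" and e.disposition != "transfer_from_ed":
                    n_out_ed += 1
                    day = (e.date - out_start).days + 1
                    if first_event is None or day < first_event:
                        first_event = day
        counts["prior_ed_count"] = prior_ed
        counts["chronic_flag"] = 1 if chronic_fams else 0
        counts["n_chronic_categories"] = len(chronic_fams)
        for fam in chronic_fams:
            counts[f"chronic_cat_{fam}"] = 1
        count_rows.append(counts)
        demo_rows.append({
            f"age_{assign_age_group(h.age)}": 1,
            "gender_F": 1 if h.gender == "F" else 0,
            "zip_income": h.zip_income,
            "zip_education": h.zip_education,
        })
        if first_event is not None:
            outcome_rows.append((1, first_event, 1, n_out_ed))
        else:
            outcome_rows.append((0, horizon, 0, 0))

    counts_df = pd.DataFrame(count_rows, index=pids).fillna(0.0)
    demo_df = pd.DataFrame(demo_rows, index=pids).fillna(0.0)
    for g in vocab.AGE_GROUPS:
        col = f"age_{g}"
        if col not in demo_df.columns:
            demo_df[col] = 0.0
    for fam in vocab.CHAPTER_FAMILIES:
        col = f"chronic_cat_{fam}"
        if col not in counts_df.columns:
            counts_df[col] = 0.0
    values = pd.concat([demo_df, counts_df], axis=1)
    values = values[sorted(values.columns)].astype(float)
    values.index.name = "patient_id"

    meta = pd.DataFrame({"name": values.columns})
    meta["category"] = [_feature_category(c) for c in meta["name"]]
    meta["source"] = [_feature_source(c) for c in meta["name"]]

    out = pd.DataFrame(
        outcome_rows, index=values.index,
        columns=["outcome", "time_to_event", "event_observed", "ed_count"],
    )
    return FeatureMatrix(
        values, meta,
        out["outcome"].astype(int),
        out["time_to_event"].astype(int),
        out["event_observed"].astype(int),
        out["ed_count"].astype(int),  # used by mean-ED-by-risk-group reports
    )


def flag_chronic_quiet(dx_code: str) -> bool:
    """Chronic dichotomy without the unknown-code warning (bulk path)."""
    entry = vocab.DIAGNOSIS_LOOKUP.get(dx_code)
    return bool(entry is not None and entry[1])


def _feature_category(name: str) -> str:
    if name.startswith("age_"):
        return "age_group"
    if name.startswith("enc_type_"):
        return "encounter_type"
    if name.startswith("pdx_"):
        return "primary_dx"
    if name.startswith("sdx_"):
        return "secondary_dx"
    if name.startswith(("chronic_", "n_chronic")):
        return "chronic"
    if name.startswith("lab_"):
        return "lab"
    if name.startswith("rad_"):
        return "radiology"
    if name.startswith(("med_", "n_medications")):
        return "medication"
    if name == "prior_ed_count":
        return "encounter_type"
    return "ses"


def _feature_source(name: str) -> str:
    for prefix in ("pdx_", "sdx_", "enc_type_", "lab_", "rad_", "med_",
                   "age_", "chronic_cat_"):
        if name.startswith(prefix):
            return name[len(prefix):]
    return name


class VarianceThresholdFilter(BaseEstimator, TransformerMixin):
    """Keep the ``keep_n`` highest-variance columns of a DataFrame.

    Variance is computed after per-column min-max scaling to [0, 1] so
    counts and indicators compete on one scale; ties break toward the
    lexicographically smaller name; ``always_keep`` columns survive
    regardless of rank.
    """

    def __init__(self, keep_n: int = 40,
                 always_keep: tuple = EMPIRICAL_FEATURES):
        self.keep_n = keep_n
        self.always_keep = always_keep

    def fit(self, X: pd.DataFrame, y=None) -> "VarianceThresholdFilter":
        if self.keep_n < 1:
            raise ValueError("keep_n must be >= 1")
        X = pd.DataFrame(X)
        rng_ = X.max(axis=0) - X.min(axis=0)
        scaled = (X - X.min(axis=0)) / rng_.replace(0, 1.0)
        var = scaled.var(axis=0, ddof=1)
        order = sorted(X.columns, key=lambda c: (-var[c], c))
        keep = set(order[: self.keep_n])
        keep.update(c for c in self.always_keep if c in X.columns)
        # preserve original column order
        self.selected_features_ = [c for c in X.columns if c in keep]
        self.variances_ = var
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(X)[self.selected_features_]


def variance_filter(matrix: FeatureMatrix, keep_n: int) -> FeatureMatrix:
    """Reduce a FeatureMatrix to its ``keep_n`` highest-variance features.

    ``keep_n`` >= the feature count returns the matrix unchanged.  The
    empirical routing features are always retained.  Idempotent: filtering
    an already-filtered matrix with the same ``keep_n`` is the identity.
    """
    if keep_n >= matrix.values.shape[1]:
        return matrix
    f = VarianceThresholdFilter(keep_n=keep_n).fit(matrix.values)
    return matrix.subset_columns(f.selected_features_)
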