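"""Exclusions, six-stratum stratification, and the I/II/III cohort split.

Study-frame exclusions: patients with an ``expired`` encounter disposition
anywhere in the frame are dropped; same-day ED pairs where the second record
carries ``transfer_from_ed`` are merged into a single ED visit.

Stratification: chronic-condition status (2 levels) x prior-ED band
(0 / 1 / >=2) gives six cells.  Within each cell, cases (any outcome-window
ED visit) and controls are separately shuffled and dealt round-robin to
Cohort I (training), II (calibrating) and III (blind testing), so the split
is balanced deterministically: per-stratum per-cohort case counts differ
pairwise by at most one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .features import FeatureMatrix
from .synth import PatientHistory

__all__ = [
    "CohortSplit",
    "apply_exclusions",
    "stratify_six_subgroups",
    "split_cohorts",
    "STRATA",
]

COHORTS = ("I", "II", "III")

STRATA = (
    "nonchronic_ed0", "nonchronic_ed1", "nonchronic_ed2plus",
    "chronic_ed0", "chronic_ed1", "chronic_ed2plus",
)


@dataclass
class CohortSplit:
    """Assignment of every analyzable patient to cohort I, II or III."""

    assignment: pd.Series  # patient_id -> cohort label
    stratum: pd.Series     # patient_id -> stratum label
    seed: int

    def cohort_ids(self, cohort: str) -> pd.Index:
        return self.assignment.index[self.assignment == cohort]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"stratum": self.stratum, "cohort": self.assignment}
        ).rename_axis("patient_id")

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)


def apply_exclusions(
    histories: Iterable[PatientHistory],
) -> tuple[list[PatientHistory], pd.DataFrame]:
    """Apply study-frame exclusions and ED transfer merges.

    Returns the filtered histories and a log with one row per removal or
    merge (columns: patient_id, action, reason).  Surviving patients'
    non-ED records are never altered.
    """
    kept: list[PatientHistory] = []
    log_rows: list[dict] = []
    for h in histories:
        if any(e.disposition == "expired" for e in h.encounters):
            log_rows.append({
                "patient_id": h.patient_id, "action": "exclude_patient",
                "reason": "expired disposition in study frame",
            })
            continue
        transfer_days = {
            e.date for e in h.encounters
            if e.kind == "ED" and e.disposition == "transfer_from_ed"
        }
        if transfer_days:
            new_enc = []
            merged = set()
            for e in h.encounters:
                if (e.kind == "ED" and e.disposition == "transfer_from_ed"
                        and e.date in transfer_days):
                    # second leg of a same-day ED pair: drop it
                    merged.add(e.date)
                    continue
                new_enc.append(e)
            for d in sorted(merged):
                log_rows.append({
                    "patient_id": h.patient_id, "action": "merge_ed_transfer",
                    "reason": f"same-day ED transfer pair on {d.isoformat()} "
                              "counted as one ED visit",
                })
            h = PatientHistory(
                h.patient_id, h.age, h.gender, h.zip_income,
                h.zip_education, new_enc,
                truth_hazard=h.truth_hazard, event_flag=h.event_flag,
                event_day=h.event_day,
            )
        kept.append(h)
    log = pd.DataFrame(log_rows, columns=["patient_id", "action", "reason"])
    return kept, log


def _stratum_label(chronic: int, prior_ed: int) -> str:
    prefix = "chronic" if chronic else "nonchronic"
    band = "ed0" if prior_ed == 0 else ("ed1" if prior_ed == 1 else "ed2plus")
    return f"{prefix}_{band}"


def stratify_six_subgroups(matrix: FeatureMatrix) -> pd.Series:
    """Label every patient with one of the six strata.

    Strata are chronic-condition status {0,1} x prior-ED band {0, 1, >=2}:
    a disjoint, exhaustive partition of any population.
    """
    chronic = matrix.chronic_flag.astype(int)
    prior = matrix.prior_ed_count.astype(int)
    labels = [
        _stratum_label(c, p) for c, p in zip(chronic.to_numpy(),
                                             prior.to_numpy())
    ]
    return pd.Series(labels, index=matrix.patient_ids, name="stratum")


def split_cohorts(strata: pd.Series, outcome: pd.Series,
                  seed: int) -> CohortSplit:
    """Deal cases and controls round-robin to cohorts I/II/III per stratum.

    Within each stratum, cases (outcome=1) and controls (outcome=0) are
    shuffled with the given seed and dealt in turn, so per-stratum
    per-cohort case (and control) counts differ pairwise by at most one.
    """
    outcome = outcome.loc[strata.index]
    rng = np.random.default_rng(seed)
    assignment = pd.Series(index=strata.index, dtype=object, name="cohort")
    for stratum in sorted(strata.unique()):
        in_stratum = strata.index[strata == stratum]
        for label_value in (1, 0):
            ids = in_stratum[outcome.loc[in_stratum] == label_value]
            ids = ids.to_numpy()
            if len(ids) < 3:
                kind = "cases" if label_value == 1 else "controls"
                warnings.warn(
                    f"stratum {stratum!r} has only {len(ids)} {kind}; "
                    "dealing as far as possible", stacklevel=2)
            order = rng.permutation(len(ids))
            for pos, idx in enumerate(order):
                assignment.loc[ids[idx]] = COHORTS[pos % 3]
    return CohortSplit(assignment=assignment, stratum=strata, seed=seed)
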