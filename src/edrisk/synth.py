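"""Seeded synthetic HIE-style encounter generator.

Emulates the structure of a statewide health-information-exchange extract:
dated encounters (ED, inpatient, outpatient), laboratory results, radiology
events and outpatient prescriptions for a population of patients, together
with a latent per-patient 6-month ED event probability (``truth_hazard``)
that downstream models never see but tests can score against.

The stated world of the generator:

* marginal 6-month ED incidence targets 11.5% (the intercept of the logistic
  truth-hazard is solved numerically so the population mean matches
  ``target_incidence``);
* ED-visit recurrence is strong enough that more than 80% of patients with
  two or more historical ED visits revisit within the 180-day outcome
  window;
* chronic condition burden, medication counts and age drive risk through
  configurable log-hazard weights;
* event days are skewed earlier for higher-risk patients, so risk groups
  separate on time-to-event curves.

All randomness flows through one ``numpy.random.Generator`` seeded from the
config; identical configs produce byte-identical output.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import vocab

__all__ = [
    "ConfigurationError",
    "SyntheticConfig",
    "EncounterRecord",
    "PatientHistory",
    "generate_population",
    "write_tables",
    "read_tables",
    "TableParseError",
]

VISIT_KINDS = ("ED", "inpatient", "outpatient")
EVENT_KINDS = VISIT_KINDS + ("lab", "radiology", "medication")
DISPOSITIONS = ("routine", "expired", "transfer_from_ed", "other")


class ConfigurationError(ValueError):
    """A SyntheticConfig field is out of contract."""


class TableParseError(ValueError):
    """A CSV row could not be parsed; the message names the row."""


DEFAULT_HAZARD_COEFFICIENTS: dict[str, float] = {
    # log-hazard weight per historical ED visit (capped at 3 visits)
    "prior_ed_count": 2.6,
    "chronic_flag": 0.9,
    # weight on age band scaled to [0, 1] over the four bands
    "age_group": 0.9,
    "n_medications": 0.08,
    "n_chronic_categories": 0.30,
}

# visits beyond this count add no further log-hazard (risk saturates)
_ED_CAP = 3


@dataclass
class SyntheticConfig:
    """Stated world of one synthetic population draw."""

    n_patients: int
    index_date: dt.date = dt.date(2013, 1, 1)
    observation_days: int = 365
    outcome_days: int = 180
    target_incidence: float = 0.115
    hazard_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HAZARD_COEFFICIENTS)
    )
    chronic_prevalence: float = 0.30
    death_rate: float = 0.005
    transfer_rate: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if not isinstance(self.n_patients, (int, np.integer)) or self.n_patients < 0:
            raise ConfigurationError("n_patients must be a non-negative integer")
        if self.observation_days <= 0:
            raise ConfigurationError("observation_days must be > 0")
        if self.outcome_days <= 0:
            raise ConfigurationError("outcome_days must be > 0")
        for name in ("target_incidence", "chronic_prevalence", "death_rate",
                     "transfer_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v!r}")
        if not 0.0 < self.target_incidence < 1.0:
            raise ConfigurationError("target_incidence must lie in (0, 1)")
        unknown = set(self.hazard_coefficients) - set(DEFAULT_HAZARD_COEFFICIENTS)
        if unknown:
            raise ConfigurationError(
                f"hazard_coefficients has unknown drivers: {sorted(unknown)}"
            )


@dataclass
class EncounterRecord:
    """One dated clinical event for one patient."""

    patient_id: str
    date: dt.date
    kind: str
    encounter_type_code: str = ""
    disposition: str = "routine"
    primary_dx: str | None = None
    secondary_dx: list[str] = field(default_factory=list)
    detail: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown encounter kind {self.kind!r}")
        if self.disposition == "transfer_from_ed" and self.kind != "ED":
            raise ValueError("disposition=transfer_from_ed only valid on kind=ED")


@dataclass
class PatientHistory:
    """One patient: demographics plus a date-ordered encounter list.

    ``truth_hazard`` / ``event_flag`` / ``event_day`` are generator
    bookkeeping (the latent 6-month ED event probability and the realized
    outcome); they are persisted in a separate ground-truth table and are
    never exposed to the model.
    """

    patient_id: str
    age: int
    gender: str
    zip_income: float
    zip_education: int
    encounters: list[EncounterRecord] = field(default_factory=list)
    truth_hazard: float = field(default=0.0, compare=False)
    event_flag: int = field(default=0, compare=False)
    event_day: int = field(default=-1, compare=False)

    def sort_encounters(self) -> None:
        self.encounters.sort(
            key=lambda e: (e.date, e.kind, e.encounter_type_code,
                           e.disposition, e.primary_dx or "")
        )


def _solve_intercept(lp: np.ndarray, target: float) -> float:
    """Bisect the logistic intercept so mean sigmoid(a + lp) == target."""
    lo, hi = -20.0, 10.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        m = float(np.mean(1.0 / (1.0 + np.exp(-(mid + lp)))))
        if m < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _sample_days(rng: np.random.Generator, n: int, n_days: int) -> np.ndarray:
    """Uniform day offsets in [1, n_days]."""
    return rng.integers(1, n_days + 1, size=n)


def _pick_dx(rng: np.random.Generator, chronic_fams: Sequence[str]) -> str:
    """Diagnosis for a visit: chronic patients draw their own chronic codes
    60% of the time, otherwise an acute code."""
    if chronic_fams and rng.random() < 0.6:
        fam = chronic_fams[rng.integers(len(chronic_fams))]
        codes = vocab.CHRONIC_CODES_BY_FAMILY[fam]
        return codes[rng.integers(len(codes))]
    return vocab.ACUTE_CODES[rng.integers(len(vocab.ACUTE_CODES))]


def _maybe_secondary(rng: np.random.Generator,
                     chronic_fams: Sequence[str]) -> list[str]:
    if rng.random() < 0.3:
        return [_pick_dx(rng, chronic_fams)]
    return []


def generate_population(config: SyntheticConfig) -> list[PatientHistory]:
    """Draw a full synthetic population from the configured stated world.

    Returns exactly ``config.n_patients`` histories whose encounters span the
    observation window (``observation_days`` before ``index_date``) and the
    outcome window (``outcome_days`` after).  Outcome-window ED events are
    Bernoulli draws from each patient's latent logistic ``truth_hazard``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    coeffs = {**DEFAULT_HAZARD_COEFFICIENTS, **config.hazard_coefficients}

    # ---- patient-level drivers, fully vectorized -------------------------
    age_band = rng.choice(4, size=n, p=[0.20, 0.25, 0.22, 0.33])
    band_lo = np.array([0, 19, 35, 50])
    band_hi = np.array([18, 34, 49, 90])
    age = band_lo[age_band] + rng.integers(
        0, band_hi[age_band] - band_lo[age_band] + 1
    )
    gender = np.where(rng.random(n) < 0.52, "F", "M")
    zip_income = np.round(np.exp(rng.normal(10.8, 0.3, size=n)), 2)
    zip_education = rng.choice([1, 2, 3, 4], size=n, p=[0.10, 0.35, 0.35, 0.20])

    chronic = (rng.random(n) < config.chronic_prevalence).astype(int)
    n_cat = np.where(chronic == 1, 1 + rng.binomial(3, 0.35, size=n), 0)
    has_prior_ed = rng.random(n) < 0.18
    prior_ed = np.where(
        has_prior_ed, 1 + rng.poisson(0.45, size=n), 0
    ).astype(int)
    n_medications = rng.poisson(
        0.8 + 1.5 * chronic + 0.4 * n_cat
    ).astype(int)

    lp = (
        coeffs["prior_ed_count"] * np.minimum(prior_ed, _ED_CAP)
        + coeffs["chronic_flag"] * chronic
        + coeffs["age_group"] * age_band / 3.0
        + coeffs["n_medications"] * n_medications
        + coeffs["n_chronic_categories"] * n_cat
    )
    intercept = _solve_intercept(lp, config.target_incidence)
    hazard = 1.0 / (1.0 + np.exp(-(intercept + lp)))

    event = (rng.random(n) < hazard).astype(int)
    # higher hazard -> earlier event day (power-skewed uniform)
    u = rng.random(n)
    event_day = np.ceil(
        config.outcome_days * u ** (1.0 + 2.5 * hazard)
    ).astype(int)
    event_day = np.clip(event_day, 1, config.outcome_days)
    event_day = np.where(event == 1, event_day, -1)
    # repeat outcome-window visits scale with hazard
    extra_outcome_ed = np.where(
        event == 1, rng.poisson(1.5 * hazard), 0
    ).astype(int)

    died = rng.random(n) < config.death_rate

    # per-patient ancillary counts
    n_outpt_extra = rng.poisson(1.2, size=n)
    inpt = rng.random(n) < (0.05 + 0.05 * chronic)
    n_labs = rng.poisson(1.0 + 0.8 * chronic + 0.3 * n_cat)
    n_rad = rng.poisson(0.3 + 0.2 * chronic)

    obs_days = config.observation_days
    out_days = config.outcome_days
    index = config.index_date
    fams = np.array(vocab.CHAPTER_FAMILIES)

    histories: list[PatientHistory] = []
    for i in range(n):
        pid = f"P{i:07d}"
        chronic_fams = (
            list(rng.choice(fams, size=min(n_cat[i], len(fams)), replace=False))
            if n_cat[i] > 0
            else []
        )
        enc: list[EncounterRecord] = []

        def obs_date(day_offset: int) -> dt.date:
            return index - dt.timedelta(days=int(day_offset))

        def out_date(day_offset: int) -> dt.date:
            return index + dt.timedelta(days=int(day_offset))

        # one outpatient visit per chronic category anchors the chronic codes
        for fam in chronic_fams:
            codes = vocab.CHRONIC_CODES_BY_FAMILY[fam]
            enc.append(EncounterRecord(
                pid, obs_date(_sample_days(rng, 1, obs_days)[0]), "outpatient",
                encounter_type_code=str(rng.choice(
                    vocab.ENCOUNTER_TYPE_CODES["outpatient"])),
                primary_dx=codes[rng.integers(len(codes))],
                secondary_dx=_maybe_secondary(rng, chronic_fams),
            ))
        # historical ED visits
        for d in _sample_days(rng, int(prior_ed[i]), obs_days):
            enc.append(EncounterRecord(
                pid, obs_date(d), "ED", encounter_type_code="ED",
                primary_dx=_pick_dx(rng, chronic_fams),
                secondary_dx=_maybe_secondary(rng, chronic_fams),
            ))
        # other outpatient / inpatient visits
        for d in _sample_days(rng, int(n_outpt_extra[i]), obs_days):
            enc.append(EncounterRecord(
                pid, obs_date(d), "outpatient",
                encounter_type_code=str(rng.choice(
                    vocab.ENCOUNTER_TYPE_CODES["outpatient"])),
                primary_dx=_pick_dx(rng, chronic_fams),
            ))
        if inpt[i]:
            enc.append(EncounterRecord(
                pid, obs_date(_sample_days(rng, 1, obs_days)[0]), "inpatient",
                encounter_type_code=str(rng.choice(
                    vocab.ENCOUNTER_TYPE_CODES["inpatient"])),
                primary_dx=_pick_dx(rng, chronic_fams),
                secondary_dx=_maybe_secondary(rng, chronic_fams),
            ))
        # labs, radiology, prescriptions
        for d in _sample_days(rng, int(n_labs[i]), obs_days):
            name = str(rng.choice(vocab.LAB_NAMES))
            abnormal = rng.random() < (0.25 + 0.2 * chronic[i])
            enc.append(EncounterRecord(
                pid, obs_date(d), "lab",
                detail={"lab_name": name,
                        "result": "abnormal" if abnormal else "normal"},
            ))
        for d in _sample_days(rng, int(n_rad[i]), obs_days):
            enc.append(EncounterRecord(
                pid, obs_date(d), "radiology",
                detail={"modality": str(rng.choice(
                    vocab.RADIOLOGY_MODALITIES))},
            ))
        for d in _sample_days(rng, int(n_medications[i]), obs_days):
            enc.append(EncounterRecord(
                pid, obs_date(d), "medication",
                detail={"medication_class": str(rng.choice(
                    vocab.MEDICATION_CLASSES))},
            ))
        # outcome-window ED events
        if event[i] == 1:
            days = [int(event_day[i])]
            if extra_outcome_ed[i] > 0:
                lo = int(event_day[i])
                days += list(rng.integers(lo, out_days + 1,
                                          size=int(extra_outcome_ed[i])))
            for d in days:
                enc.append(EncounterRecord(
                    pid, out_date(d), "ED", encounter_type_code="ED",
                    primary_dx=_pick_dx(rng, chronic_fams),
                ))
        # expired disposition on one encounter for the death fraction
        if died[i]:
            enc.append(EncounterRecord(
                pid, out_date(_sample_days(rng, 1, out_days)[0]), "inpatient",
                encounter_type_code="inpatient_acute",
                disposition="expired",
                primary_dx=_pick_dx(rng, chronic_fams),
            ))
        # transfer pairs: a fraction of ED visits arrive transferred from
        # another ED as a same-day paired record
        for e in [e for e in enc if e.kind == "ED"
                  and e.disposition == "routine"]:
            if rng.random() < config.transfer_rate:
                enc.append(EncounterRecord(
                    pid, e.date, "ED", encounter_type_code="ED",
                    disposition="transfer_from_ed",
                    primary_dx=e.primary_dx,
                ))

        h = PatientHistory(
            pid, int(age[i]), str(gender[i]), float(zip_income[i]),
            int(zip_education[i]), enc,
            truth_hazard=float(hazard[i]),
            event_flag=int(event[i]), event_day=int(event_day[i]),
        )
        h.sort_encounters()
        histories.append(h)
    return histories


# ---------------------------------------------------------------------------
# CSV persistence

_TABLES = ("patients", "encounters", "labs", "medications", "radiology",
           "ground_truth")


def write_tables(histories: Iterable[PatientHistory],
                 directory: str | Path) -> dict[str, Path]:
    """Write the population as flat CSV tables (dates ISO-8601).

    ``ground_truth.csv`` holds the latent hazard and realized outcome and is
    the only table downstream models must never read.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {t: directory / f"{t}.csv" for t in _TABLES}

    with open(paths["patients"], "w", newline="") as fp, \
         open(paths["encounters"], "w", newline="") as fe, \
         open(paths["labs"], "w", newline="") as fl, \
         open(paths["medications"], "w", newline="") as fm, \
         open(paths["radiology"], "w", newline="") as fr, \
         open(paths["ground_truth"], "w", newline="") as fg:
        wp = csv.writer(fp)
        we = csv.writer(fe)
        wl = csv.writer(fl)
        wm = csv.writer(fm)
        wr = csv.writer(fr)
        wg = csv.writer(fg)
        wp.writerow(["patient_id", "age", "gender", "zip_income",
                     "zip_education"])
        we.writerow(["patient_id", "date", "kind", "encounter_type_code",
                     "disposition", "primary_dx", "secondary_dx"])
        wl.writerow(["patient_id", "date", "lab_name", "result"])
        wm.writerow(["patient_id", "date", "medication_class"])
        wr.writerow(["patient_id", "date", "modality"])
        wg.writerow(["patient_id", "truth_hazard", "event_flag", "event_day"])
        for h in histories:
            wp.writerow([h.patient_id, h.age, h.gender,
                         f"{h.zip_income:.2f}", h.zip_education])
            wg.writerow([h.patient_id, repr(h.truth_hazard), h.event_flag,
                         h.event_day])
            for e in h.encounters:
                iso = e.date.isoformat()
                if e.kind in VISIT_KINDS:
                    we.writerow([e.patient_id, iso, e.kind,
                                 e.encounter_type_code, e.disposition,
                                 e.primary_dx or "",
                                 "|".join(e.secondary_dx)])
                elif e.kind == "lab":
                    wl.writerow([e.patient_id, iso,
                                 e.detail["lab_name"], e.detail["result"]])
                elif e.kind == "medication":
                    wm.writerow([e.patient_id, iso,
                                 e.detail["medication_class"]])
                elif e.kind == "radiology":
                    wr.writerow([e.patient_id, iso, e.detail["modality"]])
    return paths


def _parse_date(value: str, table: str, row: int) -> dt.date:
    try:
        return dt.date.fromisoformat(value)
    except ValueError:
        raise TableParseError(
            f"{table}.csv row {row}: invalid date {value!r}"
        ) from None


def read_tables(directory: str | Path) -> list[PatientHistory]:
    """Read a population previously written by :func:`write_tables`.

    Round-trip identity holds for everything except the ground-truth
    bookkeeping, which is restored from ``ground_truth.csv`` when present.
    """
    directory = Path(directory)
    patients: dict[str, PatientHistory] = {}

    with open(directory / "patients.csv", newline="") as f:
        for irow, row in enumerate(csv.DictReader(f), start=2):
            try:
                patients[row["patient_id"]] = PatientHistory(
                    row["patient_id"], int(row["age"]), row["gender"],
                    float(row["zip_income"]), int(row["zip_education"]), [],
                )
            except (TypeError, ValueError):
                raise TableParseError(
                    f"patients.csv row {irow}: malformed record {row!r}"
                ) from None

    def add(pid: str, rec: EncounterRecord, table: str, irow: int) -> None:
        if pid not in patients:
            raise TableParseError(
                f"{table}.csv row {irow}: unknown patient_id {pid!r}")
        patients[pid].encounters.append(rec)

    with open(directory / "encounters.csv", newline="") as f:
        for irow, row in enumerate(csv.DictReader(f), start=2):
            d = _parse_date(row["date"], "encounters", irow)
            sec = [s for s in row["secondary_dx"].split("|") if s]
            add(row["patient_id"], EncounterRecord(
                row["patient_id"], d, row["kind"],
                encounter_type_code=row["encounter_type_code"],
                disposition=row["disposition"],
                primary_dx=row["primary_dx"] or None,
                secondary_dx=sec,
            ), "encounters", irow)
    with open(directory / "labs.csv", newline="") as f:
        for irow, row in enumerate(csv.DictReader(f), start=2):
            d = _parse_date(row["date"], "labs", irow)
            add(row["patient_id"], EncounterRecord(
                row["patient_id"], d, "lab",
                detail={"lab_name": row["lab_name"],
                        "result": row["result"]},
            ), "labs", irow)
    with open(directory / "medications.csv", newline="") as f:
        for irow, row in enumerate(csv.DictReader(f), start=2):
            d = _parse_date(row["date"], "medications", irow)
            add(row["patient_id"], EncounterRecord(
                row["patient_id"], d, "medication",
                detail={"medication_class": row["medication_class"]},
            ), "medications", irow)
    with open(directory / "radiology.csv", newline="") as f:
        for irow, row in enumerate(csv.DictReader(f), start=2):
            d = _parse_date(row["date"], "radiology", irow)
            add(row["patient_id"], EncounterRecord(
                row["patient_id"], d, "radiology",
                detail={"modality": row["modality"]},
            ), "radiology", irow)

    gt = directory / "ground_truth.csv"
    if gt.exists():
        with open(gt, newline="") as f:
            for irow, row in enumerate(csv.DictReader(f), start=2):
                pid = row["patient_id"]
                if pid in patients:
                    patients[pid].truth_hazard = float(row["truth_hazard"])
                    patients[pid].event_flag = int(row["event_flag"])
                    patients[pid].event_day = int(row["event_day"])

    out = list(patients.values())
    for h in out:
        h.sort_encounters()
    return out
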