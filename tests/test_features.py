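"""Pivot table construction, chronic dichotomy, age bins, variance filter."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from edrisk.features import (
    EMPIRICAL_FEATURES,
    FeatureMatrix,
    assign_age_group,
    build_pivot_table,
    flag_chronic,
    variance_filter,
)
from edrisk.synth import EncounterRecord, PatientHistory

from conftest import OBS_WINDOW, OUT_WINDOW, INDEX_DATE, ed_visit, make_history


def _obs_day(offset):
    return INDEX_DATE - dt.timedelta(days=offset)


def _out_day(offset):
    return INDEX_DATE + dt.timedelta(days=offset - 1)  # day 1 == index date


class TestPivotTable:
    def test_direct_construction(self):
        """3 observation-window ED visits and a first outcome ED visit at
        day 42 give prior_ed_count=3, outcome=1, time_to_event=42."""
        enc = [ed_visit("P1", _obs_day(d)) for d in (30, 90, 200)]
        enc.append(ed_visit("P1", _out_day(42)))
        enc.append(ed_visit("P1", _out_day(100)))
        fm = build_pivot_table([make_history("P1", encounters=enc)],
                               OBS_WINDOW, OUT_WINDOW)
        row = fm.values.loc["P1"]
        assert row["prior_ed_count"] == 3
        assert fm.outcome.loc["P1"] == 1
        assert fm.time_to_event.loc["P1"] == 42
        assert fm.event_observed.loc["P1"] == 1
        assert fm.outcome_ed_count.loc["P1"] == 2

    def test_censored_patient(self):
        enc = [ed_visit("P1", _obs_day(30))]
        fm = build_pivot_table([make_history("P1", encounters=enc)],
                               OBS_WINDOW, OUT_WINDOW)
        assert fm.outcome.loc["P1"] == 0
        assert fm.time_to_event.loc["P1"] == 180
        assert fm.event_observed.loc["P1"] == 0

    def test_new_patient_all_zero_features(self):
        fm = build_pivot_table([make_history("P1")], OBS_WINDOW, OUT_WINDOW)
        counts = fm.values.loc["P1"].drop(
            ["zip_income", "zip_education", "gender_F", "age_35-49"])
        assert (counts == 0).all()

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError, match="overlap|out of order"):
            build_pivot_table([], (INDEX_DATE - dt.timedelta(days=365),
                                   INDEX_DATE),
                              (INDEX_DATE, INDEX_DATE + dt.timedelta(days=179)))

    def test_ed_dummy_sums_match_raw_recount(self, small_population,
                                             small_matrix):
        """Column sum of the ED encounter-type dummy equals a brute-force
        recount of observation-window ED encounters (post-merge)."""
        expected = 0
        for h in small_population:
            if any(e.disposition == "expired" for e in h.encounters):
                continue
            for e in h.encounters:
                if (e.kind == "ED" and e.disposition != "transfer_from_ed"
                        and OBS_WINDOW[0] <= e.date <= OBS_WINDOW[1]):
                    expected += 1
        assert small_matrix.values["enc_type_ED"].sum() == expected
        assert (small_matrix.values["enc_type_ED"]
                == small_matrix.values["prior_ed_count"]).all()

    def test_temporal_hygiene(self):
        """Deleting or permuting outcome-window records never changes any
        feature value (leakage check)."""
        enc = [ed_visit("P1", _obs_day(d)) for d in (10, 50)]
        out_enc = [ed_visit("P1", _out_day(d)) for d in (5, 60, 120)]
        base = build_pivot_table(
            [make_history("P1", encounters=enc + out_enc)],
            OBS_WINDOW, OUT_WINDOW)
        dropped = build_pivot_table(
            [make_history("P1", encounters=enc)], OBS_WINDOW, OUT_WINDOW)
        pd.testing.assert_frame_equal(base.values, dropped.values)

    def test_age_group_dummies_exclusive(self, small_matrix):
        age_cols = [c for c in small_matrix.values.columns
                    if c.startswith("age_")]
        assert sorted(age_cols) == ["age_0-18", "age_19-34", "age_35-49",
                                    "age_50+"]
        assert (small_matrix.values[age_cols].sum(axis=1) == 1).all()

    def test_no_missing_values(self, small_matrix):
        assert not small_matrix.values.isna().any().any()

    def test_save_load_round_trip(self, small_matrix, tmp_path):
        small_matrix.save(tmp_path)
        back = FeatureMatrix.load(tmp_path)
        pd.testing.assert_frame_equal(back.values, small_matrix.values)
        pd.testing.assert_series_equal(back.outcome, small_matrix.outcome)


class TestChronicFlag:
    def test_chronic_code(self):
        assert flag_chronic("250.00") == "chronic"

    def test_acute_code(self):
        assert flag_chronic("845.00") == "non_chronic"

    def test_unknown_code_warns_non_chronic(self):
        with pytest.warns(UserWarning, match="not in chronic-condition"):
            assert flag_chronic("V99.99") == "non_chronic"


class TestAgeGroups:
    @pytest.mark.parametrize("age,label", [
        (0, "0-18"), (18, "0-18"), (19, "19-34"), (34, "19-34"),
        (35, "35-49"), (49, "35-49"), (50, "50+"), (90, "50+"),
    ])
    def test_boundaries(self, age, label):
        assert assign_age_group(age) == label

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            assign_age_group(-1)


def _toy_matrix(values: pd.DataFrame) -> FeatureMatrix:
    n = len(values)
    meta = pd.DataFrame({"name": values.columns,
                         "category": "lab", "source": values.columns})
    idx = values.index
    return FeatureMatrix(values, meta,
                         pd.Series(0, index=idx), pd.Series(180, index=idx),
                         pd.Series(0, index=idx))


class TestVarianceFilter:
    def _base(self, extra: dict) -> FeatureMatrix:
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "prior_ed_count": rng.integers(0, 4, 50).astype(float),
            "chronic_flag": rng.integers(0, 2, 50).astype(float),
            **extra,
        }, index=[f"P{i}" for i in range(50)])
        return _toy_matrix(df)

    def test_constant_column_dropped(self):
        rng = np.random.default_rng(1)
        fm = self._base({"const": np.ones(50),
                         "varying": rng.random(50)})
        out = variance_filter(fm, keep_n=fm.values.shape[1] - 1)
        assert "const" not in out.values.columns
        assert "varying" in out.values.columns

    def test_tie_breaks_lexicographic(self):
        col = np.array([0.0, 1.0] * 25)
        fm = self._base({"zeta": col.copy(), "alpha": col.copy()})
        out = variance_filter(fm, keep_n=3)
        assert "alpha" in out.values.columns

    def test_matches_exhaustive_ranking(self):
        """keep_n=3 on a random 20x10 matrix matches brute-force ranking of
        min-max-scaled variances."""
        rng = np.random.default_rng(7)
        df = pd.DataFrame(rng.random((20, 10)),
                          columns=[f"c{i}" for i in range(10)],
                          index=[f"P{i}" for i in range(20)])
        fm = _toy_matrix(df)
        out = variance_filter(fm, keep_n=3)
        scaled = (df - df.min()) / (df.max() - df.min())
        expected = set(
            sorted(df.columns, key=lambda c: (-scaled[c].var(ddof=1), c))[:3])
        assert set(out.values.columns) == expected

    def test_empirical_features_always_retained(self):
        rng = np.random.default_rng(3)
        fm = self._base({f"x{i}": rng.random(50) * 100 for i in range(8)})
        out = variance_filter(fm, keep_n=2)
        for col in EMPIRICAL_FEATURES:
            assert col in out.values.columns

    def test_keep_n_too_large_is_identity(self, small_matrix):
        out = variance_filter(small_matrix, keep_n=10_000)
        assert out.values.columns.tolist() == small_matrix.values.columns.tolist()

    def test_idempotent(self, small_matrix):
        once = variance_filter(small_matrix, keep_n=15)
        twice = variance_filter(once, keep_n=15)
        assert once.values.columns.tolist() == twice.values.columns.tolist()
        pd.testing.assert_frame_equal(once.values, twice.values)
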