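"""ROC/AUC, PPV tables, Kaplan-Meier, log-rank, shrunken differences."""

import numpy as np
import pandas as pd
import pytest

from edrisk.evaluation import (
    km_curve,
    logrank_test,
    mean_ed_by_group,
    ppv_table,
    roc_auc,
    shrunken_difference,
)


def pair_count_auc(scores, labels):
    """O(n^2) concordance oracle: P(case > control) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_ranking(self):
        auc, _ = roc_auc([0.9, 0.1], [1, 0])
        assert auc == 1.0

    def test_all_ties(self):
        auc, _ = roc_auc([0.5] * 10, [1, 0] * 5)
        assert auc == 0.5

    def test_matches_pair_count_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(20, 200)
            scores = np.round(rng.random(n), 2)  # force ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            auc, _ = roc_auc(scores, labels)
            assert abs(auc - pair_count_auc(scores, labels)) < 1e-12

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="one-class"):
            roc_auc([0.1, 0.2], [1, 1])


class TestPpvTable:
    def test_counts_identity_and_prevalence_at_zero(self):
        rng = np.random.default_rng(1)
        idx = rng.uniform(0, 100, 500)
        labels = rng.integers(0, 2, 500)
        tab = ppv_table(idx, labels, thresholds=[0, 25, 50, 75])
        assert (tab["n_true"] + tab["n_false"] == tab["n_flagged"]).all()
        at0 = tab[tab["threshold"] == 0].iloc[0]
        assert at0["n_flagged"] == 500
        assert at0["ppv"] == pytest.approx(100 * labels.mean())

    def test_zero_flagged_reports_nan(self):
        tab = ppv_table([10.0, 20.0], [1, 0], thresholds=[99.0])
        assert np.isnan(tab.iloc[0]["ppv"])

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 100\]"):
            ppv_table([50.0], [1], thresholds=[120.0])


class TestKaplanMeier:
    def test_no_events_flat_at_one(self):
        curves = km_curve([50, 80, 180], [0, 0, 0], ["g"] * 3)
        assert (curves["g"]["survival"] == 1.0).all()

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(2)
        t = rng.integers(1, 100, 60)
        curves = km_curve(t, np.ones(60, dtype=int), ["g"] * 60)
        for _, row in curves["g"].iterrows():
            emp = (t > row["day"]).mean()
            assert row["survival"] == pytest.approx(emp)

    def test_toy_product_limit_hand_values(self):
        """times (2,3,3,5), events (1,1,0,1): S(2)=3/4, S(3)=1/2, S(5)=0."""
        curves = km_curve([2, 3, 3, 5], [1, 1, 0, 1], ["g"] * 4)
        sf = curves["g"].set_index("day")["survival"]
        assert sf.loc[2.0] == pytest.approx(0.75)
        assert sf.loc[3.0] == pytest.approx(0.5)
        assert sf.loc[5.0] == pytest.approx(0.0)

    def test_curves_non_increasing_start_at_one(self):
        rng = np.random.default_rng(3)
        t = rng.integers(1, 181, 200)
        e = rng.integers(0, 2, 200)
        curves = km_curve(t, e, rng.choice(["a", "b"], 200))
        for df in curves.values():
            s = df["survival"].to_numpy()
            assert s[0] == 1.0  # day 0
            assert (np.diff(s) <= 1e-12).all()


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = [5, 10, 15, 5, 10, 15]
        e = [1, 1, 0, 1, 1, 0]
        g = ["a", "a", "a", "b", "b", "b"]
        stat, p = logrank_test(t, e, g)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_worksheet_two_group_toy(self):
        """Observed-minus-expected tabulation done by hand.

        Group a: times (1, 2) both events; group b: times (2, 3), event at
        3 only (censored at 2).
        day 1: N=4, d=1, n_a=2 -> E_a=0.5, V=0.25
        day 2: N=3, d=1, n_a=1 -> E_a=1/3, V=2/9
        day 3: N=1, d=1, n_a=0 -> E_a=0,  V=0
        O_a=2, E_a=5/6, V=0.25+2/9 => chi2 = (2-5/6)^2/(17/36) = 49/17.
        """
        stat, p = logrank_test([1, 2, 2, 3], [1, 1, 0, 1],
                               ["a", "a", "b", "b"])
        assert stat == pytest.approx(49 / 17, rel=1e-9)

    def test_label_renaming_invariance(self):
        rng = np.random.default_rng(4)
        t = rng.integers(1, 181, 120)
        e = rng.integers(0, 2, 120)
        g = rng.choice(["x", "y", "z"], 120)
        stat1, _ = logrank_test(t, e, g)
        renamed = pd.Series(g).map({"x": "low", "y": "medium",
                                    "z": "high"}).to_numpy()
        stat2, _ = logrank_test(t, e, renamed)
        assert stat1 == pytest.approx(stat2)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            logrank_test([1, 2], [1, 1], ["a", "a"])


class TestMeanEdByGroup:
    def test_simple_mean(self):
        out = mean_ed_by_group([0, 2, 4], ["g", "g", "g"])
        assert out["g"] == 2.0

    def test_all_zero(self):
        out = mean_ed_by_group([0, 0], ["a", "b"])
        assert (out == 0.0).all()

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            mean_ed_by_group([-1], ["a"])


class TestShrunkenDifference:
    def test_identical_feature_all_zero(self):
        X = np.ones((40, 1))
        g = np.array(["a"] * 20 + ["b"] * 20)
        with pytest.warns(UserWarning, match="zero pooled SD"):
            d = shrunken_difference(X, g)
        assert (d.to_numpy() == 0).all()

    def test_full_shrinkage_zeroes_everything(self):
        rng = np.random.default_rng(5)
        X = rng.random((60, 4))
        g = np.array(["a", "b", "c"] * 20)
        d = shrunken_difference(X, g, shrinkage=1e6)
        assert (d.to_numpy() == 0).all()

    def test_two_class_formula_oracle(self):
        """Matches an independent direct evaluation of
        (class mean - overall mean) / (m_k (s + s0)) on a fixed design."""
        rng = np.random.default_rng(6)
        X = np.concatenate([rng.normal(0, 1, (50, 1)),
                            rng.normal(1, 1, (50, 1))])
        g = np.array(["lo"] * 50 + ["hi"] * 50)
        d = shrunken_difference(X, g, shrinkage=0.0)
        # independent oracle
        overall = X.mean()
        ss = (((X[:50] - X[:50].mean()) ** 2).sum()
              + ((X[50:] - X[50:].mean()) ** 2).sum())
        s = np.sqrt(ss / (100 - 2))
        s0 = s  # single feature: median of pooled SDs is itself
        mk = np.sqrt(1 / 50 + 1 / 100)
        expect_lo = (X[:50].mean() - overall) / (mk * (s + s0))
        assert d.loc["f0", "lo"] == pytest.approx(expect_lo)
        assert d.loc["f0", "hi"] == pytest.approx(-expect_lo, rel=1e-6)

    def test_monotone_in_effect_size(self):
        """A larger class-mean gap yields a larger |d| at fixed SD and n."""
        rng = np.random.default_rng(7)
        base = rng.normal(0, 1, 100)
        g = np.array(["a"] * 50 + ["b"] * 50)
        gaps = []
        for delta in (0.5, 1.0, 2.0):
            X = (base + np.where(g == "b", delta, 0.0)).reshape(-1, 1)
            d = shrunken_difference(X, g)
            gaps.append(abs(d.loc["f0", "b"]))
        assert gaps[0] < gaps[1] < gaps[2]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            shrunken_difference(np.ones((5, 1)), np.array(["a"] * 5))
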