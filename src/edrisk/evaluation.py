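"""Blind-test / prospective-style validation of the risk model.

ROC/AUC (c-statistic), PPV-by-threshold tables on the 0-100 risk index,
Kaplan-Meier time-to-event curves by risk group with the k-group log-rank
test, mean outcome-window ED counts per risk group, and shrunken-difference
feature diagnostics (the nearest-shrunken-centroid style standardized
distance between a risk class mean and the overall mean).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

__all__ = [
    "EvaluationReport",
    "roc_auc",
    "ppv_table",
    "km_curve",
    "logrank_test",
    "mean_ed_by_group",
    "shrunken_difference",
    "evaluate",
]

DEFAULT_THRESHOLDS = (30.0, 50.0, 70.0, 80.0)


def roc_auc(scores, labels) -> tuple[float, pd.DataFrame]:
    """c-statistic and ROC curve points.

    The trapezoidal area under the threshold-swept ROC curve equals the
    probability that a random case outscores a random control, with ties
    credited one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC is undefined with one-class labels")
    fpr, tpr, thr = roc_curve(labels, scores)
    value = float(_trapezoid_auc(fpr, tpr))
    curve = pd.DataFrame({"threshold": thr, "fpr": fpr, "tpr": tpr})
    return value, curve


def ppv_table(indices, labels, thresholds=DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """Case-finding yield per risk-index threshold.

    Per threshold t: flagged = {index >= t}; ppv = true positives among
    flagged / flagged; false_flag_rate = 1 - ppv.  A threshold flagging
    nobody reports NaN (undefined), not zero.
    """
    indices = np.asarray(indices, dtype=float)
    labels = np.asarray(labels).astype(int)
    if np.any((np.asarray(thresholds) < 0) | (np.asarray(thresholds) > 100)):
        raise ValueError("thresholds must lie in [0, 100]")
    rows = []
    for t in thresholds:
        flagged = indices >= t
        n_flagged = int(flagged.sum())
        n_true = int(labels[flagged].sum())
        n_false = n_flagged - n_true
        if n_flagged > 0:
            ppv = 100.0 * n_true / n_flagged
            ffr = 100.0 * n_false / n_flagged
        else:
            ppv = np.nan
            ffr = np.nan
        rows.append({"threshold": float(t), "n_flagged": n_flagged,
                     "n_true": n_true, "n_false": n_false,
                     "ppv": ppv, "false_flag_rate": ffr})
    return pd.DataFrame(rows)


def km_curve(time_to_event, event_flags, group_labels) -> dict[str, pd.DataFrame]:
    """Product-limit survival curve per risk group (right censoring)."""
    t = np.asarray(time_to_event, dtype=float)
    e = np.asarray(event_flags, dtype=int)
    g = np.asarray(group_labels)
    out: dict[str, pd.DataFrame] = {}
    for label in pd.unique(g):
        m = g == label
        if not m.any():
            warnings.warn(f"empty group {label!r} omitted from KM curves",
                          stacklevel=2)
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(t[m], e[m])
        sf = kmf.survival_function_
        out[str(label)] = pd.DataFrame({
            "day": sf.index.to_numpy(dtype=float),
            "survival": sf.iloc[:, 0].to_numpy(dtype=float),
        })
    return out


def logrank_test(time_to_event, event_flags, group_labels) -> tuple[float, float]:
    """k-group log-rank chi-square (k-1 df) and its upper-tail p-value."""
    g = pd.Series(np.asarray(group_labels))
    if g.nunique() < 2:
        raise ValueError("log-rank test requires at least two groups")
    res = multivariate_logrank_test(
        np.asarray(time_to_event, dtype=float), g.to_numpy(),
        np.asarray(event_flags, dtype=int))
    return float(res.test_statistic), float(res.p_value)


def mean_ed_by_group(outcome_ed_counts, risk_groups) -> pd.Series:
    """Mean outcome-window ED visit count per risk group."""
    c = np.asarray(outcome_ed_counts, dtype=float)
    if (c < 0).any():
        raise ValueError("ED visit counts must be non-negative")
    s = pd.Series(c).groupby(np.asarray(risk_groups)).mean()
    s.index.name = "risk_group"
    return s


def shrunken_difference(matrix, class_labels, shrinkage: float = 0.0,
                        feature_names=None) -> pd.DataFrame:
    """Per-feature, per-class standardized shrunken mean differences.

    For feature j and class k:
        d_jk = (mean_jk - mean_j) / (m_k * (s_j + s0)),
    where s_j is the pooled within-class standard deviation, s0 the median
    of all s_j, and m_k = sqrt(1/n_k + 1/n).  |d| is soft-thresholded by
    ``shrinkage`` toward zero, preserving sign.  Features with zero pooled
    SD when s0 is also zero are reported as 0 with a warning.
    """
    X = np.asarray(matrix, dtype=float)
    g = np.asarray(class_labels)
    classes = pd.unique(g)
    if len(classes) < 2:
        raise ValueError("shrunken differences require at least two classes")
    if shrinkage < 0:
        raise ValueError("shrinkage must be non-negative")
    n, p = X.shape
    overall = X.mean(axis=0)
    ss = np.zeros(p)
    for k in classes:
        Xk = X[g == k]
        ss += ((Xk - Xk.mean(axis=0)) ** 2).sum(axis=0)
    dof = max(n - len(classes), 1)
    s = np.sqrt(ss / dof)
    s0 = float(np.median(s))
    denom_scale = s + s0
    degenerate = denom_scale == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} feature(s) have zero pooled SD and "
            "zero s0; their shrunken differences are reported as 0",
            stacklevel=2)
        denom_scale = np.where(degenerate, 1.0, denom_scale)
    cols = {}
    for k in classes:
        nk = int((g == k).sum())
        mk = np.sqrt(1.0 / nk + 1.0 / n)
        d = (X[g == k].mean(axis=0) - overall) / (mk * denom_scale)
        d = np.where(degenerate, 0.0, d)
        d = np.sign(d) * np.maximum(np.abs(d) - shrinkage, 0.0)
        cols[str(k)] = d
    idx = (list(feature_names) if feature_names is not None
           else [f"f{j}" for j in range(p)])
    return pd.DataFrame(cols, index=idx)


@dataclass
class EvaluationReport:
    """Everything the blind-test / prospective validation step reports."""

    auc: float
    roc_points: pd.DataFrame
    ppv_table: pd.DataFrame
    km_curves: dict[str, pd.DataFrame]
    logrank_statistic: float
    logrank_p: float
    mean_ed_by_group: pd.Series
    shrunken: pd.DataFrame
    n_patients: int

    def to_json_dict(self) -> dict:
        return {
            "auc": self.auc,
            "n_patients": self.n_patients,
            "ppv_table": self.ppv_table.to_dict(orient="records"),
            "km_curves": {k: v.to_dict(orient="list")
                          for k, v in self.km_curves.items()},
            "logrank": {"statistic": self.logrank_statistic,
                        "p_value": self.logrank_p},
            "mean_ed_by_group": self.mean_ed_by_group.to_dict(),
            "shrunken": self.shrunken.to_dict(orient="index"),
        }

    def save(self, directory: str | Path, stem: str = "report") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / f"{stem}.json", "w") as f:
            json.dump(self.to_json_dict(), f, indent=1, sort_keys=True)
        self.ppv_table.to_csv(directory / f"{stem}_ppv_table.csv",
                              index=False)
        km = pd.concat(
            [v.assign(risk_group=k) for k, v in self.km_curves.items()],
            ignore_index=True) if self.km_curves else pd.DataFrame()
        km.to_csv(directory / f"{stem}_km_curves.csv", index=False)


def evaluate(indices, labels, time_to_event, event_flags, risk_groups,
             outcome_ed_counts, feature_values=None, feature_names=None,
             scores=None, thresholds=DEFAULT_THRESHOLDS,
             shrinkage: float = 0.0) -> EvaluationReport:
    """Assemble the full evaluation report for one scored cohort."""
    scores = np.asarray(indices if scores is None else scores, dtype=float)
    auc_value, curve = roc_auc(scores, labels)
    table = ppv_table(indices, labels, thresholds)
    km = km_curve(time_to_event, event_flags, risk_groups)
    groups = pd.Series(np.asarray(risk_groups))
    if groups.nunique() >= 2:
        stat, p = logrank_test(time_to_event, event_flags, risk_groups)
    else:
        stat, p = np.nan, np.nan
    means = mean_ed_by_group(outcome_ed_counts, risk_groups)
    if feature_values is not None:
        shrunk = shrunken_difference(feature_values, risk_groups, shrinkage,
                                     feature_names)
    else:
        shrunk = pd.DataFrame()
    return EvaluationReport(
        auc=auc_value, roc_points=curve, ppv_table=table, km_curves=km,
        logrank_statistic=stat, logrank_p=p, mean_ed_by_group=means,
        shrunken=shrunk, n_patients=int(len(scores)),
    )
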