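"""PPV-semantics risk index: raw score -> 0-100 with a probability meaning.

The calibrating cohort defines, for each distinct raw score s, the positive
predictive value among patients scored at or above s (as a percentage).  A
running maximum from the lowest score upward makes the curve monotone, and
linear interpolation between the resulting knots maps any raw score to a
0-100 risk index L with the defining property: patients with index >= L
have (approximately) an L% probability of an ED visit within the outcome
window.  Thresholds at 30 and 70 index units split the population into
low / medium / high risk groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "CalibrationError",
    "PPVCalibrator",
    "RiskAssessment",
    "fit_calibration",
    "risk_index",
    "assign_risk_group",
    "T_MEDIUM",
    "T_HIGH",
]

T_MEDIUM = 30.0
T_HIGH = 70.0


class CalibrationError(ValueError):
    """Calibration is undefined (e.g. one-class labels)."""


@dataclass
class RiskAssessment:
    """One patient's scored risk."""

    patient_id: str
    raw_score: float
    risk_index: float
    risk_group: str


def assign_risk_group(index: float) -> str:
    """low if index<30; medium if 30<=index<70; high if index>=70."""
    if not 0.0 <= index <= 100.0:
        raise ValueError(f"risk index must lie in [0, 100], got {index!r}")
    if index < T_MEDIUM:
        return "low"
    if index < T_HIGH:
        return "medium"
    return "high"


class PPVCalibrator(BaseEstimator, TransformerMixin):
    """Monotone raw-score -> risk-index map with PPV semantics.

    Parameters
    ----------
    min_cell : int
        Knot indices are estimated only where at least ``min_cell``
        calibration patients lie at or above the knot score; sparser tails
        inherit the nearest valid knot (variance control).
    """

    def __init__(self, min_cell: int = 50):
        self.min_cell = min_cell

    def fit(self, scores, labels=None) -> "PPVCalibrator":
        scores = np.asarray(scores, dtype=float)
        labels = np.asarray(labels)
        if scores.ndim != 1 or scores.shape != labels.shape:
            raise ValueError("scores and labels must be equal-length 1-D")
        if len(np.unique(labels)) < 2:
            raise CalibrationError(
                "calibration requires both positive and negative labels "
                "(PPV undefined as a gradient otherwise)")
        order = np.argsort(scores, kind="stable")
        s_sorted = scores[order]
        y_sorted = labels[order].astype(float)
        uniq, first_idx = np.unique(s_sorted, return_index=True)
        n = scores.size
        # positives / total at or above each distinct score
        pos_cum = np.cumsum(y_sorted[::-1])[::-1]
        pos_above = pos_cum[first_idx]
        n_above = n - first_idx
        raw_ppv = 100.0 * pos_above / n_above
        valid = n_above >= self.min_cell
        if not valid.any():
            valid = np.zeros_like(valid)
            valid[0] = True  # the full-population knot always exists
        # sparse high tail inherits the highest valid knot's PPV
        idx_valid = np.flatnonzero(valid)
        last_valid = idx_valid[-1]
        ppv = raw_ppv.copy()
        ppv[last_valid + 1:] = raw_ppv[last_valid]
        # monotone correction: running maximum from lowest score upward
        index = np.maximum.accumulate(ppv)
        self.knots_score_ = uniq
        self.knots_index_ = index
        self.n_calibration_ = int(n)
        self.t_m_ = T_MEDIUM
        self.t_h_ = T_HIGH
        return self

    def transform(self, scores) -> np.ndarray:
        """Risk index for raw scores: linear interpolation between knots,
        clamped to the terminal knots outside their range."""
        if not hasattr(self, "knots_score_"):
            raise RuntimeError("PPVCalibrator is not fitted")
        scores = np.asarray(scores, dtype=float)
        return np.interp(scores, self.knots_score_, self.knots_index_)

    def assess(self, patient_ids, scores) -> pd.DataFrame:
        """Per-patient risk assessment table."""
        idx = self.transform(scores)
        groups = [assign_risk_group(v) for v in idx]
        return pd.DataFrame({
            "patient_id": patient_ids,
            "raw_score": np.asarray(scores, dtype=float),
            "risk_index": idx,
            "risk_group": groups,
        })

    def to_dict(self) -> dict:
        return {
            "min_cell": self.min_cell,
            "knots_score": self.knots_score_.tolist(),
            "knots_index": self.knots_index_.tolist(),
            "n_calibration": self.n_calibration_,
            "t_m": T_MEDIUM,
            "t_h": T_HIGH,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PPVCalibrator":
        c = cls(min_cell=d["min_cell"])
        c.knots_score_ = np.asarray(d["knots_score"], dtype=float)
        c.knots_index_ = np.asarray(d["knots_index"], dtype=float)
        c.n_calibration_ = int(d["n_calibration"])
        c.t_m_ = float(d["t_m"])
        c.t_h_ = float(d["t_h"])
        return c


def fit_calibration(scores, labels, min_cell: int = 50) -> PPVCalibrator:
    """Fit the PPV-above-threshold calibration map on Cohort II scores."""
    return PPVCalibrator(min_cell=min_cell).fit(scores, labels)


def risk_index(calibrator: PPVCalibrator, raw_score) -> float | np.ndarray:
    """Map raw score(s) through a fitted calibration to the 0-100 index."""
    out = calibrator.transform(np.atleast_1d(raw_score))
    return float(out[0]) if np.isscalar(raw_score) else out
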