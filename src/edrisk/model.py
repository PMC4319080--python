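"""The active case-finding learner.

A hybrid of prior knowledge and statistical learning:

1. A deterministic 2x2 decision tree on the two empirical features — any
   historical ED visit, any chronic diagnosis — partitions the training
   cohort into four subgroups.
2. Within each subgroup, greedy forward feature selection picks the fewest
   features that maximize out-of-fold case-finding sensitivity in a
   review-capacity slice while holding positive predictive value above a
   target once attainable.
3. A per-subgroup bagged survival-tree forest (log-rank splitting, leaves =
   within-horizon event fraction) scores each patient's probability of an
   ED visit inside the outcome horizon.

``EDRiskModel`` is a scikit-learn-style estimator (``get_params`` /
``set_params`` / ``fit`` / ``predict_proba``); the module-level functions
are thin wrappers over it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .features import FeatureMatrix
from .tree import SurvivalForest

__all__ = [
    "SUBGROUPS",
    "DeterministicPartition",
    "SubgroupModel",
    "EDRiskModel",
    "NotFittedError",
    "partition",
    "select_features",
    "train_subgroup_model",
    "score",
]

SUBGROUPS = ("EDpos_CHRpos", "EDpos_CHRneg", "EDneg_CHRpos", "EDneg_CHRneg")

MODEL_FORMAT_VERSION = 1


class NotFittedError(RuntimeError):
    """Scoring was attempted on an unfitted model."""


class DeterministicPartition:
    """Total 2x2 rule: (any prior ED visit?, any chronic diagnosis?)."""

    @staticmethod
    def subgroup(prior_ed_count: float, chronic_flag: float) -> str:
        ed = "EDpos" if prior_ed_count > 0 else "EDneg"
        chr_ = "CHRpos" if chronic_flag > 0 else "CHRneg"
        return f"{ed}_{chr_}"

    @staticmethod
    def assign(X: pd.DataFrame) -> pd.Series:
        ed = X["prior_ed_count"].to_numpy() > 0
        ch = X["chronic_flag"].to_numpy() > 0
        labels = np.where(
            ed,
            np.where(ch, "EDpos_CHRpos", "EDpos_CHRneg"),
            np.where(ch, "EDneg_CHRpos", "EDneg_CHRneg"),
        )
        return pd.Series(labels, index=X.index, name="subgroup")


def partition(patient_row: Mapping[str, float] | pd.Series) -> str:
    """Route one patient row to its empirical subgroup."""
    return DeterministicPartition.subgroup(
        float(patient_row["prior_ed_count"]),
        float(patient_row["chronic_flag"]),
    )


# ---------------------------------------------------------------------------
# greedy PPV-constrained forward selection

def _slice_metrics(scores: np.ndarray, y: np.ndarray,
                   review_fraction: float) -> tuple[float, float]:
    """(sensitivity, PPV) in the top review_fraction slice of scores."""
    n = y.size
    k = max(1, int(round(review_fraction * n)))
    top = np.argsort(-scores, kind="stable")[:k]
    flagged = y[top]
    n_pos = y.sum()
    sens = flagged.sum() / n_pos if n_pos > 0 else 0.0
    ppv = flagged.mean()
    return float(sens), float(ppv)


def _oof_scores(X: np.ndarray, y: np.ndarray, seed: int,
                n_folds: int) -> np.ndarray:
    """5-fold out-of-fold logistic scores (the selection surrogate)."""
    n_folds = min(n_folds, int(np.bincount(y).min()), y.size)
    n_folds = max(n_folds, 2)
    kf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    out = np.zeros(y.size)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for train, test in kf.split(X, y):
            lr = LogisticRegression(max_iter=200)
            lr.fit(X[train], y[train])
            out[test] = lr.predict_proba(X[test])[:, 1]
    return out


def select_features(
    subgroup_train: FeatureMatrix | pd.DataFrame,
    review_fraction: float = 0.15,
    ppv_target: float = 0.7,
    seed: int = 0,
    y: np.ndarray | None = None,
    max_features: int = 10,
    tol: float = 0.0,
    n_folds: int = 5,
) -> list[str]:
    """Greedy forward selection of the minimal discriminant feature set.

    At each step the candidate feature maximizing out-of-fold sensitivity
    within the top ``review_fraction`` of scored patients is added; once any
    candidate attains PPV >= ``ppv_target`` in that slice, the choice is
    restricted to candidates that keep it.  Stops when the marginal
    sensitivity gain no longer exceeds ``tol`` or ``max_features`` is
    reached.

    Slice sensitivity has granularity 1/n_cases, so ties are common: among
    equal-sensitivity candidates the one with higher out-of-fold AUC wins,
    then the lexicographically smaller name; and a candidate that leaves
    sensitivity unchanged but strictly improves out-of-fold AUC still
    extends the selection (it refines the ranking inside the review slice).
    """
    if isinstance(subgroup_train, FeatureMatrix):
        Xdf = subgroup_train.values
        y = subgroup_train.outcome.to_numpy()
    else:
        Xdf = subgroup_train
        if y is None:
            raise ValueError("y is required when passing a plain DataFrame")
        y = np.asarray(y)
    if not 0.0 < review_fraction < 1.0:
        raise ValueError("review_fraction must lie in (0, 1)")
    if not 0.0 < ppv_target < 1.0:
        raise ValueError("ppv_target must lie in (0, 1)")
    if len(np.unique(y)) < 2:
        raise ValueError("subgroup must contain both cases and controls")

    candidates = [c for c in Xdf.columns if Xdf[c].nunique() > 1]
    Xall = Xdf.to_numpy(dtype=float)
    col_of = {c: i for i, c in enumerate(Xdf.columns)}

    selected: list[str] = []
    # empty-set baselines: random flagging finds review_fraction of cases;
    # an uninformative ranking has AUC 1/2
    best_sens = review_fraction
    best_auc = 0.5
    auc_tol = 1e-4
    first_best: tuple[float, str] | None = None
    while len(selected) < max_features:
        step: list[tuple[str, float, float, float]] = []
        for c in sorted(set(candidates) - set(selected)):
            cols = [col_of[f] for f in selected + [c]]
            scores = _oof_scores(Xall[:, cols], y, seed, n_folds)
            sens, ppv = _slice_metrics(scores, y, review_fraction)
            step.append((c, sens, ppv, float(roc_auc_score(y, scores))))
        if not step:
            break
        feasible = [s for s in step if s[2] >= ppv_target]
        pool = feasible if feasible else step
        # max sensitivity; ties -> higher oof AUC, then smaller name
        name, sens, ppv, auc = sorted(
            pool, key=lambda s: (-s[1], -s[3], s[0]))[0]
        if first_best is None:
            first_best = (sens, name)
        # accept on a sensitivity gain, or on an AUC refinement at equal
        # sensitivity (the slice metric is too coarse to see every gain)
        if sens - best_sens > tol:
            pass
        elif sens - best_sens >= 0 and auc - best_auc > auc_tol:
            pass
        else:
            break
        selected.append(name)
        best_sens = max(best_sens, sens)
        best_auc = max(best_auc, auc)
    if not selected:
        warnings.warn(
            "no feature improved case-finding sensitivity over the empty "
            "set; returning the single best feature", stacklevel=2)
        selected = [first_best[1]] if first_best else candidates[:1]
    return selected


# ---------------------------------------------------------------------------
# per-subgroup models

@dataclass
class SubgroupModel:
    """Scorer for one empirical subgroup."""

    subgroup_id: str
    selected_features: list[str]
    forest: object | None  # SurvivalForest | RandomForestClassifier | None
    constant: float | None = None
    mode: str = "survival"
    training_meta: dict = dc_field(default_factory=dict)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if self.constant is not None:
            return np.full(len(X), self.constant)
        # name-based routing; a feature column absent from X reads as 0
        Xs = X.reindex(columns=self.selected_features, fill_value=0.0)
        A = Xs.to_numpy(dtype=float)
        if self.mode == "survival":
            return self.forest.predict(A)
        return self.forest.predict_proba(A)[:, 1]

    def to_dict(self) -> dict:
        d = {
            "subgroup_id": self.subgroup_id,
            "selected_features": self.selected_features,
            "constant": self.constant,
            "mode": self.mode,
            "training_meta": self.training_meta,
        }
        if self.constant is None and self.mode == "survival":
            d["forest"] = self.forest.to_dict()
        elif self.constant is None:
            raise ValueError(
                "classification-mode forests are not JSON-serializable; "
                "persist survival-mode models")
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SubgroupModel":
        forest = (SurvivalForest.from_dict(d["forest"])
                  if d.get("forest") is not None else None)
        return cls(d["subgroup_id"], list(d["selected_features"]), forest,
                   d["constant"], d["mode"], dict(d["training_meta"]))


def train_subgroup_model(
    subgroup_train: FeatureMatrix,
    selected_features: Sequence[str],
    hyperparams: Mapping | None = None,
    seed: int = 0,
    mode: str = "survival",
) -> SubgroupModel:
    """Fit one subgroup's forest on its selected features.

    A degenerate subgroup (all cases or all controls) yields a constant
    model emitting the subgroup's event fraction.
    """
    hp = {"n_trees": 100, "bootstrap_fraction": 0.8, "max_depth": 8,
          "min_samples_leaf": 25, "max_thresholds": 8,
          "feature_fraction": 0.7}
    hp.update(hyperparams or {})
    y = subgroup_train.outcome.to_numpy()
    sub_id = "custom"
    meta = {"seed": seed, **hp}
    selected = list(selected_features)
    if len(np.unique(y)) < 2:
        return SubgroupModel(sub_id, selected, None,
                             constant=float(y.mean()) if y.size else 0.0,
                             mode=mode, training_meta=meta)
    X = subgroup_train.values[selected].to_numpy(dtype=float)
    if mode == "survival":
        forest = SurvivalForest(
            n_trees=hp["n_trees"],
            bootstrap_fraction=hp["bootstrap_fraction"],
            max_depth=hp["max_depth"],
            min_samples_leaf=hp["min_samples_leaf"],
            max_thresholds=hp["max_thresholds"],
            feature_fraction=hp["feature_fraction"],
            random_state=seed,
        ).fit(X, subgroup_train.time_to_event.to_numpy(),
              subgroup_train.event_observed.to_numpy())
    elif mode == "classification":
        forest = RandomForestClassifier(
            n_estimators=hp["n_trees"],
            max_depth=hp["max_depth"],
            min_samples_leaf=hp["min_samples_leaf"],
            max_samples=hp["bootstrap_fraction"],
            random_state=seed,
        ).fit(X, y)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return SubgroupModel(sub_id, selected, forest, mode=mode,
                         training_meta=meta)


class EDRiskModel(BaseEstimator, ClassifierMixin):
    """Deterministic 2x2 partition + four subgroup survival-tree forests.

    Parameters
    ----------
    n_trees, bootstrap_fraction, max_depth, min_samples_leaf, max_thresholds
        Forest hyperparameters (applied per subgroup).
    review_fraction, ppv_target, max_features, selection_folds, selection_tol
        Greedy forward-selection controls.
    mode : {"survival", "classification"}
        Split criterion family: log-rank survival trees (default) or a
        plain Gini classification forest for comparison.
    random_state : int
        Master seed; per-subgroup seeds are derived by fixed offsets.
    """

    def __init__(self, n_trees: int = 100, bootstrap_fraction: float = 0.8,
                 max_depth: int = 8, min_samples_leaf: int = 25,
                 max_thresholds: int = 8, feature_fraction: float = 0.7,
                 review_fraction: float = 0.15,
                 ppv_target: float = 0.7, max_features: int = 10,
                 selection_folds: int = 5, selection_tol: float = 0.0,
                 mode: str = "survival", random_state: int = 0):
        self.n_trees = n_trees
        self.bootstrap_fraction = bootstrap_fraction
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.max_thresholds = max_thresholds
        self.feature_fraction = feature_fraction
        self.review_fraction = review_fraction
        self.ppv_target = ppv_target
        self.max_features = max_features
        self.selection_folds = selection_folds
        self.selection_tol = selection_tol
        self.mode = mode
        self.random_state = random_state

    # -- fitting ----------------------------------------------------------
    def fit(self, X: pd.DataFrame, y, times=None, events=None):
        """Fit the four subgroup models.

        ``X`` must be a DataFrame carrying ``prior_ed_count`` and
        ``chronic_flag`` columns; ``y`` is the binary outcome;
        ``times``/``events`` give time-to-first-event with censor flags
        (required in survival mode).
        """
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a pandas DataFrame (name-based routing)")
        for col in ("prior_ed_count", "chronic_flag"):
            if col not in X.columns:
                raise ValueError(f"X must carry the empirical feature {col!r}")
        y = pd.Series(np.asarray(y), index=X.index)
        if self.mode == "survival":
            if times is None or events is None:
                raise ValueError("survival mode requires times and events")
            times = pd.Series(np.asarray(times), index=X.index)
            events = pd.Series(np.asarray(events), index=X.index)

        groups = DeterministicPartition.assign(X)
        self.submodels_ = {}
        self.selected_features_ = {}
        for k, sub in enumerate(SUBGROUPS):
            sub_seed = (int(self.random_state) * 16 + k) % (2**31 - 1)
            mask = (groups == sub).to_numpy()
            Xs, ys = X.loc[mask], y.loc[mask].to_numpy()
            if mask.sum() == 0:
                sm = SubgroupModel(sub, [], None,
                                   constant=float(y.mean()), mode=self.mode,
                                   training_meta={"seed": sub_seed,
                                                  "empty_subgroup": True})
            elif len(np.unique(ys)) < 2:
                sm = SubgroupModel(sub, [], None, constant=float(ys.mean()),
                                   mode=self.mode,
                                   training_meta={"seed": sub_seed})
            else:
                feats = select_features(
                    Xs, review_fraction=self.review_fraction,
                    ppv_target=self.ppv_target, seed=sub_seed, y=ys,
                    max_features=self.max_features, tol=self.selection_tol,
                    n_folds=self.selection_folds,
                )
                fm = FeatureMatrix(
                    Xs, pd.DataFrame({"name": Xs.columns}),
                    y.loc[mask],
                    times.loc[mask] if times is not None
                    else pd.Series(1, index=Xs.index),
                    events.loc[mask] if events is not None
                    else y.loc[mask],
                )
                sm = train_subgroup_model(
                    fm, feats,
                    {"n_trees": self.n_trees,
                     "bootstrap_fraction": self.bootstrap_fraction,
                     "max_depth": self.max_depth,
                     "min_samples_leaf": self.min_samples_leaf,
                     "max_thresholds": self.max_thresholds,
                     "feature_fraction": self.feature_fraction},
                    seed=sub_seed, mode=self.mode,
                )
                sm.subgroup_id = sub
            self.submodels_[sub] = sm
            self.selected_features_[sub] = list(sm.selected_features)
        self.classes_ = np.array([0, 1])
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def fit_matrix(self, matrix: FeatureMatrix) -> "EDRiskModel":
        """Convenience: fit from a FeatureMatrix."""
        return self.fit(matrix.values, matrix.outcome,
                        matrix.time_to_event, matrix.event_observed)

    # -- scoring ----------------------------------------------------------
    def predict_score(self, X: pd.DataFrame) -> np.ndarray:
        """Raw risk score in [0, 1]: each row routed through the partition
        to its subgroup forest."""
        if not hasattr(self, "submodels_"):
            raise NotFittedError("EDRiskModel is not fitted")
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a pandas DataFrame (name-based routing)")
        groups = DeterministicPartition.assign(X)
        out = np.empty(len(X))
        for sub, sm in self.submodels_.items():
            mask = (groups == sub).to_numpy()
            if mask.any():
                out[mask] = sm.predict(X.loc[mask])
        return np.clip(out, 0.0, 1.0)

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        s = self.predict_score(X)
        return np.column_stack([1.0 - s, s])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_score(X) >= 0.5).astype(int)

    # -- persistence ------------------------------------------------------
    def to_json_dict(self) -> dict:
        if not hasattr(self, "submodels_"):
            raise NotFittedError("EDRiskModel is not fitted")
        return {
            "format_version": MODEL_FORMAT_VERSION,
            "params": self.get_params(),
            "partition": {"rule": "prior_ed_count>0 x chronic_flag>0",
                          "subgroups": list(SUBGROUPS)},
            "submodels": {k: v.to_dict() for k, v in self.submodels_.items()},
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w") as f:
            json.dump(self.to_json_dict(), f)

    @classmethod
    def load(cls, path: str | Path) -> "EDRiskModel":
        with open(path) as f:
            d = json.load(f)
        if d.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format version {d.get('format_version')!r}")
        m = cls(**d["params"])
        m.submodels_ = {k: SubgroupModel.from_dict(v)
                        for k, v in d["submodels"].items()}
        m.selected_features_ = {k: list(v.selected_features)
                                for k, v in m.submodels_.items()}
        m.classes_ = np.array([0, 1])
        return m


def score(model: EDRiskModel, patient_row) -> np.ndarray | float:
    """Raw score(s) for a patient row (Series/dict) or a DataFrame."""
    if isinstance(patient_row, pd.DataFrame):
        return model.predict_score(patient_row)
    row = pd.DataFrame([pd.Series(patient_row)])
    return float(model.predict_score(row)[0])
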