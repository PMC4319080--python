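"""Bagged survival trees with log-rank split search.

Each tree recursively splits on the feature/threshold pair maximizing the
two-sample log-rank chi-square statistic on (time-to-event, event) restricted
to the outcome horizon; leaves predict the empirical within-horizon event
fraction.  The forest score is the mean of leaf predictions over bootstrap
resamples, i.e. an estimate of the patient's probability of an event within
the horizon.

Numerical choices
-----------------
* Candidate thresholds per feature per node: at most ``max_thresholds``
  quantile midpoints of the node's observed values.
* The log-rank statistic is evaluated on the node's distinct event days,
  quantile-coarsened to at most 24 time points when there are more; with
  administrative censoring only (everyone censored at the horizon), this
  loses little and keeps split search to a pair of matrix products.
* Leaf value is the plain event-flag mean: with censoring only at the
  horizon this equals the within-horizon event fraction.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SurvivalTree", "SurvivalForest"]

_MAX_TIME_POINTS = 24


def _logrank_grid(times: np.ndarray, events: np.ndarray):
    """Event-time grid plus per-sample one-hot / at-risk matrices."""
    ev_times = np.unique(times[events == 1])
    if ev_times.size == 0:
        return None
    if ev_times.size > _MAX_TIME_POINTS:
        qs = np.linspace(0, 1, _MAX_TIME_POINTS)
        grid = np.unique(np.quantile(ev_times, qs, method="lower"))
    else:
        grid = ev_times
    # bin index of each event time: largest grid value <= t
    bin_idx = np.searchsorted(grid, times, side="right") - 1
    n, T = times.size, grid.size
    D = np.zeros((n, T))
    rows = np.flatnonzero((events == 1) & (bin_idx >= 0))
    D[rows, bin_idx[rows]] = 1.0
    R = (times[:, None] >= grid[None, :]).astype(float)
    return grid, D, R


def _best_split(X: np.ndarray, times: np.ndarray, events: np.ndarray,
                min_leaf: int, max_thresholds: int):
    """Return (feature, threshold, stat) of the best log-rank split, or None."""
    pack = _logrank_grid(times, events)
    if pack is None:
        return None
    _, D, R = pack
    d = D.sum(axis=0)          # events per time point
    N = R.sum(axis=0)          # at risk per time point

    masks = []
    meta = []
    for j in range(X.shape[1]):
        col = X[:, j]
        uniq = np.unique(col)
        if uniq.size < 2:
            continue
        if uniq.size - 1 > max_thresholds:
            qs = np.linspace(0, 1, max_thresholds + 2)[1:-1]
            cand = np.unique(np.quantile(col, qs, method="lower"))
            cand = cand[cand < uniq[-1]]
        else:
            cand = uniq[:-1]
        for thr in cand:
            m = col <= thr
            nl = int(m.sum())
            if nl < min_leaf or (col.size - nl) < min_leaf:
                continue
            masks.append(m)
            meta.append((j, float(thr)))
    if not masks:
        return None
    M = np.asarray(masks, dtype=float)
    d1 = M @ D                 # group-1 events per time point
    n1 = M @ R                 # group-1 at risk per time point
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(N > 0, n1 / N, 0.0)
        E1 = frac * d
        V = d * frac * (1.0 - frac) * np.where(N > 1, (N - d) / (N - 1), 0.0)
    O1 = d1.sum(axis=1)
    var = V.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(var > 0, (O1 - E1.sum(axis=1)) ** 2 / var, 0.0)
    best = int(np.argmax(stat))
    if stat[best] <= 0.0:
        return None
    j, thr = meta[best]
    return j, thr, float(stat[best])


class SurvivalTree:
    """One log-rank-splitting survival tree (internal to the forest)."""

    def __init__(self, max_depth: int = 8, min_samples_leaf: int = 25,
                 max_thresholds: int = 8):
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.max_thresholds = max_thresholds
        self.root_: dict | None = None

    def fit(self, X: np.ndarray, times: np.ndarray,
            events: np.ndarray) -> "SurvivalTree":
        X = np.asarray(X, dtype=float)
        times = np.asarray(times, dtype=float)
        events = np.asarray(events, dtype=int)
        self.root_ = self._grow(X, times, events, depth=0)
        return self

    def _grow(self, X, times, events, depth) -> dict:
        leaf = {"leaf": True, "value": float(events.mean()),
                "n": int(events.size)}
        if (depth >= self.max_depth
                or events.size < 2 * self.min_samples_leaf
                or events.min() == events.max()):
            return leaf
        found = _best_split(X, times, events, self.min_samples_leaf,
                            self.max_thresholds)
        if found is None:
            return leaf
        j, thr, stat = found
        m = X[:, j] <= thr
        return {
            "leaf": False, "feature": int(j), "threshold": thr,
            "stat": stat, "n": int(events.size),
            "left": self._grow(X[m], times[m], events[m], depth + 1),
            "right": self._grow(X[~m], times[~m], events[~m], depth + 1),
        }

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.root_ is None:
            raise RuntimeError("tree is not fitted")
        X = np.asarray(X, dtype=float)
        out = np.empty(X.shape[0])
        stack = [(self.root_, np.arange(X.shape[0]))]
        while stack:
            node, idx = stack.pop()
            if idx.size == 0:
                continue
            if node["leaf"]:
                out[idx] = node["value"]
            else:
                m = X[idx, node["feature"]] <= node["threshold"]
                stack.append((node["left"], idx[m]))
                stack.append((node["right"], idx[~m]))
        return out

    def to_dict(self) -> dict:
        return {"max_depth": self.max_depth,
                "min_samples_leaf": self.min_samples_leaf,
                "max_thresholds": self.max_thresholds,
                "root": self.root_}

    @classmethod
    def from_dict(cls, d: dict) -> "SurvivalTree":
        t = cls(d["max_depth"], d["min_samples_leaf"], d["max_thresholds"])
        t.root_ = d["root"]
        return t


class SurvivalForest:
    """Bagged log-rank survival trees; score = mean leaf event fraction.

    Each tree sees a bootstrap resample of the rows and a random
    ``feature_fraction`` of the columns.  Feature subsampling decorrelates
    the trees — with predominantly small-integer count features, otherwise
    every bootstrap finds the same greedy splits and the ensemble collapses
    onto a handful of distinct scores, which coarsens the risk-index
    calibration downstream.
    """

    def __init__(self, n_trees: int = 100, bootstrap_fraction: float = 0.8,
                 max_depth: int = 8, min_samples_leaf: int = 25,
                 max_thresholds: int = 8, feature_fraction: float = 0.7,
                 random_state: int = 0):
        self.n_trees = n_trees
        self.bootstrap_fraction = bootstrap_fraction
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.max_thresholds = max_thresholds
        self.feature_fraction = feature_fraction
        self.random_state = random_state
        self.trees_: list[SurvivalTree] = []
        self.tree_columns_: list[list[int]] = []

    def fit(self, X: np.ndarray, times: np.ndarray,
            events: np.ndarray) -> "SurvivalForest":
        X = np.asarray(X, dtype=float)
        times = np.asarray(times, dtype=float)
        events = np.asarray(events, dtype=int)
        rng = np.random.default_rng(self.random_state)
        n, p = X.shape
        m = max(1, int(round(self.bootstrap_fraction * n)))
        k = max(1, int(round(self.feature_fraction * p)))
        self.trees_ = []
        self.tree_columns_ = []
        for _ in range(self.n_trees):
            idx = rng.integers(0, n, size=m)
            cols = np.sort(rng.choice(p, size=k, replace=False))
            tree = SurvivalTree(self.max_depth, self.min_samples_leaf,
                                self.max_thresholds)
            tree.fit(X[np.ix_(idx, cols)], times[idx], events[idx])
            self.trees_.append(tree)
            self.tree_columns_.append([int(c) for c in cols])
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self.trees_:
            raise RuntimeError("forest is not fitted")
        X = np.asarray(X, dtype=float)
        acc = np.zeros(X.shape[0])
        for t, cols in zip(self.trees_, self.tree_columns_):
            acc += t.predict(X[:, cols])
        return acc / len(self.trees_)

    def to_dict(self) -> dict:
        return {
            "n_trees": self.n_trees,
            "bootstrap_fraction": self.bootstrap_fraction,
            "max_depth": self.max_depth,
            "min_samples_leaf": self.min_samples_leaf,
            "max_thresholds": self.max_thresholds,
            "feature_fraction": self.feature_fraction,
            "random_state": self.random_state,
            "trees": [t.to_dict() for t in self.trees_],
            "tree_columns": self.tree_columns_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SurvivalForest":
        f = cls(d["n_trees"], d["bootstrap_fraction"], d["max_depth"],
                d["min_samples_leaf"], d["max_thresholds"],
                d.get("feature_fraction", 1.0), d["random_state"])
        f.trees_ = [SurvivalTree.from_dict(td) for td in d["trees"]]
        f.tree_columns_ = [list(c) for c in d["tree_columns"]]
        return f
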