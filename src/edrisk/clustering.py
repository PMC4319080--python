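"""High-risk subpopulation phenotyping: PCA + seeded K-means (K=6).

Patients with risk index >= 70 are standardized, projected onto the fewest
principal components reaching a cumulative explained-variance target, and
clustered with best-of-restarts K-means using greedy farthest-point
initialization (the first center of each restart is a seeded random pick,
the rest maximize distance to the chosen set).  Cluster profiles report
age/gender composition, chronic ICD-chapter prevalences as n/N fractions,
and mean lab / radiology / prescription counts, ordered by cluster size.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from . import vocab
from .features import FeatureMatrix

__all__ = [
    "HighRiskClusterer",
    "reduce_dimensions",
    "kmeans_cluster",
    "profile_clusters",
]


def reduce_dimensions(matrix, variance_target: float = 0.8):
    """Center/unit-scale features and keep the fewest leading principal
    components whose cumulative explained variance reaches the target.

    Returns (projected ndarray, loadings DataFrame-like ndarray, explained
    variance ratios of the retained components).
    """
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("dimension reduction requires at least 2 patients")
    if not 0.0 < variance_target <= 1.0:
        raise ValueError("variance_target must lie in (0, 1]")
    scaler = StandardScaler()
    # constant columns scale to 0 and carry no variance
    with np.errstate(invalid="ignore"):
        Z = scaler.fit_transform(X)
    Z = np.nan_to_num(Z, nan=0.0, posinf=0.0, neginf=0.0)
    pca = PCA(svd_solver="full")
    proj = pca.fit_transform(Z)
    ratios = pca.explained_variance_ratio_
    cum = np.cumsum(ratios)
    # numeric-rank guard: variance_target=1.0 keeps exactly rank components
    m = int(np.searchsorted(cum, variance_target - 1e-10) + 1)
    m = min(m, int((pca.explained_variance_ > 1e-12).sum()) or 1)
    return proj[:, :m], pca.components_[:m].T, ratios[:m]


def _farthest_point_centers(X: np.ndarray, k: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Greedy maximin initialization: random first center, then repeatedly
    the point farthest from the chosen set."""
    centers = [X[rng.integers(X.shape[0])]]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for _ in range(1, k):
        nxt = int(np.argmax(d2))
        centers.append(X[nxt])
        d2 = np.minimum(d2, ((X - centers[-1]) ** 2).sum(axis=1))
    return np.asarray(centers)


def kmeans_cluster(projected, k: int = 6, seed: int = 0,
                   restarts: int = 25) -> np.ndarray:
    """Best-of-restarts seeded K-means with farthest-point initialization.

    Deterministic given the seed; the restart with the lowest within-cluster
    sum of squares wins.
    """
    X = np.asarray(projected, dtype=float)
    if k > X.shape[0]:
        raise ValueError(
            f"k={k} exceeds the number of patients ({X.shape[0]})")
    rng = np.random.default_rng(seed)
    best_labels, best_inertia = None, np.inf
    for _ in range(restarts):
        centers = _farthest_point_centers(X, k, rng)
        km = KMeans(n_clusters=k, init=centers, n_init=1, random_state=0)
        labels = km.fit_predict(X)
        if km.inertia_ < best_inertia:
            best_inertia = km.inertia_
            best_labels = labels
    return best_labels


class HighRiskClusterer(BaseEstimator, ClusterMixin):
    """Standardize -> PCA (cumulative-variance cutoff) -> seeded K-means.

    Parameters
    ----------
    n_clusters : int, default 6
        Number of phenotype clusters.
    variance_target : float, default 0.8
        Cumulative explained-variance fraction retained by PCA.
    restarts : int, default 25
        K-means restarts; lowest within-cluster sum of squares wins.
    random_state : int
        Seed for initialization.
    """

    def __init__(self, n_clusters: int = 6, variance_target: float = 0.8,
                 restarts: int = 25, random_state: int = 0):
        self.n_clusters = n_clusters
        self.variance_target = variance_target
        self.restarts = restarts
        self.random_state = random_state

    def fit(self, X, y=None) -> "HighRiskClusterer":
        proj, loadings, ratios = reduce_dimensions(X, self.variance_target)
        self.labels_ = kmeans_cluster(proj, self.n_clusters,
                                      self.random_state, self.restarts)
        self.projection_ = proj
        self.component_loadings_ = loadings
        self.explained_variance_ratio_ = ratios
        self.n_components_ = proj.shape[1]
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_


def profile_clusters(assignments, highrisk_matrix: FeatureMatrix) -> pd.DataFrame:
    """Per-cluster phenotype profiles, ordered by cluster size descending.

    Reports age-band and gender composition, chronic ICD-chapter-family
    prevalences with explicit n/N, and mean lab / radiology / medication
    counts.  Clusters are renumbered 1..K by size; an empty cluster yields
    a row with N=0 and NaN prevalences.
    """
    a = np.asarray(assignments)
    vals = highrisk_matrix.values
    if len(a) != len(vals):
        raise ValueError("assignments must cover the matrix rows")
    lab_cols = [c for c in vals.columns if c.startswith("lab_")]
    rad_cols = [c for c in vals.columns if c.startswith("rad_")]
    med_cols = ["n_medications"] if "n_medications" in vals.columns else [
        c for c in vals.columns if c.startswith("med_")]

    uniq = pd.unique(a)
    sizes = {k: int((a == k).sum()) for k in uniq}
    order = sorted(uniq, key=lambda k: (-sizes[k], str(k)))
    rows = []
    for rank, k in enumerate(order, start=1):
        m = a == k
        N = int(m.sum())
        row: dict[str, object] = {"cluster": rank, "n": N,
                                  "source_label": k}
        sub = vals.loc[m]
        for g in vocab.AGE_GROUPS:
            col = f"age_{g}"
            row[f"share_age_{g}"] = (float(sub[col].mean())
                                     if N and col in sub else np.nan)
        row["share_female"] = (float(sub["gender_F"].mean())
                               if N and "gender_F" in sub else np.nan)
        for fam in vocab.CHAPTER_FAMILIES:
            col = f"chronic_cat_{fam}"
            if N and col in sub.columns:
                n_with = int((sub[col] > 0).sum())
                row[f"prev_{fam}"] = n_with / N
                row[f"prev_{fam}_n"] = n_with
            else:
                row[f"prev_{fam}"] = np.nan
                row[f"prev_{fam}_n"] = 0
            row[f"prev_{fam}_N"] = N
        row["mean_lab_count"] = (float(sub[lab_cols].sum(axis=1).mean())
                                 if N and lab_cols else np.nan)
        row["mean_radiology_count"] = (
            float(sub[rad_cols].sum(axis=1).mean()) if N and rad_cols
            else np.nan)
        row["mean_medication_count"] = (
            float(sub[med_cols].sum(axis=1).mean()) if N and med_cols
            else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
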