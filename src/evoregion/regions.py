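"""Evoregion classification.

Grid-cell assemblages ordinated on PCPS axes are grouped into evoregions in
three steps: the number of groups k is chosen by the elbow of the k-means
within-cluster sum-of-squares curve, cells are partitioned by best-of-restarts
k-means, and the partition is refined by a discriminant analysis of principal
components (DAPC): PCA reduction followed by linear discriminant analysis on
the k-means labels, which yields per-cell posterior membership probabilities.
Regions are renamed A, B, ... by descending cell count.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

__all__ = [
    "Regionalization",
    "elbow_k",
    "kmeans_cluster",
    "dapc_assign",
    "classify_evoregions",
    "EvoregionClassifier",
]


def _region_names(k: int) -> list[str]:
    letters = string.ascii_uppercase
    if k <= len(letters):
        return list(letters[:k])
    return [f"R{i + 1}" for i in range(k)]


@dataclass
class Regionalization:
    """Cell-to-evoregion assignment with discriminant posteriors.

    ``labels`` is a Series (index = cell ids) of region letters;
    ``assignment_probability`` has one column per region and rows summing
    to 1; ``provenance`` records k, seeds and the ordination eigenvalues.
    """

    labels: pd.Series
    assignment_probability: pd.DataFrame
    k: int
    provenance: dict = field(default_factory=dict)

    @classmethod
    def from_labels(cls, labels: pd.Series) -> "Regionalization":
        """Wrap a plain cell -> label Series (one-hot posteriors)."""
        labels = pd.Series(labels)
        post = pd.get_dummies(labels).astype(float)
        return cls(labels=labels, assignment_probability=post,
                   k=labels.nunique())

    @property
    def cell_ids(self) -> np.ndarray:
        return self.labels.index.to_numpy()

    @property
    def regions(self) -> list[str]:
        return list(self.assignment_probability.columns)

    def to_frame(self) -> pd.DataFrame:
        out = self.assignment_probability.copy()
        out.insert(0, "evoregion", self.labels)
        out.index.name = "cell_id"
        return out


def _wss_curve(x: np.ndarray, k_max: int, restarts: int, seed: int) -> np.ndarray:
    wss = np.empty(k_max)
    centroid = x.mean(axis=0)
    wss[0] = float(((x - centroid) ** 2).sum())
    for k in range(2, k_max + 1):
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed, tol=1e-6)
        km.fit(x)
        wss[k - 1] = km.inertia_
    return wss


def elbow_k(x, k_max: int = 10, restarts: int = 20, seed: int = 0) -> int:
    """Choose k at the elbow of the within-cluster sum-of-squares curve.

    The elbow is the k whose (k, WSS) point lies farthest (perpendicular
    distance) from the chord joining (1, WSS_1) and (k_max, WSS_kmax); ties
    go to the smaller k.  Degenerate input (all rows identical) returns 1.
    """
    x = np.asarray(x, dtype=float)
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if x.shape[0] < k_max + 1:
        raise ValueError("need at least k_max + 1 cells")
    if np.allclose(x, x[0]):
        return 1
    wss = _wss_curve(x, k_max, restarts, seed)
    ks = np.arange(1, k_max + 1, dtype=float)
    p1 = np.array([ks[0], wss[0]])
    p2 = np.array([ks[-1], wss[-1]])
    chord = p2 - p1
    norm = np.hypot(*chord)
    # distance of each curve point to the chord; |cross product| / |chord|
    dist = np.abs(chord[0] * (wss - p1[1]) - chord[1] * (ks - p1[0])) / norm
    return int(ks[int(np.argmax(dist))])


def kmeans_cluster(x, k: int, restarts: int = 20, seed: int = 0) -> np.ndarray:
    """Best-of-restarts k-means partition (labels 0..k-1), deterministic per seed."""
    x = np.asarray(x, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    n_distinct = np.unique(x, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the {n_distinct} distinct rows")
    if k == 1:
        return np.zeros(x.shape[0], dtype=int)
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed, tol=1e-6)
    return km.fit_predict(x)


def dapc_assign(x, initial_labels, n_pca: int | str = "auto") -> tuple[np.ndarray, np.ndarray]:
    """Discriminant analysis of principal components.

    PCA-reduces ``x`` (default: smallest number of components explaining at
    least 90% of the variance, capped at n_cells/3) and fits a linear
    discriminant analysis on the initial k-means labels.  Returns
    ``(labels, posteriors)`` where labels are the argmax of the per-cell
    posterior probabilities over groups.
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(initial_labels)
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("DAPC needs at least 2 groups")
    if counts.min() < 2:
        raise ValueError("every group needs at least 2 members")
    if n_pca == "auto":
        full = PCA().fit(x)
        cum = np.cumsum(full.explained_variance_ratio_)
        n_90 = int(np.searchsorted(cum, 0.90) + 1)
        cap = max(1, x.shape[0] // 3)
        n_comp = min(n_90, cap, x.shape[1])
    else:
        n_comp = min(int(n_pca), x.shape[1], x.shape[0])
    scores = PCA(n_components=n_comp).fit_transform(x)
    lda = LinearDiscriminantAnalysis(solver="svd")
    try:
        lda.fit(scores, labels)
    except np.linalg.LinAlgError:
        warnings.warn("singular within-group covariance; regularizing")
        scores = scores + np.random.default_rng(0).normal(0, 1e-8, scores.shape)
        lda.fit(scores, labels)
    post = lda.predict_proba(scores)
    new_labels = lda.classes_[np.argmax(post, axis=1)]
    return new_labels, post


class EvoregionClassifier(ClusterMixin, BaseEstimator):
    """Cluster ordination axes into evoregions (elbow k-means + DAPC).

    Parameters
    ----------
    k : int or "elbow"
        Number of evoregions, or "elbow" to select it from the WSS curve.
    k_max, restarts : int
        Elbow search range and k-means restarts.
    n_pca : int or "auto"
        Retained principal components for the discriminant step.
    random_state : int
        Seed for all stochastic stages.

    Attributes
    ----------
    k_ : selected number of evoregions.
    labels_ : region letter per cell (A, B, ... by descending count).
    posterior_ : DataFrame of per-cell membership probabilities.
    wss_ : within-cluster sum-of-squares curve used by the elbow.
    """

    def __init__(self, k: int | str = "elbow", k_max: int = 10,
                 restarts: int = 20, n_pca: int | str = "auto",
                 random_state: int = 0):
        self.k = k
        self.k_max = k_max
        self.restarts = restarts
        self.n_pca = n_pca
        self.random_state = random_state

    def fit(self, X, y=None):
        index = X.index if isinstance(X, pd.DataFrame) else pd.RangeIndex(len(X))
        x = np.asarray(X, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        if self.k == "elbow":
            k = elbow_k(x, k_max=self.k_max, restarts=self.restarts,
                        seed=self.random_state)
        else:
            k = int(self.k)
        if k == 1:
            labels = np.array(["A"] * x.shape[0])
            post_df = pd.DataFrame(np.ones((x.shape[0], 1)),
                                   index=index, columns=["A"])
        else:
            initial = kmeans_cluster(x, k, restarts=self.restarts,
                                     seed=self.random_state)
            final, post = dapc_assign(x, initial, n_pca=self.n_pca)
            # posterior columns follow sorted(unique(initial)); rename groups
            # to letters by descending final cell count (ties: group id)
            classes = np.unique(initial)
            counts = np.array([(final == c).sum() for c in classes])
            order = np.lexsort((classes, -counts))
            names = _region_names(len(classes))
            mapping = {classes[g]: names[i] for i, g in enumerate(order)}
            labels = np.array([mapping[c] for c in final])
            post_df = pd.DataFrame(post[:, order], index=index, columns=names)
        self.k_ = len(np.unique(labels))
        self.labels_ = pd.Series(labels, index=index, name="evoregion")
        self.posterior_ = post_df
        self.wss_ = _wss_curve(x, self.k_max, self.restarts, self.random_state) \
            if self.k == "elbow" else None
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_.to_numpy()


def classify_evoregions(
    p: pd.DataFrame,
    var_threshold: float = 0.05,
    k_max: int = 10,
    restarts: int = 20,
    seed: int = 0,
    k: int | str = "elbow",
) -> Regionalization:
    """Full classification pipeline from the fuzzy composition matrix P.

    sqrt-Bray-Curtis -> PCoA (axes with > ``var_threshold`` variance) ->
    elbow k -> k-means -> DAPC.  Returns a :class:`Regionalization` whose
    provenance records k, the eigenvalue spectrum and the seed.
    """
    from .fuzzy import PCPS, sqrt_bray_curtis

    if sqrt_bray_curtis(p).to_numpy().max() < 1e-12:
        # all assemblages identical: a single degenerate evoregion
        labels = pd.Series(["A"] * len(p), index=p.index, name="evoregion")
        post = pd.DataFrame(np.ones((len(p), 1)), index=p.index, columns=["A"])
        return Regionalization(labels=labels, assignment_probability=post,
                               k=1, provenance={"k": 1, "seed": seed,
                                                "degenerate": True})
    ord_ = PCPS(var_threshold=var_threshold)
    axes = ord_.fit_transform(p)
    if axes.shape[1] == 0:  # no axis above threshold; fall back to first axis
        axes = ord_.result_.axes.iloc[:, :1]
    clf = EvoregionClassifier(k=k, k_max=min(k_max, max(2, axes.shape[0] - 1)),
                              restarts=restarts, random_state=seed)
    clf.fit(axes)
    prov = {
        "k": clf.k_,
        "seed": seed,
        "var_threshold": var_threshold,
        "n_axes_used": axes.shape[1],
        "eigenvalues": ord_.eigenvalues_.tolist(),
        "relative_variance": ord_.relative_variance_.tolist(),
        "wss": None if clf.wss_ is None else list(map(float, clf.wss_)),
    }
    return Regionalization(
        labels=clf.labels_,
        assignment_probability=clf.posterior_,
        k=clf.k_,
        provenance=prov,
    )
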