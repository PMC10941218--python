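"""Phylogenetic fuzzy weighting and PCPS ordination.

The fuzzy-weighting transform distributes each species' occurrence across its
relatives in proportion to phylogenetic similarity.  From a patristic
distance matrix ``d`` we form a similarity ``s = 1 - d/max(d)``, standardize
its columns to obtain the species-membership matrix ``Q`` (each column the
fuzzy membership of all species in one species' lineage), and multiply the
binary presence matrix by ``Q`` to obtain the phylogeny-weighted assemblage
composition ``P`` (rows standardized to unit sum, so entries are degrees of
belonging in [0, 1]).

Ordination of ``P`` uses classical principal coordinates analysis of
square-rooted Bray-Curtis dissimilarities between cells -- the square root
makes the dissimilarity Euclidean-embeddable in practice and avoids negative
eigenvalues.  Axes explaining more than ``var_threshold`` (strictly more than
5% by default) of the variance are the PCPS axes carrying the gradients of
phylogenetic turnover.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "phylo_similarity",
    "build_q",
    "build_p",
    "sqrt_bray_curtis",
    "pcoa",
    "PcpsResult",
    "PhylogeneticFuzzyWeighting",
    "PCPS",
]


def phylo_similarity(d: pd.DataFrame, kernel: str = "linear",
                     decay: float = 1.0) -> pd.DataFrame:
    """Species similarity from patristic distances.

    ``linear`` (default): ``s = 1 - d / max(d)``.  ``exponential`` is an
    alternative kernel ``s = exp(-decay * d / max(d))``.
    """
    dm = np.asarray(d, dtype=float)
    if dm.shape[0] != dm.shape[1] or not np.allclose(dm, dm.T):
        raise ValueError("distance matrix must be symmetric")
    dmax = dm.max()
    if dmax <= 0:
        raise ValueError("all pairwise distances are zero")
    if kernel == "linear":
        s = 1.0 - dm / dmax
    elif kernel == "exponential":
        s = np.exp(-decay * dm / dmax)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    np.fill_diagonal(s, 1.0)
    return pd.DataFrame(s, index=d.index, columns=d.columns)


def build_q(s: pd.DataFrame) -> pd.DataFrame:
    """Column-standardize a similarity matrix into the fuzzy matrix Q.

    ``Q[i, j] = s[i, j] / sum_k s[k, j]``; every column sums to 1 and the
    diagonal entry is each column's maximum.
    """
    sm = np.asarray(s, dtype=float)
    q = sm / sm.sum(axis=0, keepdims=True)
    return pd.DataFrame(q, index=s.index, columns=s.columns)


def build_p(presence: pd.DataFrame, q: pd.DataFrame) -> pd.DataFrame:
    """Phylogeny-weighted composition P = row-standardized presence @ Q."""
    if list(presence.columns) != list(q.index):
        raise ValueError("species order of presence matrix and Q differ")
    raw = presence.to_numpy(dtype=float) @ q.to_numpy()
    sums = raw.sum(axis=1, keepdims=True)
    if np.any(sums == 0):
        raise ValueError("empty cell rows; drop empty cells first")
    return pd.DataFrame(raw / sums, index=presence.index, columns=q.columns)


def sqrt_bray_curtis(p: pd.DataFrame) -> pd.DataFrame:
    """Square-rooted Bray-Curtis dissimilarities between cell rows."""
    d = np.sqrt(squareform(pdist(np.asarray(p, dtype=float), metric="braycurtis")))
    return pd.DataFrame(d, index=p.index, columns=p.index)


@dataclass
class PcpsResult:
    """Principal-coordinates ordination with axis selection.

    ``axes`` holds coordinates scaled by the square root of each (positive)
    eigenvalue; ``relative_variance`` is each eigenvalue's share of the
    positive total; ``selected`` indexes the axes with relative variance
    strictly above the threshold.
    """

    axes: pd.DataFrame
    eigenvalues: np.ndarray
    relative_variance: np.ndarray
    selected: list[int]
    n_negative_dropped: int = 0

    @property
    def selected_axes(self) -> pd.DataFrame:
        return self.axes.iloc[:, self.selected]


def pcoa(d: pd.DataFrame, var_threshold: float = 0.05) -> PcpsResult:
    """Classical scaling (PCoA) of a dissimilarity matrix.

    Double-centres ``-1/2 d**2`` and eigendecomposes; axes are eigenvectors
    scaled by sqrt(eigenvalue).  Negative eigenvalues are dropped with a
    warning.  Axis selection keeps components with strictly more than
    ``var_threshold`` of the positive variance.
    """
    dm = np.asarray(d, dtype=float)
    n = dm.shape[0]
    if dm.shape[1] != n or not np.allclose(dm, dm.T, atol=1e-12):
        raise ValueError("dissimilarity matrix must be square and symmetric")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dm ** 2) @ j
    vals, vecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(abs(vals).max(), 1.0) * 1e-12
    n_neg = int(np.sum(vals < -tol))
    if n_neg:
        warnings.warn(f"dropping {n_neg} negative eigenvalues from PCoA")
    pos = vals > tol
    if not pos.any():
        raise ValueError("PCoA found no positive eigenvalue")
    vals_pos = vals[pos]
    axes = vecs[:, pos] * np.sqrt(vals_pos)
    relvar = vals_pos / vals_pos.sum()
    selected = [i for i, rv in enumerate(relvar) if rv > var_threshold]
    index = d.index if isinstance(d, pd.DataFrame) else pd.RangeIndex(n)
    axes_df = pd.DataFrame(
        axes, index=index, columns=[f"pcps_{i + 1}" for i in range(axes.shape[1])]
    )
    return PcpsResult(
        axes=axes_df,
        eigenvalues=vals_pos,
        relative_variance=relvar,
        selected=selected,
        n_negative_dropped=n_neg,
    )


class PhylogeneticFuzzyWeighting(TransformerMixin, BaseEstimator):
    """Transformer mapping binary presence matrices to fuzzy composition P.

    Parameters
    ----------
    distances : DataFrame
        Patristic distance matrix between species (see
        :func:`evoregion.tree.patristic_distances`).
    kernel, decay
        Similarity kernel passed to :func:`phylo_similarity`.

    Attributes
    ----------
    q_ : DataFrame
        Column-standardized fuzzy membership matrix (species x species).
    """

    def __init__(self, distances: pd.DataFrame | None = None,
                 kernel: str = "linear", decay: float = 1.0):
        self.distances = distances
        self.kernel = kernel
        self.decay = decay

    def fit(self, X=None, y=None):
        if self.distances is None:
            raise ValueError("a patristic distance matrix is required")
        s = phylo_similarity(self.distances, kernel=self.kernel, decay=self.decay)
        self.q_ = build_q(s)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return build_p(X, self.q_)


class PCPS(TransformerMixin, BaseEstimator):
    """Transformer: fuzzy composition P -> selected PCPS ordination axes.

    Computes square-rooted Bray-Curtis dissimilarities between rows of P and
    ordinates them by PCoA; ``transform`` is only defined for the fitted
    data (classical scaling has no out-of-sample map), so use
    ``fit_transform``.
    """

    def __init__(self, var_threshold: float = 0.05):
        self.var_threshold = var_threshold

    def fit(self, X: pd.DataFrame, y=None):
        d = sqrt_bray_curtis(X)
        self.dissimilarity_ = d
        self.result_ = pcoa(d, var_threshold=self.var_threshold)
        self.eigenvalues_ = self.result_.eigenvalues
        self.relative_variance_ = self.result_.relative_variance
        self._fit_index = X.index
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not X.index.equals(self._fit_index):
            raise ValueError("PCPS has no out-of-sample transform; "
                             "call fit_transform on the full data")
        return self.result_.selected_axes

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X).transform(X)
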