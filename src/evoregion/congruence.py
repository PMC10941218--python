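"""Congruence between two regionalizations: the V-measure.

Two maps of the same cells are crossed into a weighted contingency
(overlap) table; homogeneity and completeness are entropy-based scores on
that table and the V-measure is their harmonic mean.  With ``p_ij`` the
joint weight fraction of (region i of the first map, zone j of the second):

    h = 1 - H(R|Z) / H(R)      (1 if H(R) = 0)
    c = 1 - H(Z|R) / H(Z)      (1 if H(Z) = 0)
    v = 2 h c / (h + c)        (0 if h = c = 0)

Natural logarithms are used throughout (V is invariant to the base).
Swapping the two maps exchanges h and c and leaves v unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regions import Regionalization

__all__ = [
    "OverlapTable",
    "CongruenceResult",
    "build_overlap",
    "v_measure",
    "v_measure_from_labels",
]


@dataclass
class OverlapTable:
    """Weighted contingency of two regionalizations (rows x cols)."""

    weights: pd.DataFrame
    n_shared_cells: int = 0

    @property
    def total(self) -> float:
        return float(self.weights.to_numpy().sum())


@dataclass
class CongruenceResult:
    v: float
    homogeneity: float
    completeness: float
    overlap: OverlapTable

    def swapped(self) -> "CongruenceResult":
        return CongruenceResult(
            v=self.v,
            homogeneity=self.completeness,
            completeness=self.homogeneity,
            overlap=OverlapTable(self.overlap.weights.T,
                                 self.overlap.n_shared_cells),
        )


def build_overlap(
    r1: Regionalization,
    r2: Regionalization,
    weight: str = "count",
    grid=None,
) -> OverlapTable:
    """Cross-tabulate two regionalizations over their shared cells.

    ``weight="count"`` adds 1 per shared cell; ``weight="area"`` adds the
    cosine-latitude cell area (requires ``grid``).  Cells present in only
    one map are dropped.
    """
    l1, l2 = r1.labels, r2.labels
    shared = l1.index.intersection(l2.index)
    if len(shared) == 0:
        raise ValueError("the two regionalizations share no cells")
    if weight == "count":
        w = pd.Series(1.0, index=shared)
    elif weight == "area":
        if grid is None:
            raise ValueError("area weighting needs a GridSpec")
        w = pd.Series([grid.cell_area(c) for c in shared], index=shared)
    else:
        raise ValueError(f"unknown weight mode {weight!r}")
    tab = pd.crosstab(l1.loc[shared], l2.loc[shared],
                      values=w, aggfunc="sum").fillna(0.0)
    return OverlapTable(weights=tab, n_shared_cells=len(shared))


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def v_measure(o: OverlapTable) -> CongruenceResult:
    """Homogeneity, completeness and V from an overlap table."""
    w = o.weights.to_numpy(dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("overlap table has zero total weight")
    p = w / total
    prow = p.sum(axis=1)
    pcol = p.sum(axis=0)
    h_r, h_z = _entropy(prow), _entropy(pcol)
    # conditional entropies
    with np.errstate(divide="ignore", invalid="ignore"):
        h_r_given_z = -np.nansum(
            np.where(p > 0, p * np.log(p / pcol[None, :]), 0.0))
        h_z_given_r = -np.nansum(
            np.where(p > 0, p * np.log(p / prow[:, None]), 0.0))
    h = 1.0 if h_r == 0 else 1.0 - h_r_given_z / h_r
    c = 1.0 if h_z == 0 else 1.0 - h_z_given_r / h_z
    v = 0.0 if (h + c) == 0 else 2.0 * h * c / (h + c)
    return CongruenceResult(v=float(v), homogeneity=float(h),
                            completeness=float(c), overlap=o)


def v_measure_from_labels(labels1, labels2) -> CongruenceResult:
    """Convenience wrapper: V-measure of two equal-length label arrays."""
    l1 = pd.Series(np.asarray(labels1))
    l2 = pd.Series(np.asarray(labels2))
    if len(l1) != len(l2):
        raise ValueError("label arrays differ in length")
    tab = pd.crosstab(l1, l2).astype(float)
    return v_measure(OverlapTable(weights=tab, n_shared_cells=len(l1)))
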