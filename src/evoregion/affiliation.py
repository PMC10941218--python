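"""Cell affiliations, transition zones and species-evoregion association.

A cell's affiliation is its phylogenetic similarity to the rest of its own
evoregion: ``1 - mean(sqrt-Bray-Curtis dissimilarity to co-members)``.  Cells
with low affiliation (below the within-region lower quartile, by default
additionally required to touch a different region) are flagged; connected
groups of flagged cells form evolutionary transition zones.

A species is associated with the evoregion holding at least 60% of its
occupied cells; species that cannot reach that majority anywhere are
classed as widespread.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .grid import GridSpec, OccurrenceGrid
from .regions import Regionalization

__all__ = [
    "WIDESPREAD",
    "AffiliationMap",
    "TransitionZone",
    "cell_affiliation",
    "transition_zones",
    "species_association",
]

WIDESPREAD = "WIDESPREAD"


@dataclass
class AffiliationMap:
    """Per-cell affiliation values and transition flags.

    ``table`` columns: ``evoregion``, ``affiliation`` in [0, 1] and
    ``transition_flag``; indexed by cell id.
    """

    table: pd.DataFrame
    quantile: float

    @property
    def affiliation(self) -> pd.Series:
        return self.table["affiliation"]

    @property
    def flagged(self) -> pd.Index:
        return self.table.index[self.table["transition_flag"]]


@dataclass
class TransitionZone:
    cells: list[int]
    bordering_regions: set[str]


def cell_affiliation(
    d: pd.DataFrame,
    r: Regionalization,
    quantile: float = 0.25,
    require_boundary: bool = True,
    grid: GridSpec | None = None,
) -> AffiliationMap:
    """Affiliation of every cell with its evoregion.

    ``affiliation(c) = 1 - mean d(c, c')`` over the other cells ``c'`` of
    ``c``'s region; a region's sole member gets affiliation 1.  A cell is
    transition-flagged when its affiliation falls strictly below its region's
    lower ``quantile`` and (when ``require_boundary`` and a grid are given)
    it is 4-adjacent to a cell of a different region.
    """
    cells = r.labels.index
    if not d.index.equals(cells):
        d = d.loc[cells, cells]
    dm = d.to_numpy()
    labels = r.labels.to_numpy()
    aff = np.empty(len(cells))
    for i in range(len(cells)):
        mask = labels == labels[i]
        mask[i] = False
        aff[i] = 1.0 if not mask.any() else 1.0 - dm[i, mask].mean()
    aff_s = pd.Series(aff, index=cells)
    flag = np.zeros(len(cells), dtype=bool)
    for region in np.unique(labels):
        member = labels == region
        cutoff = np.quantile(aff[member], quantile)
        flag[member] = aff[member] < cutoff
    if require_boundary and grid is not None:
        label_of = dict(zip(cells, labels))
        for i, c in enumerate(cells):
            if flag[i]:
                flag[i] = any(
                    nb in label_of and label_of[nb] != labels[i]
                    for nb in grid.neighbors(c)
                )
    table = pd.DataFrame(
        {"evoregion": labels, "affiliation": aff, "transition_flag": flag},
        index=cells,
    )
    table.index.name = "cell_id"
    return AffiliationMap(table=table, quantile=quantile)


def transition_zones(a: AffiliationMap, grid: GridSpec) -> list[TransitionZone]:
    """Connected components (4-neighbour) of transition-flagged cells.

    Each zone is annotated with the evoregion labels of the non-flagged
    cells it touches (plus the labels of its own cells' regions).
    """
    flagged = set(int(c) for c in a.flagged)
    g = nx.Graph()
    g.add_nodes_from(flagged)
    for c in flagged:
        for nb in grid.neighbors(c):
            if nb in flagged:
                g.add_edge(c, nb)
    label_of = a.table["evoregion"].to_dict()
    zones = []
    for comp in nx.connected_components(g):
        borders: set[str] = set()
        for c in comp:
            borders.add(label_of[c])
            for nb in grid.neighbors(c):
                if nb in label_of and nb not in flagged:
                    borders.add(label_of[nb])
        zones.append(TransitionZone(cells=sorted(comp), bordering_regions=borders))
    zones.sort(key=lambda z: (-len(z.cells), z.cells))
    return zones


def species_association(
    g: OccurrenceGrid,
    r: Regionalization,
    threshold: float = 0.60,
) -> pd.DataFrame:
    """Assign each species to its modal evoregion under the majority rule.

    For each species the fraction of its occupied cells falling in its modal
    evoregion is computed; the species belongs to that region when the
    fraction is at least ``threshold`` (ties at the maximum count as
    widespread).  Returns a DataFrame with columns ``assignment`` and
    ``fraction`` indexed by species.
    """
    labels = r.labels
    pres = g.presence.loc[labels.index]
    rows = {}
    for sp in pres.columns:
        occ = labels[pres[sp].to_numpy().astype(bool)]
        if len(occ) == 0:
            raise ValueError(f"species {sp!r} occupies no cells")
        counts = occ.value_counts()
        frac = counts.iloc[0] / len(occ)
        tie = (counts == counts.iloc[0]).sum() > 1
        if frac >= threshold and not tie:
            rows[sp] = (counts.index[0], frac)
        else:
            rows[sp] = (WIDESPREAD, frac)
    out = pd.DataFrame.from_dict(rows, orient="index",
                                 columns=["assignment", "fraction"])
    out.index.name = "species"
    return out
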