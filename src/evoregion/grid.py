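"""Gridded species occurrences.

A :class:`GridSpec` tiles a lon/lat rectangle into equal-angle cells
(2 degrees by default); an :class:`OccurrenceGrid` couples the grid geometry
with a binary cells x species presence matrix.  Ranges supplied as polygons
are rasterized with a minimum-coverage rule: a species is present in a cell
when its range covers at least ``min_coverage`` (default 12.5%) of the cell
area.  Areas use the cosine-latitude approximation; within a single cell the
numerator and denominator share the same latitude factor, so the coverage
ratio reduces to the planar area ratio.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import box
from shapely.validation import make_valid

__all__ = [
    "GridSpec",
    "OccurrenceGrid",
    "rasterize_ranges",
    "drop_empty_cells",
    "drop_unobserved_species",
    "align_to_tree",
]


@dataclass(frozen=True)
class GridSpec:
    """Equal-angle grid; cell ids run row-major from the north-west corner.

    Cells are half-open ``[lon, lon+d) x [lat-d, lat)`` boxes so shared
    borders belong to exactly one cell.
    """

    lon_min: float
    lat_max: float
    n_rows: int
    n_cols: int
    cell_size_deg: float = 2.0

    @property
    def cell_ids(self) -> np.ndarray:
        return np.arange(self.n_rows * self.n_cols)

    def rowcol(self, cell_id: int) -> tuple[int, int]:
        return divmod(int(cell_id), self.n_cols)

    def cell_box(self, cell_id: int):
        r, c = self.rowcol(cell_id)
        d = self.cell_size_deg
        lon0 = self.lon_min + c * d
        lat1 = self.lat_max - r * d
        return box(lon0, lat1 - d, lon0 + d, lat1)

    def centroid(self, cell_id: int) -> tuple[float, float]:
        r, c = self.rowcol(cell_id)
        d = self.cell_size_deg
        return (self.lon_min + (c + 0.5) * d, self.lat_max - (r + 0.5) * d)

    def cell_area(self, cell_id: int) -> float:
        """Relative cell area under the cosine-latitude approximation."""
        _, lat = self.centroid(cell_id)
        return self.cell_size_deg ** 2 * math.cos(math.radians(lat))

    def neighbors(self, cell_id: int) -> list[int]:
        """4-neighbour (rook) adjacency within the grid bounds."""
        r, c = self.rowcol(cell_id)
        out = []
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < self.n_rows and 0 <= cc < self.n_cols:
                out.append(rr * self.n_cols + cc)
        return out


@dataclass
class OccurrenceGrid:
    """Binary presence matrix (cells x species) tied to a grid geometry.

    ``presence`` is a 0/1 DataFrame indexed by cell id with one column per
    species; ``grid`` may be ``None`` when a ready matrix without geometry is
    analysed.
    """

    presence: pd.DataFrame
    grid: GridSpec | None = None

    def __post_init__(self) -> None:
        self.presence = self.presence.astype(np.int8)
        self.presence.index.name = "cell_id"

    @property
    def cell_ids(self) -> np.ndarray:
        return self.presence.index.to_numpy()

    @property
    def species(self) -> list[str]:
        return list(self.presence.columns)

    def to_csv(self, path) -> None:
        df = self.presence.copy()
        if self.grid is not None:
            lonlat = np.array([self.grid.centroid(c) for c in df.index])
            df.insert(0, "lat", lonlat[:, 1])
            df.insert(0, "lon", lonlat[:, 0])
        df.index.name = "cell_id"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path, grid: GridSpec | None = None) -> "OccurrenceGrid":
        df = pd.read_csv(path, index_col="cell_id")
        df = df.drop(columns=[c for c in ("lon", "lat") if c in df.columns])
        return cls(presence=df, grid=grid)


def rasterize_ranges(
    polygons: dict[str, object],
    grid: GridSpec,
    min_coverage: float = 0.125,
) -> OccurrenceGrid:
    """Rasterize per-species range polygons onto the grid.

    ``presence[c, s] = 1`` iff the species' range covers at least
    ``min_coverage`` of the cell area (>= rule, so an exact-threshold overlap
    counts as present).  Invalid polygons are repaired; species with empty
    geometry are dropped with a warning.
    """
    if not (0 < min_coverage <= 1):
        raise ValueError("min_coverage must be in (0, 1]")
    cells = grid.cell_ids
    boxes = [grid.cell_box(c) for c in cells]
    data: dict[str, np.ndarray] = {}
    for sp, geom in polygons.items():
        if geom is None or geom.is_empty or geom.area == 0:
            warnings.warn(f"species {sp!r} has an empty range polygon; dropped")
            continue
        if not geom.is_valid:
            geom = make_valid(geom)
        col = np.zeros(len(cells), dtype=np.int8)
        for i, b in enumerate(boxes):
            if geom.intersects(b):
                frac = geom.intersection(b).area / b.area
                if frac >= min_coverage - 1e-12:
                    col[i] = 1
        data[sp] = col
    presence = pd.DataFrame(data, index=cells)
    return OccurrenceGrid(presence=presence, grid=grid)


def drop_empty_cells(g: OccurrenceGrid) -> OccurrenceGrid:
    """Remove cells with no species; original cell ids are retained."""
    keep = g.presence.sum(axis=1) > 0
    if not keep.any():
        raise ValueError("empty occurrence matrix: every cell is empty")
    return OccurrenceGrid(presence=g.presence.loc[keep], grid=g.grid)


def drop_unobserved_species(g: OccurrenceGrid) -> OccurrenceGrid:
    keep = g.presence.sum(axis=0) > 0
    if not keep.any():
        raise ValueError("empty occurrence matrix: every species is absent")
    return OccurrenceGrid(presence=g.presence.loc[:, keep], grid=g.grid)


def align_to_tree(g: OccurrenceGrid, tree) -> tuple[OccurrenceGrid, dict]:
    """Restrict the grid to species present on the tree, in tip order.

    Returns the aligned grid and a report with the counts and names dropped
    on each side.  Raises if the grid and tree share no species.
    """
    from .tree import tip_labels

    tips = tip_labels(tree)
    shared = [t for t in tips if t in g.presence.columns]
    if not shared:
        raise ValueError("no species shared between occurrence grid and tree")
    report = {
        "n_shared": len(shared),
        "dropped_from_grid": sorted(set(g.presence.columns) - set(shared)),
        "dropped_from_tree": sorted(set(tips) - set(shared)),
    }
    return OccurrenceGrid(presence=g.presence[shared], grid=g.grid), report
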