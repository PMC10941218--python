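"""Synthetic faunas with known regional ground truth.

The generator emulates the structure the evoregion concept assumes: a
phylogeny whose major clades each diversified within one contiguous latent
region of a lon/lat grid.  Species ranges are contiguous cell blobs grown by
frontier sampling from a random start inside the clade's region, stepping
outside it with a small spillover probability (capped so every regional
species keeps at least 60% of its cells inside its true region).  A fraction
of species are instead constructed as widespread: their range straddles a
region boundary in two balanced halves, so no single region can claim 60% of
their cells.

Paired host/parasite scenarios share one grid; the parasite's clades either
inherit the host's clade-region territories (congruent) or are reassigned to
independent random territories (incongruent), so the expected map congruence
rises smoothly with ``congruence_level``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from .grid import GridSpec, OccurrenceGrid
from .affiliation import WIDESPREAD

__all__ = [
    "ScenarioConfig",
    "SyntheticTruth",
    "simulate_tree",
    "simulate_regional_fauna",
    "simulate_host_parasite_pair",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for a synthetic fauna.

    Defaults describe the standard test scenario: 4 latent regions on a
    12 x 12 grid of 2-degree cells, 120 species, ranges of about 10 cells,
    10% spillover per growth step and 10% widespread species.
    """

    n_regions: int = 4
    grid_shape: tuple[int, int] = (12, 12)
    n_species: int = 120
    range_size_mean: float = 10.0
    spillover_prob: float = 0.1
    widespread_frac: float = 0.1
    host_switch_frac: float = 0.0
    cell_size_deg: float = 2.0
    seed: int = 7

    def __post_init__(self):
        for name in ("spillover_prob", "widespread_frac", "host_switch_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_regions > self.grid_shape[0] * self.grid_shape[1]:
            raise ValueError("more regions than grid cells")


@dataclass
class SyntheticTruth:
    """A generated fauna plus its latent regional ground truth."""

    tree: dendropy.Tree
    grid: OccurrenceGrid
    true_cell_region: pd.Series
    true_species_region: pd.Series
    info: dict = field(default_factory=dict)


def simulate_tree(n_species: int, seed: int = 0,
                  scale_to_unit_depth: bool = True) -> dendropy.Tree:
    """Yule (pure-birth, rate 1) crown tree with ``n_species`` tips.

    Starts from two crown lineages; ultrametric by construction, depth
    rescaled to 1 unless disabled.  Deterministic for a given seed.
    """
    if n_species < 3:
        raise ValueError("need at least 3 species")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = True
    # crown start: two lineages diverge at the root at time 0
    active: list[tuple[dendropy.Node, float]] = []
    for _ in range(2):
        ch = dendropy.Node()
        tree.seed_node.add_child(ch)
        active.append((ch, 0.0))
    t = 0.0
    while len(active) < n_species:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        node, birth = active.pop(i)
        node.edge.length = t - birth
        for _ in range(2):
            ch = dendropy.Node()
            node.add_child(ch)
            active.append((ch, t))
    t_end = t + rng.exponential(1.0 / n_species)
    for node, birth in active:
        node.edge.length = t_end - birth
    width = len(str(n_species))
    for i, leaf in enumerate(tree.leaf_node_iter()):
        taxon = tns.new_taxon(label=f"s{i + 1:0{width}d}")
        leaf.taxon = taxon
    if scale_to_unit_depth:
        for node in tree.preorder_node_iter():
            if node.parent_node is not None:
                node.edge.length /= t_end
    return tree


def _block_layout(n_regions: int, n_rows: int, n_cols: int) -> np.ndarray:
    """Tile the grid into ``n_regions`` contiguous rectangular blocks.

    Returns an (n_rows, n_cols) array of region indices.  The factor pair
    closest to square is used (vertical strips for prime counts).
    """
    a = max(d for d in range(1, int(np.sqrt(n_regions)) + 1)
            if n_regions % d == 0)
    b = n_regions // a
    row_edges = np.linspace(0, n_rows, a + 1).round().astype(int)
    col_edges = np.linspace(0, n_cols, b + 1).round().astype(int)
    layout = np.empty((n_rows, n_cols), dtype=int)
    for i in range(a):
        for j in range(b):
            layout[row_edges[i]:row_edges[i + 1],
                   col_edges[j]:col_edges[j + 1]] = i * b + j
    return layout


def _cut_clades(tree: dendropy.Tree, n_clades: int) -> list[list[str]]:
    """Cut an ultrametric tree at the depth giving ``n_clades`` lineages.

    Returns the tip sets of the subtrees hanging from edges that cross the
    cutting depth.  For a binary tree any count up to the tip number is
    attainable exactly (node depths are generically distinct); if equal
    depths make the exact count unattainable the nearest achievable count
    is returned.
    """
    depths = []
    for node in tree.preorder_node_iter():
        el = node.edge.length or 0.0
        node._depth = (node.parent_node._depth if node.parent_node else 0.0) + el
        if not node.is_leaf():
            depths.append(node._depth)
    depths = sorted(depths)
    n_clades = min(n_clades, len(tree.leaf_nodes()))
    if n_clades <= 1:
        return [[lf.taxon.label for lf in tree.leaf_node_iter()]]
    lo = depths[n_clades - 2]
    hi = depths[n_clades - 1] if n_clades - 1 < len(depths) \
        else max(nd._depth for nd in tree.leaf_node_iter())
    cut = (lo + hi) / 2.0
    clades = []
    for node in tree.preorder_node_iter():
        parent_depth = node.parent_node._depth if node.parent_node else 0.0
        if node.parent_node is not None and parent_depth < cut <= node._depth:
            clades.append([lf.taxon.label for lf in node.leaf_iter()])
    return clades


def _draw_regional_tree(n_species, n_regions, rng, max_draws: int = 500,
                        max_basal_depth: float = 0.1):
    """Draw a Yule tree with ``n_regions`` well-separated, comparable clades.

    The scenario posits one radiation per region, with the radiations
    mutually well separated: the tree is redrawn until (a) the
    ``n_regions``-lineage cut exists, (b) no clade holds less than half a
    fair share of species, and (c) all basal splits fall within
    ``max_basal_depth`` of the (unit-depth) root, i.e. the regional clades
    arise in a near-simultaneous basal radiation so between-clade
    divergences are comparable.  After ``max_draws`` the best draw is kept.
    """
    fair = n_species / n_regions
    best = None
    for _ in range(max_draws):
        tree = simulate_tree(n_species, seed=int(rng.integers(2 ** 31)))
        clades = _cut_clades(tree, n_regions)
        smallest = min(len(c) for c in clades)
        depths = sorted(nd._depth for nd in tree.preorder_internal_node_iter())
        basal = depths[n_regions - 2] if len(depths) >= n_regions - 1 else 1.0
        score = (len(clades) == n_regions, smallest >= 0.5 * fair,
                 -basal, smallest)
        if best is None or score > best[2]:
            best = (tree, clades, score)
        if len(clades) == n_regions and smallest >= 0.5 * fair \
                and basal <= max_basal_depth:
            break
    return best[0], best[1]


def _grow_blob(target: int, start: int, allowed_weight, grid: GridSpec,
               rng: np.random.Generator) -> list[int]:
    """Grow a contiguous blob of cells by frontier sampling.

    ``allowed_weight(candidate, blob)`` returns True to accept a frontier
    cell.  Returns cells in addition order (so tail-trimming preserves
    contiguity).
    """
    blob = [start]
    in_blob = {start}
    tries = 0
    while len(blob) < target and tries < 60 * target:
        tries += 1
        frontier = sorted({nb for c in blob for nb in grid.neighbors(c)}
                          - in_blob)
        if not frontier:
            break
        cand = int(frontier[rng.integers(len(frontier))])
        if allowed_weight(cand, blob):
            blob.append(cand)
            in_blob.add(cand)
    return blob


def _grow_regional_range(target, region_cells, region_of, region_label,
                         spillover_prob, grid, rng):
    start = int(region_cells[rng.integers(len(region_cells))])
    n_out = 0
    state = {"n_out": 0}

    def allowed(cand, blob):
        inside = region_of[cand] == region_label
        if inside:
            return True
        if rng.random() >= spillover_prob:
            return False
        # keep at least 60% of cells inside the true region
        if (state["n_out"] + 1) > 0.4 * (len(blob) + 1) + 1e-9:
            return False
        state["n_out"] += 1
        return True

    return _grow_blob(target, start, allowed, grid, rng)


def _grow_widespread_range(target, region_of, grid, rng):
    """Two balanced half-blobs on either side of a region boundary."""
    target = max(4, target + (target % 2))
    boundary_pairs = []
    for c in grid.cell_ids:
        for nb in grid.neighbors(int(c)):
            if region_of[int(c)] != region_of[nb]:
                boundary_pairs.append((int(c), nb))
    c1, c2 = boundary_pairs[rng.integers(len(boundary_pairs))]
    half = target // 2
    parts = []
    for seed_cell in (c1, c2):
        label = region_of[seed_cell]

        def allowed(cand, blob, label=label):
            return region_of[cand] == label

        parts.append(_grow_blob(half, seed_cell, allowed, grid, rng))
    # trim the larger part so no region reaches the 60% majority
    while max(len(p) for p in parts) >= 0.6 * sum(len(p) for p in parts):
        parts.sort(key=len)
        parts[-1].pop()
    return parts[0] + parts[1]


def simulate_regional_fauna(cfg: ScenarioConfig) -> SyntheticTruth:
    """Generate one fauna: tree, gridded ranges and latent truth."""
    rng = np.random.default_rng(cfg.seed)
    tree, clades = _draw_regional_tree(cfg.n_species, cfg.n_regions, rng)
    n_rows, n_cols = cfg.grid_shape
    gspec = GridSpec(lon_min=0.0,
                     lat_max=n_rows * cfg.cell_size_deg / 2.0,
                     n_rows=n_rows, n_cols=n_cols,
                     cell_size_deg=cfg.cell_size_deg)
    layout = _block_layout(cfg.n_regions, n_rows, n_cols).ravel()
    region_labels = [f"R{i}" for i in range(cfg.n_regions)]
    region_of = np.array([region_labels[layout[c]] for c in gspec.cell_ids])
    clades = sorted(clades, key=len, reverse=True)
    perm = rng.permutation(cfg.n_regions)
    clade_region = {i: region_labels[perm[i % cfg.n_regions]]
                    for i in range(len(clades))}
    truth = _grow_fauna(tree, gspec, region_of, clades, clade_region, cfg, rng)
    truth.info.update({"n_clades": len(clades), "layout": layout})
    return truth


def _grow_fauna(tree, gspec, region_of, clades, clade_region, cfg, rng,
                territory_cells=None) -> SyntheticTruth:
    """Grow every species' range given clade-to-territory bindings.

    ``territory_cells`` optionally overrides the cell set a clade's species
    grow in (used for incongruent parasite clades); by default a clade's
    territory is its bound region's cells.
    """
    cells = gspec.cell_ids
    cells_by_region = {lab: cells[region_of == lab]
                       for lab in np.unique(region_of)}
    presence = pd.DataFrame(0, index=cells,
                            columns=[lf.taxon.label
                                     for lf in tree.leaf_node_iter()],
                            dtype=np.int8)
    species_region = {}
    for ci, clade in enumerate(clades):
        label = clade_region[ci]
        if territory_cells is not None and ci in territory_cells:
            terr = territory_cells[ci]
            terr_of = np.where(np.isin(cells, terr), label, "~other")
        else:
            terr = cells_by_region[label]
            terr_of = region_of
        for sp in clade:
            size = max(1, int(rng.poisson(cfg.range_size_mean)))
            if rng.random() < cfg.widespread_frac:
                blob = _grow_widespread_range(size, region_of, gspec, rng)
                species_region[sp] = WIDESPREAD
            else:
                sp_label, sp_terr, sp_terr_of = label, terr, terr_of
                if cfg.host_switch_frac and rng.random() < cfg.host_switch_frac:
                    sp_label = str(rng.choice(
                        [r for r in cells_by_region if r != label]))
                    sp_terr, sp_terr_of = cells_by_region[sp_label], region_of
                blob = _grow_regional_range(size, sp_terr, sp_terr_of,
                                            sp_label, cfg.spillover_prob,
                                            gspec, rng)
                species_region[sp] = sp_label
            presence.loc[blob, sp] = 1
    grid = OccurrenceGrid(presence=presence, grid=gspec)
    return SyntheticTruth(
        tree=tree,
        grid=grid,
        true_cell_region=pd.Series(region_of, index=cells, name="region"),
        true_species_region=pd.Series(species_region, name="region"),
    )


def simulate_host_parasite_pair(
    cfg: ScenarioConfig,
    congruence_level: float = 1.0,
) -> tuple[SyntheticTruth, SyntheticTruth]:
    """A host fauna and a parasite fauna on the same grid.

    The parasite's clades inherit the host's regional territories; a
    ``1 - congruence_level`` fraction of them is instead reassigned to an
    independently placed random rectangular territory, mimicking lineages
    whose history (host switching, independent dispersal) decouples them
    from the host's regionalization.  Returns ``(parasite, host)``.
    """
    if not 0 <= congruence_level <= 1:
        raise ValueError("congruence_level must be in [0, 1]")
    host = simulate_regional_fauna(cfg)
    rng = np.random.default_rng(cfg.seed + 10_007)
    tree, clades = _draw_regional_tree(cfg.n_species, cfg.n_regions, rng)
    n_rows, n_cols = cfg.grid_shape
    gspec = host.grid.grid
    region_of = host.true_cell_region.to_numpy()
    region_labels = [f"R{i}" for i in range(cfg.n_regions)]
    clades = sorted(clades, key=len, reverse=True)
    perm = rng.permutation(cfg.n_regions)
    clade_region = {i: region_labels[perm[i % cfg.n_regions]]
                    for i in range(len(clades))}
    n_reassign = int(round((1.0 - congruence_level) * len(clades)))
    reassigned = rng.choice(len(clades), size=n_reassign, replace=False)
    territory_cells = {}
    blk_r = max(1, n_rows // max(1, int(np.sqrt(cfg.n_regions))))
    blk_c = max(1, n_cols // max(1, cfg.n_regions // int(np.sqrt(cfg.n_regions))))
    for ci in reassigned:
        r0 = int(rng.integers(0, n_rows - blk_r + 1))
        c0 = int(rng.integers(0, n_cols - blk_c + 1))
        terr = np.array([r * n_cols + c
                         for r in range(r0, r0 + blk_r)
                         for c in range(c0, c0 + blk_c)])
        territory_cells[int(ci)] = terr
    parasite = _grow_fauna(tree, gspec, region_of, clades, clade_region,
                           cfg, rng, territory_cells=territory_cells)
    parasite.info.update({"n_clades": len(clades),
                          "reassigned_clades": sorted(int(i) for i in reassigned),
                          "congruence_level": congruence_level})
    return parasite, host
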