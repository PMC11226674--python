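"""Simpson turnover (βsim) among cell assemblages, taxonomic and phylogenetic.

The Simpson index of dissimilarity isolates the turnover (replacement)
component of beta diversity and is insensitive to richness differences:

    βsim = 1 − a / (min(b, c) + a)

where, in taxonomic mode (Tβsim), ``a`` is the number of taxa shared by the
two assemblages and ``b``, ``c`` the numbers unique to each; in phylogenetic
mode (Pβsim), ``a`` is the summed length of tree branches whose descendant
tips occur in both cells, and ``b``, ``c`` the summed lengths unique to each
cell.  A nested pair (one assemblage inside the other) scores 0; a disjoint
pair scores 1.

Phylogenetic uncertainty is handled by computing Pβsim over a posterior
sample of trees and taking the elementwise median
(:func:`median_posterior_betasim`).  Per-cell distinctiveness — the mean
dissimilarity of a cell to all others — maps biotic uniqueness
(:func:`distinctiveness`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .presence import PresenceMatrix

__all__ = [
    "Phylogeny",
    "PosteriorTreeSet",
    "BranchIncidence",
    "TurnoverComponents",
    "read_trees",
    "pair_components",
    "betasim",
    "betasim_matrix",
    "median_posterior_betasim",
    "distinctiveness",
]

logger = logging.getLogger(__name__)

Phylogeny = dendropy.Tree
PosteriorTreeSet = dendropy.TreeList


def read_trees(path: str | Path) -> PosteriorTreeSet:
    """Read one or more Newick trees from a file."""
    return dendropy.TreeList.get(
        path=str(path), schema="newick", preserve_underscores=True
    )


@dataclass(frozen=True)
class TurnoverComponents:
    """Shared and unique quantities of one assemblage pair.

    ``a`` is the shared taxon count (taxonomic) or shared branch length
    (phylogenetic); ``b`` and ``c`` are the quantities unique to the first
    and second assemblage respectively.
    """

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0 or self.c < 0:
            raise ValueError("turnover components must be nonnegative")


class BranchIncidence:
    """Cell -> tree-edge incidence structure for Pβsim.

    An edge is "present" in a cell iff at least one of its descendant tips
    is present there, so each cell's edge set is closed under the ancestor
    relation.  The root edge (if the Newick carries one) is excluded: it
    subtends every tip, is shared by all non-empty assemblages, and carries
    no turnover information.

    Built once per (presence matrix, tree); all pairwise quantities are then
    dense matrix products over the cell x edge incidence.
    """

    def __init__(self, pm: PresenceMatrix, tree: Phylogeny):
        edges = [
            e
            for e in tree.preorder_edge_iter()
            if e.head_node is not tree.seed_node
        ]
        edge_pos = {id(e): i for i, e in enumerate(edges)}
        self.lengths = np.array(
            [e.length if e.length is not None else 0.0 for e in edges], dtype=float
        )
        if np.any(self.lengths < 0):
            raise ValueError("negative branch length in tree")

        tip_label = {}
        for leaf in tree.leaf_node_iter():
            label = leaf.taxon.label if leaf.taxon is not None else leaf.label
            tip_label[label] = leaf

        matched = [t for t in pm.taxa if t in tip_label]
        dropped = len(pm.taxa) - len(matched)
        if dropped:
            logger.warning(
                "%d of %d taxa absent from the tree were dropped from "
                "phylogenetic turnover",
                dropped,
                len(pm.taxa),
            )
        self.n_dropped_taxa = dropped
        if not matched:
            raise ValueError("no taxon of the presence matrix occurs in the tree")

        # tip x edge: edges on each matched tip's root path
        tip_edge = np.zeros((len(matched), len(edges)), dtype=bool)
        for i, taxon in enumerate(matched):
            node = tip_label[taxon]
            while node is not tree.seed_node:
                tip_edge[i, edge_pos[id(node.edge)]] = True
                node = node.parent_node

        sub = pm.df[matched].to_numpy(bool)
        self.cells = pm.cells
        self.incidence = sub @ tip_edge  # cell x edge, boolean
        self.matched_richness = sub.sum(axis=1)

    def total_lengths(self) -> np.ndarray:
        """Summed incident branch length per cell."""
        return self.incidence @ self.lengths


def betasim(components: TurnoverComponents) -> float:
    """Evaluate βsim = 1 − a/(min(b, c) + a) on one component triple.

    Raises
    ------
    ValueError
        If a = b = c = 0 (two empty assemblages; the index is undefined).
    """
    a, b, c = components.a, components.b, components.c
    if a == 0 and b == 0 and c == 0:
        raise ValueError("βsim undefined for two empty assemblages (a=b=c=0)")
    if a == 0:
        return 1.0
    return 1.0 - a / (min(b, c) + a)


def _components_matrices(
    pm: PresenceMatrix, mode: str, tree: Phylogeny | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dense pairwise (A, B, C) component matrices for all cell pairs."""
    if mode == "taxonomic":
        inc = pm.values.astype(bool)
        weights = np.ones(inc.shape[1])
        totals = inc.sum(axis=1).astype(float)
    elif mode == "phylogenetic":
        if tree is None:
            raise ValueError("phylogenetic mode requires a tree")
        bi = BranchIncidence(pm, tree)
        if np.any(bi.matched_richness == 0):
            bad = [c for c, r in zip(bi.cells, bi.matched_richness) if r == 0]
            raise ValueError(
                f"degenerate assemblage: no tree-matched taxa in cells {bad[:5]}"
            )
        inc = bi.incidence
        weights = bi.lengths
        totals = bi.total_lengths()
    else:
        raise ValueError(f"unknown mode {mode!r}")

    shared = (inc * weights) @ inc.T
    uniq_row = totals[:, None] - shared
    uniq_col = totals[None, :] - shared
    return shared, uniq_row, uniq_col


def pair_components(
    pm: PresenceMatrix,
    cell_x: str,
    cell_y: str,
    mode: str = "taxonomic",
    tree: Phylogeny | None = None,
) -> TurnoverComponents:
    """Shared/unique components (a, b, c) for one cell pair.

    In phylogenetic mode, taxa absent from the tree are dropped (with a
    logged warning) and the root edge is excluded from all sums.
    """
    for cell in (cell_x, cell_y):
        if cell not in pm.df.index:
            raise KeyError(f"unknown cell id {cell!r}")
    if mode == "taxonomic":
        x, y = pm.taxa_of(cell_x), pm.taxa_of(cell_y)
        return TurnoverComponents(len(x & y), len(x - y), len(y - x))
    if mode != "phylogenetic":
        raise ValueError(f"unknown mode {mode!r}")
    bi = BranchIncidence(pm, tree)
    ix, iy = bi.cells.index(cell_x), bi.cells.index(cell_y)
    if bi.matched_richness[ix] == 0 or bi.matched_richness[iy] == 0:
        raise ValueError("degenerate assemblage: no tree-matched taxa in cell")
    ex, ey = bi.incidence[ix], bi.incidence[iy]
    a = float(bi.lengths[ex & ey].sum())
    b = float(bi.lengths[ex & ~ey].sum())
    c = float(bi.lengths[ey & ~ex].sum())
    return TurnoverComponents(a, b, c)


def betasim_matrix(
    pm: PresenceMatrix, mode: str = "taxonomic", tree: Phylogeny | None = None
) -> DistanceMatrix:
    """Pairwise βsim among all cells of ``pm``.

    The cell -> edge incidence structure is built once per tree; all pairs
    are then evaluated by dense linear algebra rather than per-pair set
    operations.
    """
    shared, uniq_row, uniq_col = _components_matrices(pm, mode, tree)
    denom = np.minimum(uniq_row, uniq_col) + shared
    if np.any(denom == 0):
        raise ValueError("βsim undefined: a pair of empty assemblages")
    with np.errstate(invalid="ignore"):
        d = 1.0 - shared / denom
    d = np.clip((d + d.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=pm.cells)


def median_posterior_betasim(
    pm: PresenceMatrix, trees: PosteriorTreeSet | list[Phylogeny]
) -> DistanceMatrix:
    """Elementwise median of Pβsim over a posterior sample of trees.

    For an even number of trees the median is the midpoint of the two
    central order statistics.
    """
    if len(trees) == 0:
        raise ValueError("empty posterior tree set")
    stack = np.stack(
        [betasim_matrix(pm, "phylogenetic", t).data for t in trees], axis=0
    )
    med = np.median(stack, axis=0)
    med = np.clip((med + med.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(med, 0.0)
    return DistanceMatrix(med, ids=pm.cells)


def distinctiveness(dm: DistanceMatrix) -> pd.Series:
    """Mean βsim between each focal cell and all other cells."""
    n = dm.shape[0]
    if n < 2:
        raise ValueError("distinctiveness needs at least two cells")
    means = dm.data.sum(axis=1) / (n - 1)
    return pd.Series(means, index=list(dm.ids), name="mean_betasim")


def write_dissimilarity_csv(dm: DistanceMatrix, path: str | Path) -> None:
    """Write a square dissimilarity CSV with cell-id header row and column."""
    dm.to_data_frame().to_csv(path, index_label="cell_id")


def read_dissimilarity_csv(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, index_col="cell_id", dtype={"cell_id": str})
    return DistanceMatrix(df.to_numpy(float), ids=[str(c) for c in df.columns])
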