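"""Hierarchical bioregion delineation.

Cells are clustered agglomeratively on their turnover dissimilarity; seven
classical linkage algorithms are compared by how faithfully their
cophenetic distances reproduce the input (Pearson cophenetic correlation,
higher is better; Gower distance, the sum of squared deviations, lower is
better).  The number of regions is chosen by the elbow of the
variance-explained-versus-k curve (up to 30 clusters by default); clusters
must contain strictly more than 10 cells and be spatially aggregated to
count as valid regions, and a second, coarser elbow (below 15 clusters)
groups regions into realms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.sparse.csgraph import connected_components
from scipy.stats import pearsonr
from skbio import DistanceMatrix

from .grid import HexGrid

__all__ = [
    "LINKAGE_ALGORITHMS",
    "UNASSIGNED",
    "Dendrogram",
    "Regionalization",
    "ElbowCurve",
    "hierarchical_cluster",
    "evaluate_dendrogram",
    "select_algorithm",
    "variance_explained_curve",
    "elbow",
    "delineate_regions",
    "assign_realms",
]

# name -> scipy linkage method.  Dict order is the tie-break preference used
# by select_algorithm; UPGMA leads because it is the field's default for
# turnover-based regionalization, and on an ultrametric input several
# linkages reproduce the distances exactly and tie at zero distortion.
LINKAGE_ALGORITHMS = {
    "UPGMA": "average",
    "UPGMC": "centroid",
    "WARD": "ward",
    "SL": "single",
    "CL": "complete",
    "WPGMA": "weighted",
    "WPGMC": "median",
}

UNASSIGNED = "unassigned"


@dataclass
class Dendrogram:
    """Agglomerative merge sequence over n cells (scipy linkage encoding)."""

    ids: list[str]
    linkage: np.ndarray
    method: str

    def __post_init__(self) -> None:
        if self.linkage.shape != (len(self.ids) - 1, 4):
            raise ValueError("linkage must encode n-1 merges")

    def cophenetic(self) -> np.ndarray:
        """Condensed cophenetic distances (merge height of each cell pair)."""
        return hierarchy.cophenet(self.linkage)

    def cut(self, k: int) -> np.ndarray:
        """Flat cluster labels (0-based, order of appearance) at k clusters."""
        n = len(self.ids)
        if k == n:  # scipy's cut_tree mislabels the all-singletons cut
            return np.arange(n)
        labels = hierarchy.cut_tree(self.linkage, n_clusters=k).ravel()
        # renumber by first appearance so labeling is order-stable
        seen: dict[int, int] = {}
        out = np.empty_like(labels)
        for i, lab in enumerate(labels):
            out[i] = seen.setdefault(lab, len(seen))
        return out

    def to_newick(self, path: str | Path) -> None:
        """Write the dendrogram as a Newick tree with branch lengths."""
        root = hierarchy.to_tree(self.linkage)

        def fmt(node, parent_height):
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                return f"{self.ids[node.id]}:{length:.10g}"
            left = fmt(node.left, node.dist)
            right = fmt(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        with open(path, "w") as fh:
            fh.write(f"({fmt(root.left, root.dist)},{fmt(root.right, root.dist)});\n")


@dataclass
class ElbowCurve:
    """Variance explained by k clusters, k = 1..k_max."""

    k: np.ndarray
    variance_explained: np.ndarray

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"k": self.k, "variance_explained": self.variance_explained}
        ).to_csv(path, index=False)


@dataclass
class Regionalization:
    """Cell -> region labeling with optional region -> realm grouping.

    Cells of invalid clusters carry the explicit :data:`UNASSIGNED` label;
    realms, when present, partition the valid regions.
    """

    region_of_cell: pd.Series
    cell_areas: pd.Series
    realm_of_region: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.region_of_cell = self.region_of_cell.astype(str)
        self.region_of_cell.index = self.region_of_cell.index.astype(str)
        self.cell_areas = self.cell_areas.astype(float).reindex(
            self.region_of_cell.index
        )
        if self.cell_areas.isna().any():
            raise ValueError("every labeled cell needs an area")

    @classmethod
    def from_labels(
        cls, labels: dict[str, str], areas: dict[str, float] | float = 1.0
    ) -> "Regionalization":
        cells = sorted(labels)
        if isinstance(areas, dict):
            area_s = pd.Series({c: areas[c] for c in cells})
        else:
            area_s = pd.Series(float(areas), index=cells)
        return cls(pd.Series({c: labels[c] for c in cells}), area_s)

    @property
    def cells(self) -> list[str]:
        return list(self.region_of_cell.index)

    @property
    def valid_cells(self) -> pd.Index:
        return self.region_of_cell.index[self.region_of_cell != UNASSIGNED]

    @property
    def regions(self) -> list[str]:
        labs = self.region_of_cell[self.region_of_cell != UNASSIGNED]
        return sorted(labs.unique())

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def to_frame(self) -> pd.DataFrame:
        realm = (
            self.region_of_cell.map(lambda r: (self.realm_of_region or {}).get(r, ""))
        )
        return pd.DataFrame(
            {
                "cell_id": self.region_of_cell.index,
                "region": self.region_of_cell.values,
                "realm": realm.values,
                "valid": (self.region_of_cell != UNASSIGNED).values,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, areas: dict[str, float] | float = 1.0):
        df = pd.read_csv(path, dtype={"cell_id": str, "region": str, "realm": str})
        labels = dict(zip(df["cell_id"], df["region"]))
        reg = cls.from_labels(labels, areas)
        if "realm" in df and df["realm"].notna().any():
            pairs = df[df["region"] != UNASSIGNED][["region", "realm"]].dropna()
            reg.realm_of_region = dict(
                pairs.drop_duplicates().itertuples(index=False)
            )
        return reg


def hierarchical_cluster(dm: DistanceMatrix, method: str = "UPGMA") -> Dendrogram:
    """Agglomerative clustering of a dissimilarity matrix.

    ``method`` is one of the seven classical linkages (see
    :data:`LINKAGE_ALGORITHMS`).  The merge sequence is deterministic for a
    fixed input ordering; scipy breaks merge-height ties by the lowest pair
    index.
    """
    if method not in LINKAGE_ALGORITHMS:
        raise ValueError(
            f"unknown linkage {method!r}; expected one of {list(LINKAGE_ALGORITHMS)}"
        )
    z = hierarchy.linkage(dm.condensed_form(), method=LINKAGE_ALGORITHMS[method])
    return Dendrogram(list(dm.ids), z, method)


def evaluate_dendrogram(
    dend: Dendrogram, dm: DistanceMatrix
) -> tuple[float, float]:
    """Distortion of a dendrogram w.r.t. its input distances.

    Returns ``(cophenetic_r, gower_d)``: the Pearson correlation between
    cophenetic and input distances over all pairs, and the sum of squared
    deviations between them.
    """
    if list(dend.ids) != list(dm.ids):
        raise ValueError("dendrogram and matrix cover different cells")
    coph = dend.cophenetic()
    orig = dm.condensed_form()
    if np.ptp(orig) == 0 or np.ptp(coph) == 0:
        raise ValueError("correlation undefined for constant distances")
    r = float(pearsonr(coph, orig).statistic)
    gower = float(((coph - orig) ** 2).sum())
    return r, gower


def select_algorithm(evals: dict[str, tuple[float, float]]) -> str:
    """Pick the linkage with the highest cophenetic correlation.

    Ties are broken by the lowest Gower distance, then by the canonical
    algorithm order.
    """
    if not evals:
        raise ValueError("no algorithm evaluations given")
    order = {name: i for i, name in enumerate(LINKAGE_ALGORITHMS)}
    return min(
        evals, key=lambda a: (-evals[a][0], evals[a][1], order.get(a, len(order)))
    )


def variance_explained_curve(
    dm: DistanceMatrix, dend: Dendrogram, k_max: int = 30
) -> ElbowCurve:
    """Fraction of squared dissimilarity explained by k clusters, k=1..k_max.

    ``VE(k) = 1 − (Σ within-cluster d²) / (Σ all-pair d²)`` for the flat cut
    of the dendrogram at k clusters; nondecreasing in k because cuts of one
    dendrogram are nested.
    """
    n = len(dend.ids)
    if k_max > n:
        raise ValueError("k_max exceeds the number of cells")
    sq = dm.data**2
    total = sq.sum() / 2.0
    ks = np.arange(1, k_max + 1)
    if total == 0:
        warnings.warn("all dissimilarities are zero; variance explained undefined")
        return ElbowCurve(ks, np.ones(len(ks)))
    ve = np.empty(len(ks))
    for j, k in enumerate(ks):
        labels = dend.cut(k)
        within = sum(
            sq[np.ix_(labels == lab, labels == lab)].sum() / 2.0
            for lab in np.unique(labels)
        )
        ve[j] = 1.0 - within / total
    return ElbowCurve(ks, ve)


def elbow(curve: ElbowCurve) -> int:
    """Cluster count at maximum curvature of the variance-explained curve.

    Both axes are min-max normalized; the elbow is the interior point with
    the greatest perpendicular distance to the chord joining the curve's
    endpoints.  Ties go to the smallest k; a perfectly linear curve has no
    elbow and falls back to the smallest interior k with a warning.
    """
    ks = np.asarray(curve.k, dtype=float)
    ve = np.asarray(curve.variance_explained, dtype=float)
    if len(ks) < 3:
        raise ValueError("elbow needs at least three curve points")
    x = (ks - ks.min()) / np.ptp(ks)
    y = (ve - ve.min()) / np.ptp(ve) if np.ptp(ve) > 0 else np.zeros_like(ve)
    p0, p1 = np.array([x[0], y[0]]), np.array([x[-1], y[-1]])
    chord = p1 - p0
    dist = np.abs(
        chord[0] * (y - p0[1]) - chord[1] * (x - p0[0])
    ) / np.linalg.norm(chord)
    interior = dist[1:-1]
    if np.all(interior <= 1e-12):
        warnings.warn("variance-explained curve has no elbow; using smallest k")
        return int(curve.k[1])
    return int(curve.k[1:-1][int(np.argmax(interior))])


def _largest_component_fraction(cells: list[str], grid: HexGrid) -> float:
    adj = grid.adjacency_matrix(subset=cells)
    n_comp, labels = connected_components(adj, directed=False)
    return np.bincount(labels).max() / len(cells)


def delineate_regions(
    dend: Dendrogram,
    k: int,
    grid: HexGrid,
    min_cells: int = 10,
    aggregation_threshold: float = 0.5,
) -> Regionalization:
    """Cut the dendrogram at k clusters and keep the valid ones as regions.

    A cluster is a valid region iff it has strictly more than ``min_cells``
    cells and its largest connected component on the grid adjacency graph
    holds at least ``aggregation_threshold`` of its cells (the "clearly
    aggregated in space" rule).  Cells of invalid clusters are labeled
    :data:`UNASSIGNED`.
    """
    missing = [c for c in dend.ids if c not in grid]
    if missing:
        raise ValueError(f"cells absent from the grid: {missing[:5]}")
    labels = dend.cut(k)
    region_of_cell: dict[str, str] = {}
    next_region = 1
    for lab in range(labels.max() + 1):
        members = [c for c, g in zip(dend.ids, labels) if g == lab]
        valid = len(members) > min_cells and (
            _largest_component_fraction(members, grid) >= aggregation_threshold
        )
        name = f"R{next_region}" if valid else UNASSIGNED
        if valid:
            next_region += 1
        for c in members:
            region_of_cell[c] = name
    areas = {c: grid.areas[grid.index_of(c)] for c in dend.ids}
    return Regionalization.from_labels(region_of_cell, areas)


def assign_realms(
    dend: Dendrogram,
    regions: Regionalization,
    dm: DistanceMatrix,
    max_realms: int = 15,
) -> Regionalization:
    """Group valid regions into realms by a coarser cut of the same dendrogram.

    The realm count is the elbow of the variance-explained curve restricted
    to fewer than ``max_realms`` clusters; each valid region inherits the
    realm label held by the majority of its cells.  Because both cuts come
    from one dendrogram, realms nest regions exactly.
    """
    if regions.n_regions == 0:
        raise ValueError("no valid regions to group into realms")
    curve = variance_explained_curve(
        dm, dend, k_max=min(max_realms - 1, len(dend.ids))
    )
    k_realm = elbow(curve)
    realm_labels = dend.cut(k_realm)
    realm_of_cell = pd.Series(realm_labels, index=dend.ids)
    realm_of_region: dict[str, str] = {}
    realm_names: dict[int, str] = {}
    for region in regions.regions:
        cells = regions.region_of_cell.index[regions.region_of_cell == region]
        majority = int(realm_of_cell.loc[cells].mode().iloc[0])
        name = realm_names.setdefault(majority, f"K{len(realm_names) + 1}")
        realm_of_region[region] = name
    return Regionalization(
        regions.region_of_cell.copy(), regions.cell_areas.copy(), realm_of_region
    )
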