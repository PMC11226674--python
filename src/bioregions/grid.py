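"""Equal-area hexagonal grids.

A :class:`HexGrid` carries cell identifiers, planar equal-area centroid
coordinates (km), cell areas (km^2) and the cell adjacency relation.  The
built-in constructor :func:`build_hex_grid` produces a planar pointy-top
lattice; real-world grids (e.g. an equal-area Earth tessellation built
elsewhere) are ingested through :meth:`HexGrid.from_csv`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = ["HexGrid", "build_hex_grid"]


@dataclass
class HexGrid:
    """Planar grid of equal-area cells with adjacency.

    Parameters
    ----------
    cell_ids
        Unique string identifiers, one per cell.
    centroids
        ``(n, 2)`` array of planar equal-area centroid coordinates in km.
    areas
        Cell areas in km^2, all positive.
    neighbors
        Mapping cell id -> list of adjacent cell ids.  Must be symmetric
        and free of self-loops.
    """

    cell_ids: list[str]
    centroids: np.ndarray
    areas: np.ndarray
    neighbors: dict[str, list[str]]
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        n = len(self.cell_ids)
        if len(set(self.cell_ids)) != n:
            raise ValueError("cell ids must be unique")
        if self.centroids.shape != (n, 2):
            raise ValueError(f"centroids must have shape ({n}, 2)")
        if self.areas.shape != (n,) or np.any(self.areas <= 0):
            raise ValueError("areas must be positive, one per cell")
        self._index = {c: i for i, c in enumerate(self.cell_ids)}
        for c, nbrs in self.neighbors.items():
            if c not in self._index:
                raise ValueError(f"unknown cell in adjacency: {c}")
            for m in nbrs:
                if m == c:
                    raise ValueError(f"self-loop in adjacency at {c}")
                if c not in self.neighbors.get(m, ()):
                    raise ValueError(f"asymmetric adjacency: {c} -> {m}")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def index_of(self, cell_id: str) -> int:
        return self._index[cell_id]

    def __contains__(self, cell_id: str) -> bool:
        return cell_id in self._index

    def adjacency_matrix(self, subset: list[str] | None = None) -> sparse.csr_matrix:
        """Boolean adjacency as a sparse matrix over ``subset`` (default all)."""
        ids = self.cell_ids if subset is None else list(subset)
        pos = {c: i for i, c in enumerate(ids)}
        rows, cols = [], []
        for c in ids:
            for m in self.neighbors.get(c, ()):
                if m in pos:
                    rows.append(pos[c])
                    cols.append(pos[m])
        n = len(ids)
        data = np.ones(len(rows), dtype=bool)
        return sparse.csr_matrix((data, (rows, cols)), shape=(n, n))

    def subset(self, keep: list[str]) -> "HexGrid":
        """Restrict the grid to ``keep`` (order preserved); adjacency induced."""
        keep_set = set(keep)
        idx = [self._index[c] for c in keep]
        nbrs = {
            c: [m for m in self.neighbors.get(c, ()) if m in keep_set] for c in keep
        }
        return HexGrid(list(keep), self.centroids[idx], self.areas[idx], nbrs)

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, grid_path: str | Path, adjacency_path: str | Path) -> None:
        pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "x": self.centroids[:, 0],
                "y": self.centroids[:, 1],
                "area": self.areas,
            }
        ).to_csv(grid_path, index=False)
        rows = [
            (c, m) for c in self.cell_ids for m in sorted(self.neighbors.get(c, ()))
        ]
        pd.DataFrame(rows, columns=["cell_id", "neighbor_id"]).to_csv(
            adjacency_path, index=False
        )

    @classmethod
    def from_csv(
        cls, grid_path: str | Path, adjacency_path: str | Path | None = None
    ) -> "HexGrid":
        df = pd.read_csv(grid_path, dtype={"cell_id": str})
        neighbors: dict[str, list[str]] = {c: [] for c in df["cell_id"]}
        if adjacency_path is not None:
            adj = pd.read_csv(
                adjacency_path, dtype={"cell_id": str, "neighbor_id": str}
            )
            for c, m in adj.itertuples(index=False):
                neighbors[c].append(m)
        return cls(
            list(df["cell_id"]),
            df[["x", "y"]].to_numpy(float),
            df["area"].to_numpy(float),
            neighbors,
        )


def build_hex_grid(n_cols: int, n_rows: int, cell_area: float = 5e4) -> HexGrid:
    """Build a pointy-top hexagonal lattice of ``n_rows`` x ``n_cols`` cells.

    Cells are laid out in "odd-r" offset rows: odd rows are shifted right by
    half a column.  For hexagon area :math:`A` and side :math:`s`,
    :math:`A = (3\\sqrt{3}/2)\\,s^2`; centroid spacing is :math:`\\sqrt{3}\\,s`
    horizontally and :math:`1.5\\,s` vertically.  Interior cells have six
    neighbors; the lattice boundary is not wrapped.

    Parameters
    ----------
    n_cols, n_rows
        Lattice dimensions, both >= 1.
    cell_area
        Uniform cell area in km^2 (default 5e4, i.e. 50,000 km^2).
    """
    if n_cols < 1 or n_rows < 1:
        raise ValueError("grid dimensions must be >= 1")
    if cell_area <= 0:
        raise ValueError("cell_area must be positive")
    side = np.sqrt(2.0 * cell_area / (3.0 * np.sqrt(3.0)))
    dx, dy = np.sqrt(3.0) * side, 1.5 * side

    width = len(str(n_cols * n_rows - 1))
    ids, xs, ys = [], [], []
    for r in range(n_rows):
        for c in range(n_cols):
            ids.append(f"h{r * n_cols + c:0{width}d}")
            xs.append(c * dx + (dx / 2.0 if r % 2 else 0.0))
            ys.append(r * dy)

    # odd-r offset neighbor stencils
    even = [(1, 0), (-1, 0), (0, 1), (0, -1), (-1, 1), (-1, -1)]
    odd = [(1, 0), (-1, 0), (0, 1), (0, -1), (1, 1), (1, -1)]
    neighbors: dict[str, list[str]] = {}
    for r in range(n_rows):
        for c in range(n_cols):
            nbrs = []
            for dc, dr in odd if r % 2 else even:
                cc, rr = c + dc, r + dr
                if 0 <= cc < n_cols and 0 <= rr < n_rows:
                    nbrs.append(ids[rr * n_cols + cc])
            neighbors[ids[r * n_cols + c]] = nbrs

    centroids = np.column_stack([xs, ys])
    areas = np.full(len(ids), float(cell_area))
    return HexGrid(ids, centroids, areas, neighbors)
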