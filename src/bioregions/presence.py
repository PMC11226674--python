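"""Cell x taxon presence-absence matrices and cell-level filtering.

The :class:`PresenceMatrix` is the assemblage substrate for all turnover
computation: a binary incidence matrix whose rows are grid cells and whose
columns are taxa.  Fine-resolution range rasters are brought onto the grid
by :func:`aggregate_presence` (logical OR over the fine cells of each grid
cell), and cells too poor to yield a trustworthy dissimilarity are removed
by :func:`filter_cells`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["PresenceMatrix", "aggregate_presence", "filter_cells"]


class PresenceMatrix:
    """Binary cell x taxon incidence matrix.

    Wraps a pandas DataFrame with string cell ids as the index, taxon names
    as columns, and entries in {0, 1}.
    """

    def __init__(self, incidence: pd.DataFrame):
        df = incidence.copy()
        df.index = df.index.astype(str)
        values = df.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValueError("presence matrix entries must be 0 or 1")
        if df.index.has_duplicates or df.columns.has_duplicates:
            raise ValueError("cell ids and taxon names must be unique")
        self.df = df.astype(np.int8)

    @property
    def cells(self) -> list[str]:
        return list(self.df.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.df.shape

    def taxa_of(self, cell_id: str) -> set[str]:
        """Assemblage of one cell: the set of taxa present there."""
        row = self.df.loc[cell_id]
        return set(row.index[row.to_numpy() == 1])

    def richness(self) -> pd.Series:
        """Per-cell taxon counts."""
        return self.df.sum(axis=1)

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index_label="cell_id")

    @classmethod
    def from_csv(cls, path: str | Path) -> "PresenceMatrix":
        return cls(pd.read_csv(path, index_col="cell_id", dtype={"cell_id": str}))

    def to_triplets(self, path: str | Path) -> None:
        """Write sparse triplet CSV (cell_id, taxon, 1) of the present entries."""
        stacked = self.df.stack()
        stacked = stacked[stacked == 1]
        out = stacked.reset_index()
        out.columns = ["cell_id", "taxon", "present"]
        out.to_csv(path, index=False)

    @classmethod
    def from_triplets(cls, path: str | Path) -> "PresenceMatrix":
        df = pd.read_csv(path, dtype={"cell_id": str, "taxon": str})
        wide = (
            df.assign(present=1)
            .pivot_table(
                index="cell_id", columns="taxon", values="present", fill_value=0
            )
            .astype(np.int8)
        )
        wide.columns.name = None
        wide.index.name = None
        return cls(wide)


def aggregate_presence(
    fine_presence: dict[str, set[str]], fine_to_hex: dict[str, str]
) -> PresenceMatrix:
    """Resample fine-cell presences to the grid by maximum (logical OR).

    A taxon is present in a grid cell iff it is present in at least one of
    the fine cells mapped to it.

    Parameters
    ----------
    fine_presence
        Mapping taxon -> set of fine-cell ids where it occurs.
    fine_to_hex
        Mapping fine-cell id -> grid cell id; every fine cell referenced by
        ``fine_presence`` must be mapped.
    """
    taxa = sorted(fine_presence)
    hexes = sorted(set(fine_to_hex.values()))
    hex_pos = {h: i for i, h in enumerate(hexes)}
    out = np.zeros((len(hexes), len(taxa)), dtype=np.int8)
    for j, taxon in enumerate(taxa):
        for fine in fine_presence[taxon]:
            if fine not in fine_to_hex:
                raise ValueError(f"fine cell {fine!r} has no grid cell assignment")
            out[hex_pos[fine_to_hex[fine]], j] = 1
    return PresenceMatrix(pd.DataFrame(out, index=hexes, columns=taxa))


def filter_cells(pm: PresenceMatrix, min_taxa: int = 5) -> PresenceMatrix:
    """Drop cells with fewer than ``min_taxa`` taxa, then empty taxon columns.

    Cells below the richness floor distort dissimilarities (a tiny
    assemblage makes min(b, c) unstable), hence the default floor of 5.
    Row and column order of the survivors is preserved; the operation is
    idempotent.

    Raises
    ------
    ValueError
        If no cell survives the filter.
    """
    rows = pm.df.sum(axis=1) >= min_taxa
    if not rows.any():
        raise ValueError(f"no valid cells: all have fewer than {min_taxa} taxa")
    kept = pm.df.loc[rows]
    kept = kept.loc[:, kept.sum(axis=0) >= 1]
    return PresenceMatrix(kept)
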