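"""Nonmetric multidimensional scaling of turnover and geographic rotation.

NMDS embeds the cells in a low-dimensional space so that the rank order of
configuration distances matches the rank order of the βsim dissimilarities
as closely as possible.  Fit is measured by Kruskal stress-1,

    stress = sqrt( Σ (d̂_ij − d_ij)² / Σ d_ij² ),

where d_ij are the configuration distances and d̂_ij their monotone
(isotonic) regression on the dissimilarities; many random starts guard
against local minima.  Because stress depends only on distance ranks, the
solution is free to be rotated, reflected and scaled — which is used to
align it with geography by orthogonal Procrustes superimposition onto the
cell centroids.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof

__all__ = ["OrdinationResult", "nmds", "rotate_to_geography", "stress1"]


@dataclass
class OrdinationResult:
    """An NMDS configuration with its Kruskal stress-1."""

    ids: list[str]
    coordinates: np.ndarray
    stress: float
    best_start: int
    n_starts: int

    def to_frame(self) -> pd.DataFrame:
        cols = [f"axis{i + 1}" for i in range(self.coordinates.shape[1])]
        df = pd.DataFrame(self.coordinates, columns=cols)
        df.insert(0, "cell_id", self.ids)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def stress1(dissimilarities: np.ndarray, coordinates: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against a dissimilarity matrix."""
    d_hat_input = squareform(dissimilarities, checks=False)
    d_conf = pdist(coordinates)
    iso = IsotonicRegression(increasing=True)
    fitted = iso.fit_transform(d_hat_input, d_conf)
    denom = (d_conf**2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((fitted - d_conf) ** 2).sum() / denom))


def nmds(
    dm: DistanceMatrix,
    dims: int = 2,
    n_starts: int = 200,
    max_iter: int = 300,
    seed: int = 0,
) -> OrdinationResult:
    """Best-of-``n_starts`` nonmetric MDS of a dissimilarity matrix.

    Each start runs SMACOF with monotone regression from an independent
    random initialization (convergence tolerance 1e-7 on the stress
    change); the configuration with the lowest stress-1 wins and is
    centered at the origin.
    """
    n = dm.shape[0]
    if n < dims + 1:
        raise ValueError("need at least dims + 1 cells to ordinate")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    data = dm.data
    best: tuple[float, int, np.ndarray] | None = None
    for start in range(n_starts):
        coords, _ = smacof(
            data,
            metric=False,
            n_components=dims,
            n_init=1,
            max_iter=max_iter,
            eps=1e-7,
            random_state=seed + start,
            normalized_stress=True,
        )
        s = stress1(data, coords)
        if best is None or s < best[0]:
            best = (s, start, coords)
    s, start, coords = best
    coords = coords - coords.mean(axis=0)
    return OrdinationResult(list(dm.ids), coords, s, start, n_starts)


def rotate_to_geography(
    ordination: OrdinationResult, centroids: dict[str, tuple[float, float]]
) -> OrdinationResult:
    """Superimpose the ordination onto geographic space by Procrustes.

    Finds the similarity transform (rotation, optional reflection, uniform
    scaling, translation) of the configuration minimizing the summed
    squared distances to the cell centroids.  Stress is unchanged: it
    depends only on distance ranks, which similarity transforms preserve.
    """
    missing = [c for c in ordination.ids if c not in centroids]
    if missing:
        raise ValueError(f"no centroid for cells {missing[:5]}")
    target = np.array([centroids[c] for c in ordination.ids], dtype=float)
    target_c = target - target.mean(axis=0)
    if np.allclose(target_c, 0):
        raise ValueError("degenerate geography: all centroids identical")
    x = ordination.coordinates - ordination.coordinates.mean(axis=0)
    u, sv, vt = np.linalg.svd(x.T @ target_c)
    rotation = u @ vt
    scale = sv.sum() / (x**2).sum()
    rotated = scale * x @ rotation + target.mean(axis=0)
    return OrdinationResult(
        list(ordination.ids),
        rotated,
        ordination.stress,
        ordination.best_start,
        ordination.n_starts,
    )
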