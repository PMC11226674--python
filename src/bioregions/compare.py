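"""Statistical comparison of independent regionalizations.

Two regionalizations of the same grid are compared through the area
cross-tabulation of their regions.  The V-measure (Vβ) is the harmonic
mean of two conditional-entropy scores computed from that table —
homogeneity, 1 − H(B|A)/H(B), and completeness, 1 − H(A|B)/H(A) — so it is
an area-weighted, symmetric measure of spatial association in [0, 1].
Per-region homogeneity (1 minus the normalized Shannon entropy of the
compared scheme's labels inside a focal region) maps where one scheme's
regions nest inside the other's.

Significance is assessed against a null of spatially coherent but random
regionalizations: Voronoi tessellations seeded at randomly drawn cells,
preserving the randomized scheme's region count.  Each ordered pair yields
a directional p-value (share of nulls at least as congruent as observed,
with the add-one estimator) and a standardized effect size
(observed minus null mean, over the null standard deviation).

A Mantel permutation test compares dissimilarity matrices directly (used
for sensitivity checks between turnover variants).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as _skbio_mantel

from .cluster import UNASSIGNED, Regionalization
from .grid import HexGrid

__all__ = [
    "VMeasureResult",
    "NullComparison",
    "area_crosstab",
    "v_measure",
    "random_voronoi_regionalization",
    "null_comparison",
    "mantel",
]


@dataclass
class VMeasureResult:
    """Homogeneity, completeness and their harmonic mean Vβ."""

    h: float
    comp: float
    v: float
    per_region_homogeneity: dict[str, float]


@dataclass
class NullComparison:
    """Observed Vβ against two directional Voronoi null distributions.

    ``null_v_a`` compares scheme A with randomizations of B; ``null_v_b``
    the reverse.  SES values are NaN when a null distribution has zero
    variance.
    """

    v_obs: float
    null_v_a: np.ndarray
    null_v_b: np.ndarray
    p_a: float
    p_b: float
    ses_a: float
    ses_b: float

    def summary(self) -> dict:
        return {
            "v_obs": self.v_obs,
            "p_a": self.p_a,
            "p_b": self.p_b,
            "ses_a": self.ses_a,
            "ses_b": self.ses_b,
            "null_a_mean": float(self.null_v_a.mean()),
            "null_a_sd": float(self.null_v_a.std(ddof=1)),
            "null_b_mean": float(self.null_v_b.mean()),
            "null_b_sd": float(self.null_v_b.std(ddof=1)),
        }


def _shared_codes(
    reg_a: Regionalization, reg_b: Regionalization
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str], list[str]]:
    """Integer region codes and areas over the cells valid in both schemes."""
    shared = reg_a.valid_cells.intersection(reg_b.valid_cells)
    if len(shared) == 0:
        raise ValueError("the two regionalizations share no valid cells")
    a = reg_a.region_of_cell.loc[shared]
    b = reg_b.region_of_cell.loc[shared]
    a_names = sorted(a.unique())
    b_names = sorted(b.unique())
    a_codes = a.map({n: i for i, n in enumerate(a_names)}).to_numpy()
    b_codes = b.map({n: i for i, n in enumerate(b_names)}).to_numpy()
    areas = reg_a.cell_areas.loc[shared].to_numpy()
    return a_codes, b_codes, areas, a_names, b_names


def _crosstab_array(
    a_codes: np.ndarray, b_codes: np.ndarray, areas: np.ndarray, n_a: int, n_b: int
) -> np.ndarray:
    flat = np.bincount(a_codes * n_b + b_codes, weights=areas, minlength=n_a * n_b)
    return flat.reshape(n_a, n_b)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _v_from_crosstab(ct: np.ndarray) -> tuple[float, float, float, np.ndarray]:
    """(h, comp, v, per-A-region homogeneity) from an area cross-tab array."""
    total = ct.sum()
    if total <= 0:
        raise ValueError("cross-tabulation has zero total area")
    p = ct / total
    pa, pb = p.sum(axis=1), p.sum(axis=0)
    h_a, h_b = _entropy(pa), _entropy(pb)
    h_b_given_a = sum(
        pa[i] * _entropy(p[i] / pa[i]) for i in range(len(pa)) if pa[i] > 0
    )
    h_a_given_b = sum(
        pb[j] * _entropy(p[:, j] / pb[j]) for j in range(len(pb)) if pb[j] > 0
    )
    h = 1.0 if h_b == 0 else 1.0 - h_b_given_a / h_b
    comp = 1.0 if h_a == 0 else 1.0 - h_a_given_b / h_a
    v = 0.0 if h + comp == 0 else 2.0 * h * comp / (h + comp)
    n_b = ct.shape[1]
    per_region = np.ones(ct.shape[0])
    if n_b > 1:
        for i in range(ct.shape[0]):
            if pa[i] > 0:
                per_region[i] = 1.0 - _entropy(p[i] / pa[i]) / np.log(n_b)
    return h, comp, v, per_region


def area_crosstab(reg_a: Regionalization, reg_b: Regionalization) -> pd.DataFrame:
    """Region-by-region overlap areas over the cells valid in both schemes.

    Entry (i, j) is the summed area of cells labeled i by scheme A and j by
    scheme B; row sums are A-region areas, column sums B-region areas.
    Unassigned cells are excluded.
    """
    a_codes, b_codes, areas, a_names, b_names = _shared_codes(reg_a, reg_b)
    ct = _crosstab_array(a_codes, b_codes, areas, len(a_names), len(b_names))
    return pd.DataFrame(ct, index=a_names, columns=b_names)


def v_measure(ct: pd.DataFrame | np.ndarray) -> VMeasureResult:
    """Area-weighted V-measure of an area cross-tabulation.

    With joint area fractions p_ij and natural-log Shannon entropies,
    homogeneity is 1 − H(B|A)/H(B) and completeness 1 − H(A|B)/H(A)
    (defined as 1 when the reference entropy is zero); Vβ is their harmonic
    mean.  Per-region homogeneity of A-region i is
    1 − H(B|A=i)/ln(n_B), i.e. one minus the normalized Shannon entropy of
    B's labels within that region.
    """
    if isinstance(ct, pd.DataFrame):
        names = [str(i) for i in ct.index]
        arr = ct.to_numpy(dtype=float)
    else:
        arr = np.asarray(ct, dtype=float)
        names = [str(i) for i in range(arr.shape[0])]
    if np.any(arr < 0):
        raise ValueError("cross-tabulation entries must be nonnegative")
    h, comp, v, per_region = _v_from_crosstab(arr)
    return VMeasureResult(h, comp, v, dict(zip(names, per_region)))


def _voronoi_labels(grid: HexGrid, seed_idx: np.ndarray) -> np.ndarray:
    dists = np.linalg.norm(
        grid.centroids[:, None, :] - grid.centroids[seed_idx][None, :, :], axis=2
    )
    return dists.argmin(axis=1)  # ties -> lowest seed index


def random_voronoi_regionalization(
    grid: HexGrid, k: int, rng_seed: int = 0
) -> Regionalization:
    """A random spatially coherent regionalization with k regions.

    k seed cells are drawn uniformly without replacement and every cell is
    assigned to its nearest seed by centroid distance (ties to the lowest
    seed index); all regions are valid.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > grid.n_cells:
        raise ValueError("k exceeds the number of cells")
    rng = np.random.default_rng(rng_seed)
    seed_idx = rng.choice(grid.n_cells, size=k, replace=False)
    nearest = _voronoi_labels(grid, seed_idx)
    labels = {c: f"V{nearest[i] + 1}" for i, c in enumerate(grid.cell_ids)}
    areas = dict(zip(grid.cell_ids, grid.areas))
    return Regionalization.from_labels(labels, areas)


def null_comparison(
    reg_a: Regionalization,
    reg_b: Regionalization,
    grid: HexGrid,
    n_null: int = 999,
    seed: int = 0,
) -> NullComparison:
    """Test the observed Vβ against Voronoi-randomization nulls.

    Each null replaces one scheme by a random Voronoi regionalization with
    that scheme's observed region count and recomputes Vβ against the other
    scheme, restricted to the cells valid in both observed schemes.  The
    directional p-value is (#{null ≥ observed} + 1)/(n_null + 1) — ties
    count against significance — and SES is
    (observed − null mean)/null sd.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    a_codes, b_codes, areas, a_names, b_names = _shared_codes(reg_a, reg_b)
    shared = reg_a.valid_cells.intersection(reg_b.valid_cells)
    cell_pos = np.array([grid.index_of(c) for c in shared])
    n_a, n_b = len(a_names), len(b_names)
    v_obs = _v_from_crosstab(_crosstab_array(a_codes, b_codes, areas, n_a, n_b))[2]

    rng = np.random.default_rng(seed)

    def null_draws(fixed_codes: np.ndarray, n_fixed: int, k_random: int) -> np.ndarray:
        out = np.empty(n_null)
        for i in range(n_null):
            seed_idx = rng.choice(grid.n_cells, size=k_random, replace=False)
            null_codes = _voronoi_labels(grid, seed_idx)[cell_pos]
            ct = _crosstab_array(fixed_codes, null_codes, areas, n_fixed, k_random)
            out[i] = _v_from_crosstab(ct)[2]
        return out

    null_v_a = null_draws(a_codes, n_a, n_b)  # A vs randomized B
    null_v_b = null_draws(b_codes, n_b, n_a)  # B vs randomized A

    def p_and_ses(null_v: np.ndarray) -> tuple[float, float]:
        p = (int((null_v >= v_obs).sum()) + 1) / (n_null + 1)
        sd = null_v.std(ddof=1)
        ses = float("nan") if sd == 0 else (v_obs - null_v.mean()) / sd
        return float(p), float(ses)

    p_a, ses_a = p_and_ses(null_v_a)
    p_b, ses_b = p_and_ses(null_v_b)
    return NullComparison(v_obs, null_v_a, null_v_b, p_a, p_b, ses_a, ses_b)


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel permutation test between two dissimilarity matrices.

    Returns the Pearson correlation of the off-diagonal vectors and the
    two-sided permutation p-value, (#{|r_perm| ≥ |r|} + 1)/(n_perm + 1),
    under simultaneous row/column permutations of the second matrix.
    """
    if list(d1.ids) != list(d2.ids):
        raise ValueError("matrices cover different cell sets or orderings")
    if np.ptp(d1.condensed_form()) == 0 or np.ptp(d2.condensed_form()) == 0:
        raise ValueError("correlation undefined for a constant matrix")
    r, p, _ = _skbio_mantel(
        d1, d2, method="pearson", permutations=n_perm, alternative="two-sided",
        seed=seed,
    )
    return float(r), float(p)
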