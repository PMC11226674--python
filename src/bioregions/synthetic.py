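"""Synthetic assemblages with planted biogeographic structure.

Ground-truth generators for end-to-end testing of the regionalization
pipeline without external range or phylogeny data: a Yule (pure-birth)
phylogeny, a posterior-like set of branch-length-jittered trees, planted
spatial regions on a hexagon lattice (nearest-seed tessellation), and
clade-structured presence matrices in which each planted region draws its
assemblages from its own subtree of the phylogeny, contaminated by a
tunable cross-region ``mixing`` probability.

Every generator is a pure function of its arguments and seed; a pipeline
seed is fanned out to stage seeds by fixed offsets (:data:`SEED_OFFSETS`).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .grid import HexGrid
from .presence import PresenceMatrix
from .turnover import Phylogeny, PosteriorTreeSet

__all__ = [
    "SyntheticTruth",
    "simulate_phylogeny",
    "jitter_posterior",
    "plant_regions",
    "simulate_assemblages",
    "adjusted_rand_index",
    "generate_dataset",
    "SEED_OFFSETS",
]

# fixed per-stage offsets applied to a single pipeline-level seed
SEED_OFFSETS = {
    "phylogeny": 11,
    "posterior": 22,
    "regions": 33,
    "assemblages": 44,
    "nmds": 55,
    "null": 66,
}


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic dataset.

    ``true_region_of_cell`` maps every cell to exactly one planted region;
    ``clade_of_region`` maps each region label to its taxon pool (pools are
    disjoint); ``params`` records the generating parameters.
    """

    true_region_of_cell: dict[str, str]
    clade_of_region: dict[str, set[str]]
    params: dict

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            sorted(self.true_region_of_cell.items()),
            columns=["cell_id", "true_region"],
        ).to_csv(path, index=False)


def simulate_phylogeny(n_tips: int, birth_rate: float = 1.0, seed: int = 0) -> Phylogeny:
    """Simulate a rooted binary tree under a Yule (pure-birth) process.

    Lineages split at rate ``birth_rate`` each; after the ``n_tips``-th
    lineage appears, one further exponential waiting time is appended so
    that every branch length is strictly positive.  Tips are labeled
    ``t1..tn`` in preorder.
    """
    if n_tips < 1:
        raise ValueError("n_tips must be >= 1")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    rng = np.random.default_rng(seed)

    taxon_namespace = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    birth_time = {tree.seed_node: 0.0}
    active = [tree.seed_node]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        i = int(rng.integers(len(active)))
        parent = active[i]
        parent.edge.length = (
            t - birth_time[parent] if parent is not tree.seed_node else None
        )
        children = [dendropy.Node(), dendropy.Node()]
        for child in children:
            parent.add_child(child)
            birth_time[child] = t
        active[i : i + 1] = children
    t += rng.exponential(1.0 / (birth_rate * n_tips))
    for leaf in active:
        if leaf is not tree.seed_node:
            leaf.edge.length = t - birth_time[leaf]

    for k, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = taxon_namespace.new_taxon(f"t{k}")
    return tree


def jitter_posterior(
    tree: Phylogeny, n_trees: int, sd_log: float = 0.2, seed: int = 0
) -> PosteriorTreeSet:
    """Emulate a posterior tree sample by lognormal branch-length noise.

    Topology and tip set are fixed; each branch length is multiplied by an
    independent lognormal(0, ``sd_log``) draw (multiplicative noise with
    median 1).  ``sd_log = 0`` reproduces the input exactly.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if sd_log < 0:
        raise ValueError("sd_log must be nonnegative")
    rng = np.random.default_rng(seed)
    out = dendropy.TreeList(taxon_namespace=tree.taxon_namespace)
    for _ in range(n_trees):
        clone = tree.clone(depth=1)
        for edge in clone.preorder_edge_iter():
            if edge.length is not None:
                edge.length = edge.length * rng.lognormal(0.0, sd_log)
        out.append(clone)
    return out


def plant_regions(grid: HexGrid, n_regions: int, seed: int = 0) -> dict[str, str]:
    """Plant ``n_regions`` spatial regions by nearest-seed tessellation.

    Seed cells are sampled without replacement; every cell joins the seed
    nearest to its centroid (Euclidean; ties go to the lowest seed index).
    On a convex lattice each region is spatially connected.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    if n_regions > grid.n_cells:
        raise ValueError("n_regions exceeds the number of cells")
    rng = np.random.default_rng(seed)
    seed_idx = rng.choice(grid.n_cells, size=n_regions, replace=False)
    dists = np.linalg.norm(
        grid.centroids[:, None, :] - grid.centroids[seed_idx][None, :, :], axis=2
    )
    nearest = dists.argmin(axis=1)  # ties -> lowest seed index
    return {c: f"R{nearest[i] + 1}" for i, c in enumerate(grid.cell_ids)}


def _tree_clades(tree: Phylogeny, n_clades: int, overshoot: int = 4) -> list[set[str]]:
    """Partition the tips into ``n_clades`` subtree-based pools.

    The tree is cut by expanding splits in depth order until
    ``overshoot * n_clades`` lineages exist (or all splits are exhausted),
    then the smallest pools are merged pairwise down to exactly
    ``n_clades``, which keeps pool sizes roughly balanced.
    """
    leaves = tree.leaf_nodes()
    if n_clades > len(leaves):
        raise ValueError("more clades requested than tips available")
    depth = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)

    target = min(overshoot * n_clades, len(leaves))
    frontier = [tree.seed_node]
    while len(frontier) < target:
        internal = [n for n in frontier if not n.is_leaf()]
        if not internal:
            break
        node = min(internal, key=lambda n: (depth[n], frontier.index(n)))
        i = frontier.index(node)
        frontier[i : i + 1] = node.child_nodes()

    pools = [
        {leaf.taxon.label for leaf in node.leaf_iter()} for node in frontier
    ]
    pools.sort(key=lambda p: (len(p), min(p)))
    while len(pools) > n_clades:
        a = pools.pop(0)
        b = pools.pop(0)
        merged = a | b
        pools.append(merged)
        pools.sort(key=lambda p: (len(p), min(p)))
    return sorted(pools, key=lambda p: (-len(p), min(p)))


def simulate_assemblages(
    tree: Phylogeny,
    regions: dict[str, str],
    mixing: float = 0.05,
    richness: int = 12,
    seed: int = 0,
) -> tuple[PresenceMatrix, SyntheticTruth]:
    """Draw clade-structured assemblages for planted regions.

    The tree's tips are partitioned into as many clade pools as there are
    regions; each region owns one pool.  Every cell receives ``richness``
    distinct taxa; each slot is filled from the cell's own pool with
    probability ``1 - mixing`` and uniformly from the full taxon pool with
    probability ``mixing``, so ``mixing = 1`` erases the regional signal
    entirely while ``mixing = 0`` makes every taxon occur in cells of
    exactly one region (pools permitting).
    """
    if not 0.0 <= mixing <= 1.0:
        raise ValueError("mixing must be in [0, 1]")
    n_taxa = len(tree.leaf_nodes())
    if richness < 1:
        raise ValueError("richness must be >= 1")
    if richness > n_taxa:
        raise ValueError("richness exceeds the number of taxa")
    labels = sorted(set(regions.values()))
    pools = _tree_clades(tree, len(labels))
    clade_of_region = {lab: pool for lab, pool in zip(labels, pools)}

    rng = np.random.default_rng(seed)
    all_taxa = sorted({t for p in pools for t in p})
    all_arr = np.array(all_taxa)
    cells = sorted(regions)
    pm = pd.DataFrame(0, index=cells, columns=all_taxa, dtype=np.int8)
    own_arr = {lab: np.array(sorted(pool)) for lab, pool in clade_of_region.items()}
    for cell in cells:
        own = own_arr[regions[cell]]
        n_own = min(int((rng.random(richness) < 1.0 - mixing).sum()), len(own))
        chosen = (
            rng.choice(own, size=n_own, replace=False) if n_own else np.array([])
        )
        n_mix = richness - n_own
        if n_mix:
            rest = np.setdiff1d(all_arr, chosen)
            chosen = np.concatenate([chosen, rng.choice(rest, n_mix, replace=False)])
        pm.loc[cell, chosen] = 1

    truth = SyntheticTruth(
        true_region_of_cell=dict(regions),
        clade_of_region=clade_of_region,
        params={
            "n_regions": len(labels),
            "mixing": mixing,
            "richness_per_cell": richness,
            "seed": seed,
        },
    )
    return PresenceMatrix(pm), truth


def adjusted_rand_index(labels_a: dict[str, str], labels_b: dict[str, str]) -> float:
    """Chance-corrected agreement (ARI) between two cell labelings."""
    if set(labels_a) != set(labels_b):
        raise ValueError("labelings cover different cell sets")
    cells = sorted(labels_a)
    return float(
        adjusted_rand_score([labels_a[c] for c in cells], [labels_b[c] for c in cells])
    )


def generate_dataset(
    n_cols: int = 20,
    n_rows: int = 20,
    n_regions: int = 4,
    n_taxa: int = 96,
    mixing: float = 0.05,
    richness: int = 12,
    n_trees: int = 25,
    sd_log: float = 0.2,
    seed: int = 0,
):
    """One-call synthetic study: grid, tree, posterior, presences, truth.

    Returns ``(grid, tree, trees, pm, truth)``.  Stage seeds are derived
    from ``seed`` by the fixed :data:`SEED_OFFSETS`.
    """
    from .grid import build_hex_grid

    grid = build_hex_grid(n_cols, n_rows)
    tree = simulate_phylogeny(n_taxa, seed=seed + SEED_OFFSETS["phylogeny"])
    trees = jitter_posterior(
        tree, n_trees, sd_log=sd_log, seed=seed + SEED_OFFSETS["posterior"]
    )
    regions = plant_regions(grid, n_regions, seed=seed + SEED_OFFSETS["regions"])
    pm, truth = simulate_assemblages(
        tree, regions, mixing, richness, seed=seed + SEED_OFFSETS["assemblages"]
    )
    return grid, tree, trees, pm, truth
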