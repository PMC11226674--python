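import dendropy
import numpy as np
import pandas as pd
import pytest

from bioregions import PresenceMatrix, build_hex_grid


@pytest.fixture
def small_grid():
    return build_hex_grid(5, 5, cell_area=1.0)


@pytest.fixture
def lattice_20x20():
    return build_hex_grid(20, 20, cell_area=1.0)


@pytest.fixture
def three_taxon_tree():
    """((A:1,B:1):1,C:2); — the worked branch-enumeration example."""
    return dendropy.Tree.get(
        data="((A:1,B:1):1,C:2);", schema="newick", preserve_underscores=True
    )


@pytest.fixture
def abc_presence():
    """Two cells: X={A,B}, Y={A,C}."""
    df = pd.DataFrame(
        [[1, 1, 0], [1, 0, 1]], index=["X", "Y"], columns=["A", "B", "C"]
    )
    return PresenceMatrix(df)


def random_presence(n_cells, taxa, rng, min_per_cell=1):
    """Random 0/1 matrix with at least ``min_per_cell`` taxa per cell."""
    m = (rng.random((n_cells, len(taxa))) < 0.4).astype(int)
    for i in range(n_cells):
        while m[i].sum() < min_per_cell:
            m[i, rng.integers(len(taxa))] = 1
    return PresenceMatrix(
        pd.DataFrame(m, index=[f"c{i}" for i in range(n_cells)], columns=taxa)
    )


def star_tree(taxa, length=1.0):
    """Star phylogeny: every tip attached to the root by a unit branch."""
    newick = "(" + ",".join(f"{t}:{length}" for t in taxa) + ");"
    return dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )


def brute_force_pbsim(pm, tree):
    """Per-pair branch-set enumeration oracle for Pβsim.

    Independent of the package's incidence structure: for each cell the
    present edge set is built by walking each present tip's root path, and
    (a, b, c) come from explicit set operations on edge ids.
    """
    root = tree.seed_node
    leaf_of = {
        leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()
    }

    def edge_set(taxa):
        edges = set()
        for t in taxa:
            if t not in leaf_of:
                continue
            node = leaf_of[t]
            while node is not root:
                edges.add(id(node.edge))
                node = node.parent_node
        return edges

    length = {
        id(e): (e.length or 0.0)
        for e in tree.preorder_edge_iter()
        if e.head_node is not root
    }
    cells = pm.cells
    n = len(cells)
    out = np.zeros((n, n))
    sets = [edge_set(pm.taxa_of(c)) for c in cells]
    for i in range(n):
        for j in range(i + 1, n):
            a = sum(length[e] for e in sets[i] & sets[j])
            b = sum(length[e] for e in sets[i] - sets[j])
            c = sum(length[e] for e in sets[j] - sets[i])
            val = 1.0 if a == 0 else 1.0 - a / (min(b, c) + a)
            out[i, j] = out[j, i] = val
    return out
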