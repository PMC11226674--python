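# bioregions

Quantitative biogeographic regionalization from assemblage turnover.

Biodiversity is geographically structured: cells of an equal-area grid can
be clustered into discrete biogeographic regions and realms by how strongly
their assemblages (the sets of taxa present) are replaced across space.
`bioregions` implements that workflow end to end for anyone delineating
regions from presence–absence data and a phylogeny — and for anyone asking
whether two regionalizations (say, for two different taxonomic groups)
agree more than chance would allow.

The core quantities:

- **Simpson turnover** between two assemblages X, Y:
  `βsim = 1 − a/(min(b, c) + a)`, where in taxonomic mode (Tβsim)
  a, b, c are shared/unique taxon counts, and in phylogenetic mode (Pβsim)
  they are shared/unique branch lengths (an edge is present in a cell iff
  one of its descendant tips is).  Nested pairs score 0, disjoint pairs 1,
  and richness differences cancel.  Phylogenetic uncertainty is handled by
  the elementwise median of Pβsim over a posterior tree sample.
- **Regions and realms** by UPGMA-style hierarchical clustering: seven
  linkages are compared by cophenetic Pearson correlation and Gower
  distance, the cluster count is chosen at the elbow of the
  variance-explained curve, clusters must have > 10 cells and be spatially
  aggregated to count as valid regions, and a coarser elbow (< 15
  clusters) groups regions into realms.
- **NMDS ordination** (Kruskal stress-1, best of many random starts)
  rotated onto geographic space by Procrustes superimposition.
- **V-measure (Vβ)** between two regionalizations: the harmonic mean of
  homogeneity `1 − H(B|A)/H(B)` and completeness `1 − H(A|B)/H(A)`
  computed from the area cross-tabulation of their regions, tested against
  999 random Voronoi regionalizations per direction (p-values and SES),
  plus per-region homogeneity maps and a Mantel test for matrix-level
  comparisons.

A synthetic-data module generates hexagon lattices with planted spatial
regions, Yule phylogenies with jittered posterior samples, and
clade-structured assemblages with tunable cross-region mixing, so the full
pipeline is testable with known ground truth and no external data.

## Worked example

```python
from bioregions import (
    generate_dataset, filter_cells, betasim_matrix, median_posterior_betasim,
    hierarchical_cluster, variance_explained_curve, elbow,
    delineate_regions, assign_realms, adjusted_rand_index,
)

# 400-cell lattice, 4 planted regions, 96 taxa, 25-tree posterior
grid, tree, trees, pm, truth = generate_dataset(seed=1)
pm = filter_cells(pm, min_taxa=5)

pbsim = median_posterior_betasim(pm, trees)   # posterior-median Pβsim
dend = hierarchical_cluster(pbsim, "UPGMA")
curve = variance_explained_curve(pbsim, dend, k_max=30)
k = elbow(curve)
regions = delineate_regions(dend, k, grid)
regions = assign_realms(dend, regions, pbsim)

recovered = dict(regions.region_of_cell[regions.valid_cells])
ari = adjusted_rand_index(recovered, {c: truth.true_region_of_cell[c] for c in recovered})
print(f"elbow k = {k}, valid regions = {regions.n_regions}, "
      f"VE = {curve.variance_explained[k - 1]:.3f}, ARI vs truth = {ari:.3f}")
```

Output:

```
elbow k = 4, valid regions = 4, VE = 0.952, ARI vs truth = 1.000
```

The elbow of the variance-explained curve lands on the planted number of
regions (4), all four clusters pass the size and spatial-aggregation
validity rules, the cut explains 95% of the squared turnover, and the
recovered map matches the planted truth exactly (adjusted Rand index 1.0).

The same stages are available from the shell (`bioregions simulate`,
`assemble`, `turnover`, `regionalize`, `ordinate`, `compare`,
`pipeline`); see `bioregions --help`.

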