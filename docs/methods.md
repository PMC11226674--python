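# Methods

`bioregions` implements a quantitative biogeographic regionalization
workflow: starting from a binary cell × taxon presence matrix on an
equal-area grid and a (posterior sample of) rooted, branch-lengthed
phylogeny(ies), it computes pairwise turnover among cell assemblages,
delineates hierarchical regions and realms, ordinates the cells, and
statistically compares independent regionalizations.  This note documents
the models, the defaults and why they are what they are, and the
limitations of the synthetic data used for validation.

## Turnover

Dissimilarity between two assemblages X and Y is the Simpson index of
dissimilarity, which captures only the turnover (replacement) component of
beta diversity:

    βsim = 1 − a / (min(b, c) + a)

- **Taxonomic mode (Tβsim)**: a = |X ∩ Y|, b = |X \ Y|, c = |Y \ X| over
  taxon sets.
- **Phylogenetic mode (Pβsim)**: a, b, c are summed branch lengths.  A tree
  edge is "present" in a cell iff at least one of its descendant tips is
  present there; a is the length of edges present in both cells, b and c
  the lengths present in only one.  Each cell's edge set is closed under
  the ancestor relation, so Pβsim weighs deep shared history as well as
  tip identity.

Because the denominator uses min(b, c), the index is insensitive to
richness differences, and a nested pair (X ⊆ Y) scores exactly 0 while a
disjoint pair scores 1.  On a star tree with unit branch lengths the two
modes coincide — a useful analytic cross-check exploited by the tests.

Numerical choices:

- The root edge, when the Newick carries one, is excluded: it subtends
  every tip, is shared by every non-empty assemblage, and carries no
  turnover information.
- Zero-length branches are kept; they contribute 0 to a, b and c either
  way.
- Taxa absent from the tree are dropped from phylogenetic turnover with a
  logged warning and a reported count; a cell with *no* tree-matched taxa
  is a hard error (its dissimilarity would be undefined).
- A pair of empty assemblages (a = b = c = 0) is an error rather than a
  silent 0 or 1.
- The whole cell × edge incidence is built once per tree as a boolean
  matrix and all pairs are evaluated by dense matrix products, rather than
  per-pair set enumeration (the per-pair route survives in the test suite
  as the independent oracle).

Phylogenetic uncertainty is propagated by computing the Pβsim matrix for
each tree of a posterior sample and taking the **elementwise median**; for
an even number of trees the midpoint of the two central order statistics
is used (no interpolation schemes).  Per-cell **distinctiveness** is the
mean dissimilarity of a cell to all other cells.

## Assemblage construction and filtering

Fine-resolution presences are resampled to the analysis grid by maximum
(logical OR): a taxon is present in a grid cell iff it is present in at
least one constituent fine cell.  Cells with fewer than `min_taxa = 5`
taxa are then removed, because a very small assemblage makes min(b, c) —
and hence βsim — unstable; taxon columns that become empty are dropped
too.  The filter is idempotent and preserves row/column order.

The built-in grid is a planar pointy-top hexagonal lattice ("odd-r" offset
rows) with uniform cell area (default 5 × 10⁴ km²) and up to six neighbors
per cell; the boundary is not wrapped.  Real-world equal-area grids built
elsewhere are ingested through the grid/adjacency CSV reader — the package
deliberately contains no GIS machinery, and all cells are treated as
full-area (no partial coastline weighting).

## Region and realm delineation

Cells are clustered agglomeratively on the βsim matrix.  Seven classical
linkages are evaluated (UPGMA, UPGMC, WARD, SL, CL, WPGMA, WPGMC) by two
distortion measures over all cell pairs: the Pearson correlation between
cophenetic and input distances (higher is better) and the Gower distance,
the sum of squared deviations between them (lower is better).  Selection
maximizes the correlation, breaking ties by the lower Gower distance and
then by a fixed preference order that leads with UPGMA.  The preference
order matters in one situation worth knowing about: an exactly ultrametric
input is reproduced perfectly by several linkages at once, and UPGMA — the
default linkage of turnover-based regionalization practice — is then the
canonical choice.

The number of regions is chosen by the **elbow** of the
variance-explained curve.  For each k = 1..k_max (default 30), the
dendrogram is cut into k clusters and

    VE(k) = 1 − (Σ within-cluster d²) / (Σ all-pair d²).

VE is nondecreasing in k because cuts of one dendrogram are nested.  The
curve itself does not define "maximum curvature", so the package uses the
normalized max-chord-distance rule: min–max normalize both axes, draw the
chord between the curve's endpoints, and take the interior k with the
greatest perpendicular distance to it (ties → smallest k; an exactly
linear curve has no elbow and falls back to the smallest interior k with a
warning).

A cluster only becomes a **valid region** if it (i) contains strictly more
than `min_cells = 10` cells ("more than 10" read strictly: 11 is the
smallest valid size) and (ii) is spatially aggregated.  Aggregation is
operationalized as: the largest connected component of the cluster on the
grid adjacency graph holds at least `aggregation_threshold = 0.5` of its
cells.  Cells of invalid clusters are explicitly labeled `unassigned`.

**Realms** are the coarser tier: the elbow is recomputed restricted to
fewer than `max_realms = 15` clusters, the dendrogram is cut there, and
each valid region inherits the realm of the majority of its cells.
Because both cuts come from one dendrogram they are nested, so every
region's cells lie in exactly one realm and the majority vote is
degenerate by construction — it exists only to be robust if a
regionalization was edited externally.

## Ordination

Nonmetric multidimensional scaling embeds the cells in two dimensions so
that configuration-distance ranks match βsim ranks.  Fit is Kruskal
stress-1:

    stress = sqrt( Σ (d̂ − d)² / Σ d² )

with d the configuration distances and d̂ their isotonic regression on
the dissimilarities.  Each random start runs SMACOF with monotone
regression (convergence tolerance 1e-7 on the stress change, 300
iterations max); the best of `n_starts` (default 200) wins.  The stress-1
normalization by Σ d² follows standard practice; the numerator is the
usual sum of squared differences between fitted and configuration
distances.

Since stress depends only on distance ranks, the configuration is then
aligned with geography by orthogonal Procrustes superimposition onto the
cell centroids — rotation, optional reflection, uniform scaling and
translation — which leaves stress unchanged.  Whole-cell configurations
are ordinated; per-region centroids can be derived from the output table.

## Comparing regionalizations

Two regionalizations are compared through the **area cross-tabulation**
of their regions over the cells valid in both schemes (unassigned cells
are excluded).  With joint area fractions p_ij and natural-log Shannon
entropies:

- homogeneity  h = 1 − H(B|A)/H(B)   (1 if H(B) = 0)
- completeness c = 1 − H(A|B)/H(A)   (1 if H(A) = 0)
- **Vβ** = 2hc/(h + c), the harmonic mean, 0 if h + c = 0.

The logarithm base cancels in h and c.  It matters only for the
**per-region homogeneity** map, 1 − H(B|A=i)/ln(n_B), where n_B is the
number of regions in the compared scheme (defined as 1 when n_B = 1); the
ln(n_B) normalization makes the value 1 for a region nested inside one
B-region and 0 for one split evenly across all of them.

Significance uses a **Voronoi randomization null**: a random
regionalization with k regions is built by drawing k seed cells uniformly
without replacement and assigning every cell to its nearest seed by
centroid distance (ties to the lowest seed index).  The null preserves
only the region count of the randomized scheme, not region areas,
mirroring the Voronoi construction itself.  Each ordered pair yields a
directional p-value

    p = (#{null Vβ ≥ observed Vβ} + 1) / (n_null + 1)

(add-one estimator, so p is never 0; ties count against significance) and
a standardized effect size SES = (observed − null mean)/null sd, with SES
reported as undefined (NaN) when the null variance is zero.  Both
directions are always reported separately and never pooled.  The default
is 999 nulls per direction.

The **Mantel test** (Pearson correlation of the off-diagonal vectors,
two-sided permutation p-value under simultaneous row/column permutations,
add-one estimator) is provided for matrix-level sensitivity comparisons,
e.g. Tβsim against Pβsim.

## Synthetic data: what it emulates and what it does not

The generator produces complete, internally consistent studies with known
ground truth:

- **Phylogeny**: Yule (pure-birth) trees, default birth rate 1, with one
  extra exponential waiting time appended after the last split so every
  branch length is strictly positive.
- **Posterior**: fixed topology, each branch length multiplied by an
  independent lognormal(0, sd_log) factor (default sd_log = 0.2, i.e.
  ~20% multiplicative branch-length uncertainty, median 1).  Topological
  uncertainty is deliberately not emulated: βsim uses branch lengths, and
  turnover indices of this family are insensitive to within-clade
  topology.
- **Planted regions**: nearest-seed (Voronoi) tessellation of the lattice,
  so regions are spatially connected on a convex lattice.
- **Assemblages**: the tree's tips are partitioned into one clade pool per
  region by cutting the tree in depth order into several times more
  subtrees than needed and merging the smallest pools pairwise down to the
  requested count — this keeps pools phylogenetically structured *and*
  roughly balanced, since a minimal-depth cut of a Yule tree can leave a
  near-empty clade.  Each cell draws `richness` distinct taxa (default
  12); each draw comes from the cell's own pool with probability
  1 − mixing and uniformly from the full taxon pool with probability
  `mixing` (default 0.05).  Full-pool contamination is the only mixing
  model under which `mixing = 1` genuinely erases the regional signal;
  drawing contaminants from *other* pools only would leave within-region
  cells sharing their complement pool and hence a persistent residual
  signal.

Defaults of the end-to-end pipeline: a 20 × 20 lattice (400 cells), 4
planted regions, 96 taxa, 25 posterior trees, richness 12, mixing 0.05,
199 Voronoi nulls and 20 NMDS starts.  These sizes keep a full run in the
low minutes on one core while leaving the planted structure clearly
recoverable; the NMDS start count is reduced from the 200-start default of
the `nmds` operation itself, which remains available unchanged.

What passing on synthetic data does **not** show: real range maps have
spatially autocorrelated richness gradients, coastlines and disjunct
ranges; real posteriors vary in topology; real regions are not Voronoi
cells.  Recovery of planted structure validates the machinery (the
statistics, the cluster selection, the null calibration), not the
biological adequacy of any particular empirical regionalization.

## Determinism

Every stochastic operation takes an explicit integer seed and is a pure
function of (arguments, seed).  A pipeline-level seed is fanned out to
stage seeds by fixed offsets, and two pipeline runs with the same
configuration and seed produce byte-identical outputs.  Linkage
tie-breaking follows scipy's deterministic lowest-pair-index rule;
nearest-seed ties go to the lowest seed index.

## Known limitations

- Dissimilarity matrices are dense; the practical ceiling is a few
  thousand cells (the empirical scale of continental/global hexagon
  grids), not raster-scale inputs.
- The aggregation rule ("largest component ≥ half the cluster") is one
  reasonable operationalization of spatial aggregation; archipelago-like
  valid regions with many small components require lowering the
  threshold.
- The Voronoi null preserves region count but not region areas or shapes;
  strongly area-skewed empirical schemes may need a stricter null.
- No correction for spatial autocorrelation is applied to the Mantel test
  (the modified-degrees-of-freedom t test is out of scope).
- Multiple-testing correction across many pairwise scheme comparisons is
  left to the caller; directional p-values are reported raw.
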