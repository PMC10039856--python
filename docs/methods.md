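# Methods notes

This note documents the model implemented by `pathmodes`, the numerical
choices behind it, what the synthetic-data generator does and does not
emulate, and the known limitations. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Model and assumptions

A pathway's expression submatrix (genes × cells, log-normalized CPM with
scale factor 10,000, gene rows standardized) is decomposed by PCA with
cells as observations. Each principal component is a candidate *activation
mode*: the genes with large squared loadings ("contributions", summing
to 1 per mode) define the gene subgroup, and the cell coordinates on the
component, min–max scaled to [0, 1], are the per-cell activity.

The method assumes that

* a biologically meaningful mode separates an *active* cell subpopulation
  from the rest, so its score distribution is bimodal;
* the dataset contains both activating and non-activating cells for any
  pathway it is expected to report (a mode uniformly active everywhere has
  no variance to capture);
* co-expression within the pathway list, not absolute expression level,
  carries the signal — hence the row standardization.

Depth normalization occurs once, per cell, before any pathway work; gene
standardization is recomputed per pathway on the log-normalized values
rather than reusing a globally scaled matrix (the pathway defines the
variable set, so its scaling belongs to it).

### Informativity gate

A candidate mode is kept iff, in order:

1. **Bimodality.** A Gaussian-kernel density of the scores is evaluated on
   a 512-point grid spanning [min − 3·bw, max + 3·bw]. The bandwidth `bw`
   is Silverman's rule of thumb, `0.9·min(sd, IQR/1.34)·n^(−1/5)`,
   multiplied by a coarse adjustment (2.0) on the first pass and a fine
   one (1.0) on the second; the second pass runs only if the first finds
   nothing. Local extrema are read off discrete sign changes of the first
   differences (plateaus collapse to their leftmost grid point). Only
   minima to the right of the global density maximum are considered —
   activation is a high-score phenomenon, possibly in a rare population —
   and they are scanned from the largest abscissa downward. A minimum is
   accepted when both flanking local maxima exceed its density by at least
   10% of the global maximum; a minimum with no maximum on its right is
   disqualified, since a split needs a population on both sides. The
   accepted minimum's abscissa is the activity threshold; cells strictly
   above it are "active".
2. **Active fraction.** The active cells must be at least
   `min_active_frac` (default 5%) of the dataset. No upper bound is
   imposed.
3. **Monogenic check.** The largest single-gene contribution must not
   exceed `max_contribution` (default 0.4); a mode carried by one gene is
   not a co-expression program.

`rejection_reason` records the first failed check (`no_bimodal`,
`too_few_active`, `monogenic`).

Components are examined in decreasing variance order. PC2 is always
examined even when PC1 fails — a strong but uninformative gradient
(technical depth effects, smooth biological continua) often owns PC1 while
population structure sits on PC2. From PC2 onward the scan stops at the
first uninformative component; a cap of `max_modes` (default 10)
components guards degenerate inputs.

### Key parameters

| parameter | default | meaning |
|---|---|---|
| `scale_factor` | 10,000 | per-cell depth target before log1p |
| `min_active_frac` | 0.05 | minimum active-cell fraction per mode |
| `max_contribution` | 0.4 | maximum squared loading of a single gene |
| `density_drop_frac` | 0.10 | valley depth, as a fraction of the global maximum density |
| `adjust_coarse` / `adjust_fine` | 2.0 / 1.0 | KDE bandwidth multipliers for the two passes |
| `grid_points` | 512 | density evaluation grid |
| `min_genes` | 5 | minimum usable genes per pathway (a warning is emitted below 10) |
| `k_neighbors` | 20 | kNN graph size for activity clustering |
| `assign_threshold` | 0 | cluster mean activity must strictly exceed this to receive a label |
| `leiden_max_iter` | 2 | Leiden iterations (modularity partition) |

### Numerical conventions

* PCA is computed by SVD of the cells × genes standardized matrix; the
  sign ambiguity is fixed by pointing the largest-|loading| gene positive
  (ties resolve to the earliest gene in the pathway's stored order).
  Components below `1e−12` of the leading singular value are treated as
  rank deficiency and dropped.
* Standard deviations use ddof = 1 throughout (matching the convention of
  the R `scale`/`density` stack this kind of pipeline usually follows).
* Gene symbols match by case-sensitive exact string comparison; no alias
  or ortholog resolution.
* Zero-variance genes are dropped from a pathway before standardization;
  constant score vectors are flagged `no_bimodal` without a KDE call.
* Active cells are `score > threshold` (strict); the threshold lies in a
  density valley, so the boundary choice is immaterial at float
  resolution but fixed for determinism.
* The kNN neighbor sets used for Jaccard weights include the cell itself
  (sets of size k+1), which stabilizes the similarity at small k; edges
  with zero Jaccard similarity are dropped. "Jaccard distance" in the
  clustering step is implemented as Jaccard *similarity* weights —
  modularity clustering needs weights that are large for similar cells.
  If every cell has an identical activity profile the partition is a
  single cluster by definition, bypassing the graph.
* Cluster labels require the winning mean activity to exceed the
  threshold strictly; with 0–1 scores and the default threshold 0 any
  positive mean suffices. Ties break by cell-type name order, with a
  warning.
* SDI uses the natural logarithm; the base cancels in the ratio (asserted
  against a base-2 evaluation in the tests). Precision, recall and F1
  return 0 on zero denominators, which keeps all-unassigned edge cases
  defined.
* In the specificity metric the row normalization guarantees
  `Σ_c S(m,c) = 1`; this identity (not a squared variant) follows
  directly from the definition and is what the implementation asserts.

## The synthetic-data generator

`simulate_counts` draws
`count(g,c) ~ NB(mean = baseline_g · fold_g^level(g,c) · depth_c ·
batchshift(g, batch_c), size = dispersion)` with log-uniform baselines
(default 0.1–5), log-normal depths (σ = 0.3), and planted modules that set
`level = 1` in active cells. Modules can be active in a fraction of their
population (`cell_fraction`), show a graded background engagement in
non-active cells (`background_level`: levels drawn U(0, bg)), and draw
their baselines from a module-specific range. Batch shifts
(`exp(N(0, σ))` per gene and batch) apply to non-module genes only, so
planted biology is batch-free while the background gene space carries the
batch signal. Everything is deterministic given the spec seed.

### What the canonical scenarios emulate, and why they look the way they do

*Two-module pathway* (`two_module_pathway_spec`): 600 cells — two 90-cell
module-bearing populations on a 420-cell unengaged background — and a
200-gene pathway holding a 50-gene and a 30-gene module (fold 4, fully
active in their populations) plus 120 noise genes, in a 1000-gene
universe. Two structural facts shaped this design. First, with exactly two
complementary populations the two module indicators are collinear
(z_B = 1 − z_A): the planted signal is rank one and a single principal
component absorbs both modules, so a background population is needed for
the modules to be separable at all. Second, the two block directions are
still negatively correlated through the shared background, and symmetric
blocks would make the leading eigenvectors near-equal mixtures of both;
the 50/30 size asymmetry (with the smaller module drawn from
well-expressed genes, baselines 5–10) separates the eigenvalues enough
for each component to localize on one module. Negative-binomial size 4 in
the canonical scenarios is at the cleaner end of the range typical for
UMI data.

*Annotation scenario* (`annotation_spec`): three balanced 200-cell
populations with disjoint fully-active 30-gene marker modules, optionally
with a 2-batch covariate. Marker modules must be *minority*-active: the
valley search only looks right of the global density maximum, so a marker
list active in most cells (its inactive minority forming the left bump)
can never pass — cell types are assumed to be minorities in a mixed
dataset.

*Rare population* (`rare_population_spec`): 2500 cells with a 50-cell (2%)
population fully activating a 40-gene fold-20 module, while the main
population shows graded partial engagement (levels U(0, 0.6)). The
gradation is essential: a 2%-mass bump can never rise by 10% of the peak
of a concentrated background density, but it can over a broad engagement
continuum whose density is flat. The module is kept at baseline 1–2 counts
inside a 2000-gene universe because a highly expressed module this strong
would dominate the cell's library, and depth normalization then cancels
the very fold change it carries (compositional closure).

*Outlier pair* (`outlier_gene_spec`): row standardization caps the group
separation a single Gaussian-like gene can deliver at `1/sqrt(p(1−p))`
standard deviations, and heterogeneous residual noise flattens the leading
eigenvector away from any lone gene — which is why real "monogenic" modes
come from near-binary genes (almost silent in most cells, strongly
expressed in a few: ectopic or contaminating markers). The scenario plants
a pair of such genes (folds 200/150 on baselines 0.1–0.2, active in 10% of
cells), giving a clearly bimodal leading component whose maximum gene
contribution sits near 0.5 — a mode that fails only the monogenic check.

### What the generator does not emulate

Doublets, ambient RNA, cell-cycle structure, gene-length effects,
transcript dropout beyond the NB sampling, correlated noise between
modules, and any attempt to mimic a specific tissue. Passing tests on
these data show that the pipeline recovers planted co-expression structure
under realistic count noise; they do not show that any particular
biological pathway decomposes cleanly in real tissue, where list quality,
overlapping programs and continuous gradients blur the picture.

## Problem sizes

The test suite and example scenarios use 600–2500 cells, 300–2000 genes
and 20 replicates for the spiking experiment (levels 10/50/100 added
genes), sizes at which every full pipeline stage runs in seconds on one
CPU while leaving the detection problems genuinely non-trivial (the
planted modes sit well below half of the pathway variance).

## Known limitations

* The valley search is one-sided (right of the global maximum): modes
  *inactive* in a minority of cells are reported only through the
  complementary mode of the remaining genes, and majority-active marker
  lists are rejected by construction.
* The 10%-of-global-maximum depth rule ties detectability of a rare
  active population to the shape of the background density, not only to
  separation; very rare populations over a concentrated background are
  invisible at any separation.
* Modes of one pathway are not orthogonalized across pathways; overlapping
  lists produce correlated rows in the activity matrix.
* Gene matching is exact; list/matrix vocabulary mismatches silently
  shrink pathways (a warning fires below 10 usable genes).
* Leiden/modularity freely splits large homogeneous populations into
  several clusters; cluster-level labeling is unaffected, but cluster
  counts should not be read as cell-type counts.
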