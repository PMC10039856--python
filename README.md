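# pathmodes

Multimodal pathway-activity scoring and cluster-free cell-type annotation
for single-cell RNA-seq.

## The problem

Reference pathway databases (Hallmark, KEGG, REACTOME) describe biological
functions with one gene list each, and most per-cell scoring tools reduce
each list to a single activity score. But a pathway is rarely activated the
same way in every cell type: different cell populations engage different
subsets of the same list. A single score averages those programs away.

`pathmodes` decomposes each pathway into **activation modes** — subgroups
of co-expressed pathway genes, each with its own per-cell score — and
keeps only the modes that look biologically meaningful. The same machinery,
restricted to the first mode of cell-type marker lists, provides fast
cluster-free cell-type annotation that is intrinsically robust to batch
effects (batch-distorted non-marker genes never enter the score).

## The method

For each gene list *G* and a log-normalized expression matrix
(`x = ln(1 + count / total × 10,000)`):

1. restrict the matrix to the genes of *G* and standardize each gene row
   (mean 0, sd 1), so highly expressed genes do not dominate;
2. run a PCA with cells as observations. Each principal component *k* is a
   candidate mode: per-gene loadings `w` (the **contributions** `w²` sum
   to 1) and per-cell scores (the cell coordinate on the component),
   sign-oriented so the strongest gene points positive and min–max scaled
   to [0, 1];
3. keep the mode only if it passes the **informativity gate**:
   * *bimodality* — a Gaussian-KDE density curve of the scores (Silverman
     bandwidth, coarse pass ×2 then fine pass ×1) has a valley right of
     the global density maximum whose flanking maxima both rise by at
     least 10% of the global maximum above it; the valley abscissa becomes
     the activity threshold;
   * *active fraction* — cells above the threshold are ≥ 5% of the dataset
     (modes active in a handful of cells are likely outliers);
   * *not monogenic* — no single gene contributes more than 0.4 of the
     squared-loading mass;
4. scan components in decreasing variance order, always examining PC2 even
   when PC1 fails (a dominant uninformative gradient may mask real biology),
   and stop at the first uninformative component after PC2.

Informative modes from all pathways are stacked into a modes × cells
**activity matrix**. Downstream utilities cluster cells on that matrix
(k-nearest-neighbor graph, Jaccard-similarity weights, Leiden/modularity),
label clusters by arg-max mean marker activity, and score results with the
specificity metric `S(m,c) = a(m,c)² / Σ_p a(m,p)²` (per-mode rows sum
to 1), the normalized Shannon Diversity Index
`SDI = −Σ p_i ln p_i / ln N`, and per-class precision/recall/F1.

A seeded synthetic-data generator (negative-binomial counts, log-normal
library sizes, planted co-expressed modules, optional batch covariate)
provides ground-truth datasets for every stage.

## Worked example

```python
import pathmodes as pm

# 600 cells, a 200-gene pathway containing two planted 50- and 30-gene
# modules (fold 4), each active in one of two 90-cell populations
sim = pm.simulate_counts(pm.two_module_pathway_spec(seed=0))
expr = pm.lognormalize(sim.expression)
result = pm.detect_pathway_modes(expr, sim.pathways["pathway_AB"])

pop = sim.cell_metadata["population"].to_numpy()
for mode in result.informative:
    spec = pm.specificity(
        pm.ActivityMatrix(mode.scores[None, :], [mode.mode_name],
                          list(expr.cell_ids)), pop).table.iloc[0]
    print(f"{mode.mode_name}: variance explained {mode.variance_explained:.3f}, "
          f"active fraction {mode.active_fraction:.2f}")
    print(f"  top genes: {', '.join(pm.top_genes(mode, 5))}")
    print("  specificity: " + ", ".join(f"{k}={v:.2f}" for k, v in spec.items()))
```

prints

```
pathway_AB_mode1: variance explained 0.065, active fraction 0.15
  top genes: G00005, G00023, G00021, G00038, G00031
  specificity: background=0.22, popA=0.76, popB=0.02
pathway_AB_mode2: variance explained 0.028, active fraction 0.30
  top genes: G00065, G00052, G00062, G00072, G00064
  specificity: background=0.07, popA=0.41, popB=0.51
```

The pathway splits into two modes. Mode 1's top contributing genes all come
from the module planted in population A (genes `G00000`–`G00049`) and its
specificity concentrates on popA (0.76, against a 1/3 expectation); mode 2
is driven by the second module (genes `G00050`–`G00079`) and is most
specific to popB. A single-score method would have reported one blended
signal for this pathway.

The same pipeline is available from the shell:

```bash
pathmodes simulate --out data/ --scenario annotation --seed 3
pathmodes pathways --counts data/ --gmt data/markers.gmt --out-dir run/
pathmodes annotate --counts data/ --markers data/markers.gmt --out ann/
pathmodes evaluate --annotation ann/annotation.tsv --truth data/metadata.tsv --out eval/
```

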