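"""Seeded synthetic scRNA-seq data with planted multimodal pathway structure.

The generator emulates the data the mode-detection model assumes: discrete
cell populations, negative-binomial counts with per-cell library-size
variation, planted co-expressed gene modules each up-regulated in (a
fraction of) one population, noise genes, and an optional batch covariate
perturbing non-module genes.

Counts are drawn as

    count(g, c) ~ NegBin(mean = baseline(g) * fold(g)^level(g, c)
                               * depth(c) * batch_shift(g, batch(c)),
                         size = dispersion)

where ``level`` is 1 for cells in which a module containing g is active,
0 for others (or a uniform draw in ``[0, background_level]`` for modules
modeling a graded background activation).  Everything is deterministic
given the spec's seed.

Two structural knobs matter for what PCA can recover and are worth
spelling out.  With exactly two populations and two modules each fully
active in one of them, the module indicators are complementary, the
planted signal has rank one, and a single principal component absorbs
both modules.  Planting each module in a *fraction* of its population
(``cell_fraction < 1``) — i.e. within-cell-type activation heterogeneity,
the phenomenon multimodal scoring exists to capture — decorrelates the
modules and makes the planted structure genuinely rank two, with each
component localizing on one module.  The canonical scenarios below use
this construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .expression import ExpressionMatrix, LAYER_RAW
from .gene_sets import GeneSet, GeneSetCollection, spike_random_genes

_SEED_MOD = 2**31


@dataclass(frozen=True)
class Module:
    """A planted co-expressed gene module.

    fold
        Multiplicative up-regulation of the module genes in active cells;
        either a scalar or one value per gene.
    cell_fraction
        Fraction of each active population's cells in which the module is
        on (1.0 = the whole population).
    background_level
        When positive, non-active cells get a graded activation exponent
        drawn uniformly from [0, background_level], producing a continuum
        of partial activity below the fully active cells.
    is_marker
        Marks modules whose genes act as cell-type markers (used to emit
        per-population marker sets).
    baseline_range
        Optional per-module override of the baseline expression range,
        e.g. to model well-expressed marker genes versus weakly expressed
        background genes.
    """

    name: str
    genes: tuple[int, ...]
    populations: tuple[str, ...]
    fold: float | tuple[float, ...] = 4.0
    cell_fraction: float = 1.0
    background_level: float = 0.0
    is_marker: bool = False
    baseline_range: tuple[float, float] | None = None

    def fold_per_gene(self) -> np.ndarray:
        if np.isscalar(self.fold):
            return np.full(len(self.genes), float(self.fold))
        folds = np.asarray(self.fold, dtype=float)
        if folds.size != len(self.genes):
            raise ValueError(f"module {self.name!r}: one fold per gene required")
        return folds


@dataclass(frozen=True)
class PooledPathway:
    """A pathway gene list pooling several modules plus noise genes."""

    name: str
    modules: tuple[str, ...]
    n_noise: int = 0


@dataclass(frozen=True)
class BatchSpec:
    """Two-or-more batch covariate with gene-wise multiplicative shifts.

    Shifts are log-normal (``exp(N(0, sigma))``) per gene and batch and are
    applied to non-module genes only, so planted biology is batch-free
    while the background gene space carries the batch signal.
    """

    n_batches: int = 2
    sigma: float = 1.0


@dataclass(frozen=True)
class SimSpec:
    """Full description of one synthetic dataset."""

    populations: tuple[tuple[str, int], ...]
    n_genes: int = 1000
    modules: tuple[Module, ...] = ()
    pathways: tuple[PooledPathway, ...] = ()
    baseline_range: tuple[float, float] = (0.1, 5.0)
    #: module genes draw baselines from this narrower range: a fold change on
    #: a gene with near-zero expression is invisible in sparse counts, and
    #: curated pathway/marker genes are detectably expressed in practice
    module_baseline_range: tuple[float, float] = (0.5, 5.0)
    dispersion: float = 2.0
    libsize_sigma: float = 0.3
    batch: BatchSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        names = [n for n, _ in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("population names must be unique")
        for name, n in self.populations:
            if n < 50:
                raise ValueError(
                    f"population {name!r} has {n} cells; at least 50 are needed "
                    "for stable density estimation downstream"
                )
        used: set[int] = set()
        for mod in self.modules:
            mod.fold_per_gene()
            if not 0.0 < mod.cell_fraction <= 1.0:
                raise ValueError(f"module {mod.name!r}: cell_fraction in (0, 1]")
            if np.any(mod.fold_per_gene() <= 0):
                raise ValueError(f"module {mod.name!r}: folds must be > 0")
            overlap = used.intersection(mod.genes)
            if overlap:
                raise ValueError(f"module gene ranges overlap at indices {sorted(overlap)[:5]}")
            if max(mod.genes, default=-1) >= self.n_genes:
                raise ValueError(f"module {mod.name!r}: gene index out of range")
            for pop in mod.populations:
                if pop not in names:
                    raise ValueError(f"module {mod.name!r}: unknown population {pop!r}")
            used.update(mod.genes)
        module_names = [m.name for m in self.modules]
        for pw in self.pathways:
            for mn in pw.modules:
                if mn not in module_names:
                    raise ValueError(f"pathway {pw.name!r}: unknown module {mn!r}")

    @property
    def n_cells(self) -> int:
        return sum(n for _, n in self.populations)


@dataclass
class SimResult:
    """Simulated counts plus the ground truth needed by tests and metrics."""

    expression: ExpressionMatrix  # raw counts
    cell_metadata: pd.DataFrame  # population (and batch) per cell
    pathways: GeneSetCollection  # one set per module + pooled pathways
    markers: GeneSetCollection  # disjoint marker sets per population
    module_active: dict[str, np.ndarray]  # module name -> boolean cell mask
    module_genes: dict[str, tuple[str, ...]]
    spec: SimSpec

    @property
    def background_gene_ids(self) -> list[str]:
        """Genes in no module and no pooled pathway (pure noise universe)."""
        in_sets = set()
        for s in self.pathways:
            in_sets.update(s.genes)
        for s in self.markers:
            in_sets.update(s.genes)
        return [g for g in self.expression.gene_ids if g not in in_sets]


def _gene_id(i: int) -> str:
    return f"G{i:05d}"


def simulate_counts(spec: SimSpec) -> SimResult:
    """Draw one dataset from a :class:`SimSpec`; deterministic given its seed."""
    rng = np.random.default_rng(spec.seed)
    n_genes, n_cells = spec.n_genes, spec.n_cells
    gene_ids = [_gene_id(i) for i in range(n_genes)]
    cell_ids = [f"C{i:05d}" for i in range(n_cells)]

    population = np.empty(n_cells, dtype=object)
    start = 0
    pop_slices: dict[str, np.ndarray] = {}
    for name, n in spec.populations:
        idx = np.arange(start, start + n)
        pop_slices[name] = idx
        population[idx] = name
        start += n

    lo, hi = spec.baseline_range
    baseline = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_genes))
    for mod in spec.modules:
        mlo, mhi = mod.baseline_range or spec.module_baseline_range
        gidx = np.asarray(mod.genes, dtype=int)
        baseline[gidx] = np.exp(rng.uniform(np.log(mlo), np.log(mhi), size=gidx.size))
    depth = np.exp(rng.normal(0.0, spec.libsize_sigma, size=n_cells))

    # per-cell activation level for each module, then the mean multiplier
    log_mu = (
        np.log(baseline)[:, None]
        + np.log(depth)[None, :]
        + np.zeros((n_genes, n_cells))
    )
    module_active: dict[str, np.ndarray] = {}
    module_gene_idx: set[int] = set()
    for mod in spec.modules:
        active = np.zeros(n_cells, dtype=bool)
        for pop in mod.populations:
            idx = pop_slices[pop]
            n_act = int(round(mod.cell_fraction * idx.size))
            chosen = rng.choice(idx, size=n_act, replace=False)
            active[chosen] = True
        level = active.astype(float)
        if mod.background_level > 0:
            inactive = ~active
            level[inactive] = rng.uniform(
                0.0, mod.background_level, size=int(inactive.sum())
            )
        folds = mod.fold_per_gene()
        gidx = np.asarray(mod.genes, dtype=int)
        log_mu[gidx, :] += np.log(folds)[:, None] * level[None, :]
        module_active[mod.name] = active
        module_gene_idx.update(mod.genes)

    batch = None
    if spec.batch is not None:
        n_b = spec.batch.n_batches
        batch = np.empty(n_cells, dtype=int)
        for name, idx in pop_slices.items():  # balanced within populations
            batch[idx] = np.arange(idx.size) % n_b
        non_module = np.array(
            [i for i in range(n_genes) if i not in module_gene_idx], dtype=int
        )
        shifts = rng.normal(0.0, spec.batch.sigma, size=(non_module.size, n_b))
        log_mu[non_module, :] += shifts[:, batch]

    mu = np.exp(log_mu)
    r = float(spec.dispersion)
    counts = rng.negative_binomial(r, r / (r + mu))

    expression = ExpressionMatrix(
        values=sparse.csr_matrix(counts),
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        layer=LAYER_RAW,
    )
    metadata = pd.DataFrame({"population": population}, index=cell_ids)
    if batch is not None:
        metadata["batch"] = batch

    module_genes = {
        mod.name: tuple(gene_ids[i] for i in mod.genes) for mod in spec.modules
    }
    pathway_sets = [
        GeneSet(name=mod.name, genes=module_genes[mod.name], description="planted module")
        for mod in spec.modules
    ]
    free = [i for i in range(n_genes) if i not in module_gene_idx]
    cursor = 0
    for pw in spec.pathways:
        genes: list[str] = []
        for mn in pw.modules:
            genes.extend(module_genes[mn])
        noise = free[cursor : cursor + pw.n_noise]
        if len(noise) < pw.n_noise:
            raise ValueError(f"pathway {pw.name!r}: not enough free noise genes")
        cursor += pw.n_noise
        genes.extend(gene_ids[i] for i in noise)
        pathway_sets.append(
            GeneSet(name=pw.name, genes=tuple(genes), description="pooled pathway")
        )

    marker_sets = []
    for pop, _ in spec.populations:
        genes = []
        for mod in spec.modules:
            if mod.is_marker and mod.populations == (pop,):
                genes.extend(module_genes[mod.name])
        if genes:
            marker_sets.append(
                GeneSet(name=pop, genes=tuple(genes), description="population markers")
            )

    return SimResult(
        expression=expression,
        cell_metadata=metadata,
        pathways=GeneSetCollection(pathway_sets, source=f"simulated(seed={spec.seed})"),
        markers=GeneSetCollection(marker_sets, source=f"simulated(seed={spec.seed})"),
        module_active=module_active,
        module_genes=module_genes,
        spec=spec,
    )


# --------------------------------------------------------------------------
# canonical scenarios
# --------------------------------------------------------------------------

def two_module_pathway_spec(seed: int = 0) -> SimSpec:
    """600 cells; a 200-gene pathway with two population-specific modules.

    Two small module-bearing populations (90 cells each) sit on a 420-cell
    unengaged background; the pooled pathway holds 80 module genes
    (module A: 50 genes, module B: 30 genes, both fold 4, each fully
    active in its population) plus 120 pathway noise genes, inside a
    1000-gene universe.  The background population keeps the two module
    indicators only weakly anti-correlated — with exactly two complementary
    populations the planted signal would be rank one and a single component
    would absorb both modules — and the size asymmetry (50 vs 30 genes,
    with the smaller module drawn from well-expressed genes) separates the
    two eigendirections enough for each component to localize on one
    module.
    """
    modules = (
        Module(name="module_A", genes=tuple(range(0, 50)), populations=("popA",),
               fold=4.0, baseline_range=(1.0, 5.0)),
        Module(name="module_B", genes=tuple(range(50, 80)), populations=("popB",),
               fold=4.0, baseline_range=(5.0, 10.0)),
    )
    return SimSpec(
        populations=(("popA", 90), ("popB", 90), ("background", 420)),
        n_genes=1000,
        modules=modules,
        dispersion=4.0,
        pathways=(PooledPathway(name="pathway_AB", modules=("module_A", "module_B"),
                                n_noise=120),),
        seed=seed,
    )


def annotation_spec(seed: int = 0, batch: BatchSpec | None = None) -> SimSpec:
    """Three balanced 200-cell populations with disjoint 30-gene marker sets.

    Each marker module is fully active in its population (fold 4), so the
    first mode of every marker list is bimodal with a ~33% active fraction.
    With a batch spec, log-normal gene-wise shifts hit the non-module
    background genes only: raw gene-space structure is then dominated by
    batch while marker activity stays batch-free.
    """
    modules = (
        Module(name="markers_A", genes=tuple(range(0, 30)), populations=("popA",),
               fold=4.0, is_marker=True),
        Module(name="markers_B", genes=tuple(range(30, 60)), populations=("popB",),
               fold=4.0, is_marker=True),
        Module(name="markers_C", genes=tuple(range(60, 90)), populations=("popC",),
               fold=4.0, is_marker=True),
    )
    return SimSpec(
        populations=(("popA", 200), ("popB", 200), ("popC", 200)),
        n_genes=1000,
        modules=modules,
        dispersion=4.0,
        batch=batch,
        seed=seed,
    )


def rare_population_spec(seed: int = 0) -> SimSpec:
    """A 2500-cell dataset with a rare (2%) fully-activated population.

    The pathway module is strongly up-regulated (fold 20) in every rare
    cell and shows a graded partial engagement (activation levels up to
    0.6 of the full effect) across the main population: a continuum of
    background activity topped by a small fully-active population, the
    regime in which the active group forms a sharp density bump above a
    broad background.  Module genes are kept moderately expressed
    (baseline 1-2 counts) so the module stays a small fraction of each
    cell's library — a highly expressed module this strong would dominate
    the library and depth normalization would cancel its own fold change.
    """
    modules = (
        Module(name="module_rare", genes=tuple(range(0, 40)), populations=("rare",),
               fold=20.0, cell_fraction=1.0, background_level=0.6,
               baseline_range=(1.0, 2.0)),
    )
    return SimSpec(
        populations=(("main", 2450), ("rare", 50)),
        n_genes=2000,
        modules=modules,
        dispersion=4.0,
        pathways=(PooledPathway(name="pathway_rare", modules=("module_rare",),
                                n_noise=20),),
        seed=seed,
    )


def outlier_gene_spec(seed: int = 0) -> SimSpec:
    """A pathway dominated by a spiked on/off outlier gene pair.

    Per-gene standardization caps how much any single Gaussian-like gene
    can separate two groups (at ``1/sqrt(p(1-p))`` standard deviations),
    so a realistic dominant-gene mode needs near-binary genes: almost
    silent in most cells, strongly expressed in a small fraction — the
    ectopic/contaminating-marker pattern.  A pair of such genes sharing
    one 10% activation set yields a leading component with ~0.5 maximum
    contribution and a clearly bimodal score, i.e. a mode that fails only
    the monogenic check.
    """
    modules = (
        Module(name="outlier_pair", genes=(0, 1), populations=("popA", "popB"),
               fold=(200.0, 150.0), cell_fraction=0.1, baseline_range=(0.1, 0.2)),
    )
    return SimSpec(
        populations=(("popA", 300), ("popB", 300)),
        n_genes=300,
        modules=modules,
        dispersion=4.0,
        pathways=(PooledPathway(name="pathway_outlier", modules=("outlier_pair",),
                                n_noise=8),),
        seed=seed,
    )


def module_plus_outlier_spec(seed: int = 0) -> SimSpec:
    """One healthy 40-gene module plus an on/off outlier pair, pooled.

    Used for contribution-threshold sweeps: the planted module passes the
    informativity gate at any max-contribution cutoff above its ~1/40
    per-gene contributions, while the outlier mode (max contribution
    ~0.5) appears only once the cutoff exceeds it.
    """
    modules = (
        Module(name="module_A", genes=tuple(range(0, 40)), populations=("popA",),
               fold=4.0, baseline_range=(1.0, 5.0)),
        Module(name="outlier_pair", genes=(40, 41), populations=("popB",),
               fold=(200.0, 150.0), cell_fraction=1.0, baseline_range=(0.1, 0.2)),
    )
    return SimSpec(
        populations=(("popA", 90), ("popB", 90), ("background", 420)),
        n_genes=400,
        modules=modules,
        dispersion=4.0,
        pathways=(PooledPathway(
            name="pathway_mixed", modules=("module_A", "outlier_pair"), n_noise=20),),
        seed=seed,
    )


def noise_pathway(result: SimResult, n_genes: int, seed: int) -> GeneSet:
    """A pure-noise pathway sampled from the background genes of a dataset."""
    pool = result.background_gene_ids
    if len(pool) < n_genes:
        raise ValueError("not enough background genes")
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(pool), size=n_genes, replace=False)
    return GeneSet(
        name=f"noise_{seed}",
        genes=tuple(pool[i] for i in picks),
        description="pure noise pathway",
    )


@dataclass(frozen=True)
class SpikedPathway:
    """One noise-robustness replicate: a pathway with random genes added."""

    n_add: int
    replicate: int
    gene_set: GeneSet


def make_noise_robustness_suite(
    base_set: GeneSet,
    universe: Sequence[str],
    n_add_list: Sequence[int] = (10, 50, 100, 200),
    n_reps: int = 100,
    base_seed: int = 0,
) -> list[SpikedPathway]:
    """Spiked copies of a pathway for the noise-robustness experiment.

    For every level in ``n_add_list`` and every replicate, random genes are
    added with a distinct derived seed.  ``n_add = 0`` entries reproduce
    the base pathway unchanged.
    """
    suite = []
    for n_add in n_add_list:
        for rep in range(n_reps):
            seed = (base_seed * 1_000_003 + n_add * 1_009 + rep) % _SEED_MOD
            spiked = spike_random_genes(base_set, universe, n_add, seed)
            suite.append(SpikedPathway(n_add=n_add, replicate=rep, gene_set=spiked))
    return suite
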