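"""PCA decomposition of pathway submatrices into activation modes.

For each pathway, the log-normalized expression matrix is restricted to the
pathway's genes, gene rows are standardized (so highly expressed genes do
not dominate), and a PCA with cells as observations is computed.  Each
principal component is a candidate *activation mode*: per-gene loadings
(whose squares — the contributions — sum to 1) and a per-cell score (the
cell coordinate on the component), min-max scaled to [0, 1] after a sign
convention that points the component toward its strongest gene.

Candidate modes are vetted by the informativity gate
(:mod:`pathmodes.informativity`) in decreasing order of variance explained.
PC2 is always examined even when PC1 fails (a dominant but uninformative
gradient, e.g. a technical one, may mask biology on PC2); from PC2 onward
the scan stops at the first uninformative component, as later components
explain less variance and are increasingly likely to be noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

from .gene_sets import GeneSet, GeneSetCollection, intersect_with_universe
from .informativity import REASON_NO_BIMODAL, REASON_NONE, ModeParams, assess_mode

if TYPE_CHECKING:  # pragma: no cover
    from .expression import ExpressionMatrix

_RANK_RTOL = 1e-12


@dataclass
class ActivationMode:
    """One candidate (or accepted) activation mode of a pathway."""

    set_name: str
    index: int  # 1-based principal component rank
    genes: tuple[str, ...]
    loadings: np.ndarray  # per-gene signed weights, unit squared-sum
    scores: np.ndarray  # per-cell; raw PC coordinates until 0-1 scaling
    variance_explained: float
    informative: bool = False
    threshold: float | None = None
    active_fraction: float = float("nan")
    rejection_reason: str = REASON_NONE

    @property
    def contributions(self) -> np.ndarray:
        """Squared loadings; sum to 1 by construction."""
        return self.loadings**2

    @property
    def max_contribution(self) -> float:
        return float(np.max(self.contributions))

    @property
    def mode_name(self) -> str:
        return f"{self.set_name}_mode{self.index}"


@dataclass
class ActivityMatrix:
    """Modes x cells matrix of activity scores in [0, 1]."""

    values: np.ndarray
    mode_names: list[str]
    cell_ids: list[str]
    modes: list[ActivationMode] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("activity values must be 2-D (modes x cells)")
        if self.values.shape != (len(self.mode_names), len(self.cell_ids)):
            raise ValueError(
                f"activity shape {self.values.shape} inconsistent with "
                f"{len(self.mode_names)} modes x {len(self.cell_ids)} cells"
            )
        if len(set(self.mode_names)) != len(self.mode_names):
            raise ValueError("mode names must be unique")

    @property
    def n_modes(self) -> int:
        return len(self.mode_names)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.mode_names, columns=self.cell_ids)


@dataclass
class PathwayModes:
    """Result of mode detection for one pathway."""

    set_name: str
    informative: list[ActivationMode]
    evaluated: list[ActivationMode]  # all candidates that were examined


def scale_gene_rows(
    values: np.ndarray, gene_ids: Sequence[str]
) -> tuple[np.ndarray, list[str], list[str]]:
    """Center each gene row to mean 0 and scale to unit standard deviation.

    Genes with zero variance across cells carry no signal and would divide
    by zero; they are dropped and reported.

    Returns ``(scaled, kept_gene_ids, dropped_gene_ids)``.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] != len(gene_ids):
        raise ValueError("values rows must match gene_ids")
    sd = values.std(axis=1, ddof=1)
    keep = sd > 0
    kept = [g for g, k in zip(gene_ids, keep) if k]
    dropped = [g for g, k in zip(gene_ids, keep) if not k]
    sub = values[keep]
    scaled = (sub - sub.mean(axis=1, keepdims=True)) / sd[keep][:, None]
    return scaled, kept, dropped


def pca_modes(
    scaled: np.ndarray, gene_ids: Sequence[str], max_modes: int, set_name: str = ""
) -> list[ActivationMode]:
    """Principal components of a row-standardized pathway submatrix.

    Cells are the observations and genes the variables, so loadings are
    per-gene and scores per-cell.  Candidates are ordered by decreasing
    variance explained; numerically null components (rank deficiency) are
    not returned.  Scores are raw PC coordinates at this stage.
    """
    scaled = np.asarray(scaled, dtype=float)
    n_genes, n_cells = scaled.shape
    if n_genes < 2 or n_cells < 3:
        return []
    x = scaled.T  # cells x genes, columns centered by row standardization
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    total = float(np.sum(s**2))
    if total == 0.0 or s[0] == 0.0:
        return []
    n_comp = int(np.sum(s > s[0] * _RANK_RTOL))
    n_comp = min(n_comp, max_modes, n_cells - 1, n_genes)
    modes = []
    for k in range(n_comp):
        modes.append(
            ActivationMode(
                set_name=set_name,
                index=k + 1,
                genes=tuple(gene_ids),
                loadings=vt[k].copy(),
                scores=(u[:, k] * s[k]).copy(),
                variance_explained=float(s[k] ** 2 / total),
            )
        )
    return modes


def orient_mode(mode: ActivationMode) -> ActivationMode:
    """Fix the PC sign so the largest-|loading| gene points positive.

    PCA components are defined up to sign; this convention favors the
    direction in which the dominant gene's weight is positive, so "active"
    cells sit at high scores.  Ties on |loading| resolve to the gene
    earliest in the pathway's stored order (argmax convention), which keeps
    the choice deterministic.  Idempotent; contributions are unchanged.
    """
    i = int(np.argmax(np.abs(mode.loadings)))
    if mode.loadings[i] < 0:
        mode.loadings = -mode.loadings
        mode.scores = -mode.scores
    return mode


def scale_mode_scores(mode: ActivationMode) -> ActivationMode:
    """Map raw PC scores affinely onto [0, 1].

    Constant score vectors cannot be scaled; they map to all zeros and the
    mode is pre-flagged as non-bimodal for the informativity gate.
    """
    lo = float(np.min(mode.scores))
    hi = float(np.max(mode.scores))
    rng = hi - lo
    if rng <= 0 or not np.isfinite(rng):
        mode.scores = np.zeros_like(mode.scores)
        mode.rejection_reason = REASON_NO_BIMODAL
        return mode
    mode.scores = (mode.scores - lo) / rng
    return mode


def detect_pathway_modes(
    m: "ExpressionMatrix",
    gene_set: GeneSet,
    params: ModeParams | None = None,
) -> PathwayModes:
    """Detect the informative activation modes of one pathway.

    The expression matrix must carry log-normalized values.  Pathways with
    fewer than ``params.min_genes`` usable genes are skipped with a warning
    (empty result, not an error).
    """
    params = params or ModeParams()
    if m.layer != "lognorm":
        raise ValueError("detect_pathway_modes requires a log-normalized matrix")
    sub = intersect_with_universe(gene_set, m.gene_ids)
    if len(sub) < params.min_genes:
        warnings.warn(
            f"pathway {gene_set.name!r}: only {len(sub)} of {len(gene_set)} genes "
            f"found in the matrix (< min_genes={params.min_genes}); skipped",
            stacklevel=2,
        )
        return PathwayModes(gene_set.name, [], [])
    dense = m.dense_submatrix(sub.genes)
    scaled, kept, _dropped = scale_gene_rows(dense, sub.genes)
    if len(kept) < params.min_genes:
        warnings.warn(
            f"pathway {gene_set.name!r}: only {len(kept)} genes with non-zero "
            f"variance (< min_genes={params.min_genes}); skipped",
            stacklevel=2,
        )
        return PathwayModes(gene_set.name, [], [])
    candidates = pca_modes(scaled, kept, params.max_modes, set_name=gene_set.name)
    informative: list[ActivationMode] = []
    evaluated: list[ActivationMode] = []
    for mode in candidates:
        orient_mode(mode)
        scale_mode_scores(mode)
        assess_mode(mode, params)
        evaluated.append(mode)
        if mode.informative:
            informative.append(mode)
        elif mode.index >= 2:
            break  # later PCs explain even less variance
    return PathwayModes(gene_set.name, informative, evaluated)


def build_activity_matrix(
    m: "ExpressionMatrix",
    sets: GeneSetCollection,
    params: ModeParams | None = None,
) -> tuple[ActivityMatrix, pd.DataFrame]:
    """Run mode detection over every pathway and stack the informative modes.

    Returns the activity matrix (rows named ``<set>_mode<k>``) and a
    per-candidate diagnostics table covering every component examined.
    The pipeline is deterministic: PCA is seed-free and the sign ambiguity
    is fixed by :func:`orient_mode`.
    """
    params = params or ModeParams()
    rows: list[np.ndarray] = []
    names: list[str] = []
    kept_modes: list[ActivationMode] = []
    diag_records = []
    for gene_set in sets:
        result = detect_pathway_modes(m, gene_set, params)
        for mode in result.informative:
            rows.append(mode.scores)
            names.append(mode.mode_name)
            kept_modes.append(mode)
        for mode in result.evaluated:
            diag_records.append(
                {
                    "set": mode.set_name,
                    "mode": mode.index,
                    "variance_explained": mode.variance_explained,
                    "informative": mode.informative,
                    "rejection_reason": mode.rejection_reason,
                    "active_fraction": mode.active_fraction,
                    "max_contribution": mode.max_contribution,
                    "threshold": mode.threshold,
                }
            )
    diagnostics = pd.DataFrame(
        diag_records,
        columns=[
            "set",
            "mode",
            "variance_explained",
            "informative",
            "rejection_reason",
            "active_fraction",
            "max_contribution",
            "threshold",
        ],
    )
    if not rows:
        warnings.warn("no informative mode found in any pathway", stacklevel=2)
        values = np.zeros((0, m.n_cells))
    else:
        values = np.vstack(rows)
    return (
        ActivityMatrix(
            values=values,
            mode_names=names,
            cell_ids=list(m.cell_ids),
            modes=kept_modes,
        ),
        diagnostics,
    )
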