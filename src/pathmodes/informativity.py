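"""Informativity gate for candidate activation modes.

A candidate mode (one principal component of a pathway submatrix, scaled to
[0, 1] per-cell scores) is *informative* when

1. its score distribution is bimodal — a kernel-density curve over the
   scores has a valley, right of the global density maximum, whose two
   flanking local maxima both rise at least ``density_drop_frac`` of the
   global maximum density above it;
2. the cells above the valley (the "active" cells) make up at least
   ``min_active_frac`` of the dataset, so the mode is not an outlier-cell
   artifact;
3. no single gene contributes more than ``max_contribution`` of the mode's
   (unit) squared-loading mass, so the mode reflects co-expression of a
   gene group rather than one outlier gene ("monogenic" rejection).

The density scan runs twice: first with a coarse bandwidth adjustment to
capture global shape, then — if no valley qualifies — with a finer one so
that narrow valleys (rare populations) are not missed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy import stats

if TYPE_CHECKING:  # pragma: no cover
    from .modes import ActivationMode

REASON_NONE = "none"
REASON_NO_BIMODAL = "no_bimodal"
REASON_TOO_FEW_ACTIVE = "too_few_active"
REASON_MONOGENIC = "monogenic"


@dataclass(frozen=True)
class ModeParams:
    """Tunable parameters of mode detection and the informativity gate.

    min_active_frac
        Minimum fraction of cells that must be active (default 5%).
    max_contribution
        Maximum squared loading a single gene may carry (default 0.4).
    density_drop_frac
        Valley depth criterion as a fraction of the global maximum density
        (default 10%).
    adjust_coarse, adjust_fine
        Bandwidth multipliers for the two density passes.
    grid_points
        Number of evaluation points of the density curve.
    max_modes
        Upper bound on the number of principal components examined.
    min_genes
        Minimum number of usable genes for a pathway to be analysed.
    """

    min_active_frac: float = 0.05
    max_contribution: float = 0.4
    density_drop_frac: float = 0.10
    adjust_coarse: float = 2.0
    adjust_fine: float = 1.0
    grid_points: int = 512
    max_modes: int = 10
    min_genes: int = 5

    def __post_init__(self) -> None:
        for name in ("min_active_frac", "max_contribution", "density_drop_frac"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0 and not (name == "max_contribution" and v == 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if not self.adjust_coarse >= self.adjust_fine > 0:
            raise ValueError("require adjust_coarse >= adjust_fine > 0")
        if self.grid_points < 16:
            raise ValueError("grid_points too small")
        if self.max_modes < 1 or self.min_genes < 2:
            raise ValueError("max_modes >= 1 and min_genes >= 2 required")

    def with_(self, **kwargs) -> "ModeParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class BimodalityResult:
    """Outcome of the density-valley search on one score vector."""

    found: bool
    threshold: float = float("nan")
    active_fraction: float = float("nan")
    adjust_used: float = float("nan")


def silverman_bandwidth(scores: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth, 0.9 min(sd, IQR/1.34) n^(-1/5).

    Falls back to the standard deviation when the IQR is degenerate.
    """
    x = np.asarray(scores, dtype=float)
    n = x.size
    sd = float(np.std(x, ddof=1))
    iqr = float(stats.iqr(x))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        raise ValueError("cannot pick a bandwidth for constant scores")
    return 0.9 * spread * n ** (-0.2)


def kde_curve(
    scores: np.ndarray, adjust: float = 1.0, grid_points: int = 512
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian KDE of the scores on an even grid.

    Bandwidth is Silverman's rule times ``adjust``; the grid spans
    ``[min - 3 bw, max + 3 bw]`` so the density tails decay inside it.
    """
    x = np.asarray(scores, dtype=float)
    if np.unique(x).size < 3:
        raise ValueError("need >= 3 distinct score values for a density curve")
    bw = silverman_bandwidth(x) * adjust
    kde = stats.gaussian_kde(x, bw_method=bw / np.std(x, ddof=1))
    grid = np.linspace(x.min() - 3.0 * bw, x.max() + 3.0 * bw, grid_points)
    return grid, kde(grid)


def _local_extrema(density: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local maxima and minima via sign changes of first differences.

    Plateaus collapse to their leftmost grid point (zeros of the difference
    are back-filled with the next non-zero sign).
    """
    s = np.sign(np.diff(density))
    # back-fill zeros with the following non-zero sign
    filled = s.copy()
    nxt = 0.0
    for i in range(filled.size - 1, -1, -1):
        if filled[i] == 0:
            filled[i] = nxt
        else:
            nxt = filled[i]
    idx = np.arange(1, density.size - 1)
    maxima = idx[(filled[idx - 1] > 0) & (filled[idx] < 0)]
    minima = idx[(filled[idx - 1] < 0) & (filled[idx] > 0)]
    return maxima, minima


def find_split(scores: np.ndarray, params: ModeParams | None = None) -> BimodalityResult:
    """Search the score density for a qualifying valley.

    Only minima right of the global density maximum are considered — an
    informative mode marks extreme (high-score) behaviour, possibly in a
    rare population.  They are scanned from the largest abscissa downward;
    the first whose flanking maxima both clear the depth criterion wins.
    A valley with no local maximum to its right is disqualified (a split
    needs a population on both sides).
    """
    params = params or ModeParams()
    x = np.asarray(scores, dtype=float)
    if np.unique(x).size < 3:
        return BimodalityResult(found=False)
    for adjust in (params.adjust_coarse, params.adjust_fine):
        grid, dens = kde_curve(x, adjust=adjust, grid_points=params.grid_points)
        maxima, minima = _local_extrema(dens)
        if maxima.size == 0 or minima.size == 0:
            continue
        g_idx = int(np.argmax(dens))
        drop = params.density_drop_frac * dens[g_idx]
        candidates = minima[grid[minima] > grid[g_idx]]
        for m in candidates[::-1]:  # decreasing abscissa
            left = maxima[maxima < m]
            right = maxima[maxima > m]
            if left.size == 0 or right.size == 0:
                continue
            lo, hi = left[-1], right[0]
            if dens[lo] - dens[m] >= drop and dens[hi] - dens[m] >= drop:
                threshold = float(grid[m])
                active_fraction = float(np.mean(x > threshold))
                if 0.0 < active_fraction < 1.0:
                    return BimodalityResult(
                        found=True,
                        threshold=threshold,
                        active_fraction=active_fraction,
                        adjust_used=adjust,
                    )
    return BimodalityResult(found=False)


def assess_mode(mode: "ActivationMode", params: ModeParams | None = None) -> "ActivationMode":
    """Apply the three informativity checks to a scored mode, in order.

    ``rejection_reason`` records the first failed check:
    bimodality -> active fraction -> maximum gene contribution.
    The mode is annotated in place and returned.
    """
    params = params or ModeParams()
    mode.informative = False
    if mode.rejection_reason == REASON_NO_BIMODAL:
        return mode  # constant scores flagged upstream
    split = find_split(mode.scores, params)
    if not split.found:
        mode.rejection_reason = REASON_NO_BIMODAL
        return mode
    mode.threshold = split.threshold
    mode.active_fraction = split.active_fraction
    if split.active_fraction < params.min_active_frac:
        mode.rejection_reason = REASON_TOO_FEW_ACTIVE
        return mode
    if float(np.max(mode.contributions)) > params.max_contribution:
        mode.rejection_reason = REASON_MONOGENIC
        return mode
    mode.rejection_reason = REASON_NONE
    mode.informative = True
    return mode


def contributing_genes(mode: "ActivationMode") -> list[str]:
    """Genes contributing more than the uniform expectation 1/n_genes.

    Returned in decreasing order of contribution.
    """
    contrib = mode.contributions
    expected = 1.0 / contrib.size
    order = np.argsort(contrib)[::-1]
    return [mode.genes[i] for i in order if contrib[i] > expected]


def top_genes(mode: "ActivationMode", n: int = 10) -> list[str]:
    """Top ``n`` genes of a mode by decreasing contribution."""
    order = np.argsort(mode.contributions)[::-1][:n]
    return [mode.genes[i] for i in order]
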