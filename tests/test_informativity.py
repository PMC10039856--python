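"""Density-based bimodality detection and the informativity gate."""

import numpy as np
import pytest
from scipy import stats

import pathmodes as pm
from pathmodes.informativity import (
    ModeParams,
    contributing_genes,
    find_split,
    kde_curve,
    top_genes,
)
from pathmodes.modes import ActivationMode


def _mixture_sample(rng, n=1000, w=0.7, mu=(0.2, 0.8), sd=0.02):
    comp = rng.random(n) < w
    x = np.where(comp, rng.normal(mu[0], sd, n), rng.normal(mu[1], sd, n))
    return np.clip(x, 0.0, 1.0)


def _mode_with(scores, contributions, genes=None):
    contributions = np.asarray(contributions, dtype=float)
    loadings = np.sqrt(contributions / contributions.sum())
    genes = genes or tuple(f"g{i}" for i in range(loadings.size))
    return ActivationMode(
        set_name="s", index=1, genes=tuple(genes), loadings=loadings,
        scores=np.asarray(scores, dtype=float), variance_explained=0.3,
    )


class TestKdeCurve:
    def test_bimodal_sample_has_two_maxima_at_coarse_bandwidth(self, rng):
        x = _mixture_sample(rng)
        _, dens = kde_curve(x, adjust=2.0)
        d = np.sign(np.diff(dens))
        n_max = int(np.sum((d[:-1] > 0) & (d[1:] < 0)))
        assert n_max == 2

    def test_unimodal_sample_has_single_maximum(self, rng):
        x = np.clip(rng.normal(0.5, 0.1, 1000), 0, 1)
        _, dens = kde_curve(x, adjust=2.0)
        d = np.sign(np.diff(dens))
        assert int(np.sum((d[:-1] > 0) & (d[1:] < 0))) == 1

    def test_density_integrates_to_one(self, rng):
        x = _mixture_sample(rng)
        grid, dens = kde_curve(x, adjust=1.0)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=0.01)

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            kde_curve(np.full(100, 0.5))


class TestFindSplit:
    def test_mixture_threshold_matches_analytic_minimum(self, rng):
        x = _mixture_sample(rng)
        res = find_split(x)
        assert res.found
        # oracle: brute-force minimum of the analytic mixture density
        # between the component means
        def density(v):
            return 0.7 * stats.norm.pdf(v, 0.2, 0.02) + 0.3 * stats.norm.pdf(v, 0.8, 0.02)
        grid = np.linspace(0.2, 0.8, 20001)
        oracle = grid[np.argmin(density(grid))]
        assert res.threshold == pytest.approx(oracle, abs=0.05)
        assert res.active_fraction == pytest.approx(0.3, abs=0.05)

    def test_unimodal_scores_not_split(self, rng):
        x = np.clip(rng.normal(0.5, 0.1, 1000), 0, 1)
        assert not find_split(x).found

    def test_shallow_dip_below_ten_percent_rejected(self, rng):
        # two equal-weight components close enough that the analytic dip is
        # under 10% of the peak density
        x = np.clip(
            np.concatenate(
                [rng.normal(0.42, 0.07, 1000), rng.normal(0.58, 0.07, 1000)]
            ),
            0,
            1,
        )
        def density(v):
            return 0.5 * stats.norm.pdf(v, 0.42, 0.07) + 0.5 * stats.norm.pdf(v, 0.58, 0.07)
        grid = np.linspace(0.3, 0.7, 4001)
        f = density(grid)
        dip = f[(grid >= 0.42) & (grid <= 0.58)].min()
        assert f.max() - dip < 0.10 * f.max()  # construction sanity check
        assert not find_split(x).found

    def test_split_invariant_to_score_shift_after_rescaling(self, rng):
        x = _mixture_sample(rng)
        shifted = (x + 0.37) / 1.37  # affine image inside [0, 1]
        a = find_split(x)
        b = find_split(shifted)
        assert a.found and b.found
        assert b.threshold * 1.37 - 0.37 == pytest.approx(a.threshold, abs=0.02)
        assert b.active_fraction == pytest.approx(a.active_fraction, abs=0.01)

    def test_accepted_split_leaves_cells_on_both_sides(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            res = find_split(_mixture_sample(r, w=0.5 + 0.08 * seed))
            if res.found:
                assert 0.0 < res.active_fraction < 1.0


class TestAssessMode:
    def test_informative_mode_passes_all_gates(self, rng):
        mode = _mode_with(_mixture_sample(rng), np.full(10, 0.1))
        pm.assess_mode(mode)
        assert mode.informative and mode.rejection_reason == "none"
        assert mode.active_fraction == pytest.approx(0.3, abs=0.05)

    def test_dominant_gene_rejected_as_monogenic(self, rng):
        mode = _mode_with(_mixture_sample(rng), [0.81, 0.1, 0.09])
        pm.assess_mode(mode)
        assert not mode.informative
        assert mode.rejection_reason == "monogenic"

    def test_small_active_fraction_rejected_before_contribution_check(self, rng):
        scores = _mixture_sample(rng, w=0.85)  # ~15% active
        mode = _mode_with(scores, [0.81, 0.1, 0.09])  # would also be monogenic
        pm.assess_mode(mode, ModeParams(min_active_frac=0.2))
        assert mode.rejection_reason == "too_few_active"

    def test_raising_min_active_frac_never_rescues_a_mode(self, rng):
        scores = _mixture_sample(rng)
        for strict, loose in [(0.5, 0.05), (0.9, 0.3)]:
            a = pm.assess_mode(_mode_with(scores, np.full(10, 0.1)),
                               ModeParams(min_active_frac=loose))
            b = pm.assess_mode(_mode_with(scores, np.full(10, 0.1)),
                               ModeParams(min_active_frac=strict))
            assert b.informative <= a.informative

    def test_contribution_sweep_separates_module_from_outlier(self):
        sim = pm.simulate_counts(pm.module_plus_outlier_spec(seed=0))
        m = pm.lognormalize(sim.expression)
        outlier_genes = set(sim.module_genes["outlier_pair"])
        seen = {}
        for cutoff in (0.1, 0.3, 0.6, 1.0):
            result = pm.detect_pathway_modes(
                m, sim.pathways["pathway_mixed"], ModeParams(max_contribution=cutoff)
            )
            kinds = [
                "outlier" if set(top_genes(mode, 2)) & outlier_genes else "module"
                for mode in result.informative
            ]
            seen[cutoff] = kinds
        for cutoff, kinds in seen.items():
            assert "module" in kinds, f"planted module lost at cutoff {cutoff}"
            assert ("outlier" in kinds) == (cutoff >= 0.6)


class TestContributingGenes:
    def test_above_uniform_expectation_in_rank_order(self):
        mode = _mode_with([0.0, 0.5, 1.0], [0.5, 0.3, 0.1, 0.1])
        assert contributing_genes(mode) == ["g0", "g1"]  # both > 1/4

    def test_uniform_contributions_give_empty_list(self):
        mode = _mode_with([0.0, 0.5, 1.0], np.full(5, 0.2))
        assert contributing_genes(mode) == []

    def test_single_gene_pathway_has_no_contributors(self):
        mode = _mode_with([0.0, 0.5, 1.0], [1.0])
        assert contributing_genes(mode) == []

    def test_top_genes_truncates_by_contribution(self):
        mode = _mode_with([0.0, 0.5, 1.0], [0.05, 0.4, 0.3, 0.25])
        assert top_genes(mode, 2) == ["g1", "g2"]
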