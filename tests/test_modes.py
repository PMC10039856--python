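"""PCA mode decomposition: scaling, orientation, score scaling, detection."""

import numpy as np
import pytest

import pathmodes as pm
from pathmodes.expression import ExpressionMatrix
from pathmodes.modes import (
    ActivationMode,
    orient_mode,
    pca_modes,
    scale_gene_rows,
    scale_mode_scores,
)


def _mode(loadings, scores, **kw):
    loadings = np.asarray(loadings, dtype=float)
    loadings = loadings / np.linalg.norm(loadings)
    return ActivationMode(
        set_name="s",
        index=1,
        genes=tuple(f"g{i}" for i in range(loadings.size)),
        loadings=loadings,
        scores=np.asarray(scores, dtype=float),
        variance_explained=0.5,
        **kw,
    )


class TestScaleGeneRows:
    def test_rows_become_standardized_and_constant_rows_drop(self, rng):
        values = rng.normal(2.0, 1.0, size=(5, 40))
        values[3, :] = 7.0  # constant gene
        scaled, kept, dropped = scale_gene_rows(values, [f"g{i}" for i in range(5)])
        assert dropped == ["g3"]
        assert kept == ["g0", "g1", "g2", "g4"]
        np.testing.assert_allclose(scaled.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(scaled.std(axis=1, ddof=1), 1.0, atol=1e-9)

    def test_gene_scale_invariance(self, rng):
        values = rng.normal(size=(3, 30))
        boosted = values.copy()
        boosted[1] *= 10.0
        a, _, _ = scale_gene_rows(values, list("abc"))
        b, _, _ = scale_gene_rows(boosted, list("abc"))
        np.testing.assert_allclose(a[1], b[1], atol=1e-12)


class TestPcaModes:
    def test_two_perfectly_correlated_genes(self, rng):
        base = rng.normal(size=60)
        scaled, kept, _ = scale_gene_rows(
            np.vstack([base, 2.0 * base + 1.0]), ["a", "b"]
        )
        modes = pca_modes(scaled, kept, max_modes=5)
        assert modes[0].variance_explained == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(modes[0].contributions, [0.5, 0.5], atol=1e-9)

    def test_variance_explained_non_increasing_and_projection_identity(self, rng):
        values = rng.normal(size=(8, 50))
        scaled, kept, _ = scale_gene_rows(values, [f"g{i}" for i in range(8)])
        modes = pca_modes(scaled, kept, max_modes=8)
        ve = [m.variance_explained for m in modes]
        assert all(a >= b - 1e-12 for a, b in zip(ve, ve[1:]))
        for mode in modes:
            np.testing.assert_allclose(
                mode.scores, scaled.T @ mode.loadings, atol=1e-8
            )

    def test_matches_independent_eigendecomposition(self, rng):
        # oracle: eigenvectors of the cell-space covariance matrix
        values = rng.normal(size=(10, 50)) + rng.normal(size=(1, 50))
        scaled, kept, _ = scale_gene_rows(values, [f"g{i}" for i in range(10)])
        modes = pca_modes(scaled, kept, max_modes=4)
        cov = np.cov(scaled, ddof=1)  # gene x gene covariance of standardized rows
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        for k, mode in enumerate(modes):
            oracle = v[:, order[k]]
            i = int(np.argmax(np.abs(oracle)))
            if oracle[i] < 0:
                oracle = -oracle
            orient_mode(mode)
            np.testing.assert_allclose(mode.loadings, oracle, atol=1e-8)

    def test_degenerate_rank_zero_input(self):
        scaled = np.zeros((4, 10))
        assert pca_modes(scaled, list("abcd"), max_modes=3) == []


class TestOrientMode:
    def test_flips_when_dominant_loading_negative(self):
        m = orient_mode(_mode([-0.9, 0.3], [1.0, -2.0]))
        assert m.loadings[0] > 0
        np.testing.assert_allclose(m.scores, [-1.0, 2.0])

    def test_identity_when_dominant_positive(self):
        m = _mode([0.9, -0.3], [1.0, -2.0])
        before = m.loadings.copy()
        orient_mode(m)
        np.testing.assert_array_equal(m.loadings, before)

    def test_idempotent_and_sign_invariant(self, rng):
        loadings = rng.normal(size=6)
        scores = rng.normal(size=20)
        a = orient_mode(_mode(loadings, scores))
        b = orient_mode(_mode(-loadings, -scores))
        c = orient_mode(_mode(a.loadings.copy(), a.scores.copy()))
        np.testing.assert_allclose(a.loadings, b.loadings)
        np.testing.assert_allclose(a.scores, b.scores)
        np.testing.assert_allclose(a.loadings, c.loadings)


class TestScaleModeScores:
    def test_affine_map_to_unit_interval(self):
        m = scale_mode_scores(_mode([1.0], [-2.0, 0.0, 2.0]))
        np.testing.assert_allclose(m.scores, [0.0, 0.5, 1.0])

    def test_non_degenerate_unit_scores_unchanged(self):
        m = scale_mode_scores(_mode([1.0], [0.0, 0.25, 1.0]))
        np.testing.assert_allclose(m.scores, [0.0, 0.25, 1.0])

    def test_constant_scores_flagged_non_bimodal(self):
        m = scale_mode_scores(_mode([1.0], [3.0, 3.0, 3.0]))
        assert np.all(m.scores == 0.0)
        assert m.rejection_reason == "no_bimodal"


class TestDetectPathwayModes:
    def test_planted_modules_recovered_with_correct_genes(
        self, two_module_sim, two_module_result
    ):
        result = two_module_result
        assert len(result.informative) == 2
        owners = []
        for mode in result.informative:
            top10 = set(pm.top_genes(mode, 10))
            in_a = len(top10 & set(two_module_sim.module_genes["module_A"]))
            in_b = len(top10 & set(two_module_sim.module_genes["module_B"]))
            owners.append("A" if in_a >= in_b else "B")
            assert max(in_a, in_b) >= 8
        assert sorted(owners) == ["A", "B"]

    def test_pure_noise_pathway_yields_nothing(self, two_module_sim, two_module_lognorm):
        noise = pm.noise_pathway(two_module_sim, 60, seed=4242)
        result = pm.detect_pathway_modes(two_module_lognorm, noise)
        assert result.informative == []

    def test_dominant_gradient_on_pc1_does_not_mask_pc2(self, rng):
        # a smooth gradient loads PC1 (unimodal, uninformative); a 20%
        # population module loads PC2 and must still be reported
        n = 400
        t = rng.normal(0, 1, n)
        z = np.zeros(n)
        z[rng.choice(n, 80, replace=False)] = 1.0
        values = np.vstack(
            [1.5 * t + rng.normal(0, 1, (20, n)), 3.0 * z + rng.normal(0, 1, (10, n))]
        )
        m = ExpressionMatrix(
            values, [f"g{i}" for i in range(30)], [f"c{i}" for i in range(n)],
            layer="lognorm",
        )
        result = pm.detect_pathway_modes(
            m, pm.GeneSet("pw", tuple(f"g{i}" for i in range(30)))
        )
        assert [mode.index for mode in result.informative] == [2]
        assert result.evaluated[0].rejection_reason == "no_bimodal"

    def test_small_pathway_skipped_with_warning(self, two_module_lognorm):
        tiny = pm.GeneSet("tiny", tuple(two_module_lognorm.gene_ids[:3]))
        with pytest.warns(UserWarning, match="min_genes"):
            result = pm.detect_pathway_modes(two_module_lognorm, tiny)
        assert result.informative == [] and result.evaluated == []

    def test_contributions_sum_to_one_and_scores_span_unit_interval(
        self, two_module_result
    ):
        for mode in two_module_result.evaluated:
            assert np.sum(mode.contributions) == pytest.approx(1.0, abs=1e-9)
        for mode in two_module_result.informative:
            assert mode.scores.min() == 0.0
            assert mode.scores.max() == 1.0
            assert np.all((mode.scores >= 0) & (mode.scores <= 1))


class TestBuildActivityMatrix:
    def test_rows_named_and_stacked(self, two_module_sim, two_module_lognorm):
        sets = pm.GeneSetCollection(
            [two_module_sim.pathways["pathway_AB"], pm.noise_pathway(two_module_sim, 40, 7)]
        )
        activity, diagnostics = pm.build_activity_matrix(two_module_lognorm, sets)
        assert activity.n_modes == 2
        assert activity.mode_names == ["pathway_AB_mode1", "pathway_AB_mode2"]
        assert "pathway_AB" in set(diagnostics["set"])
        assert np.all((activity.values >= 0) & (activity.values <= 1))

    def test_deterministic_and_column_equivariant(self, two_module_sim):
        m = pm.lognormalize(two_module_sim.expression)
        sets = pm.GeneSetCollection([two_module_sim.pathways["pathway_AB"]])
        a1, _ = pm.build_activity_matrix(m, sets)
        a2, _ = pm.build_activity_matrix(m, sets)
        np.testing.assert_array_equal(a1.values, a2.values)

        perm = np.random.default_rng(5).permutation(m.n_cells)
        permuted = ExpressionMatrix(
            m.to_dense()[:, perm],
            list(m.gene_ids),
            [m.cell_ids[i] for i in perm],
            layer="lognorm",
        )
        a3, _ = pm.build_activity_matrix(permuted, sets)
        np.testing.assert_allclose(a3.values, a1.values[:, perm], atol=1e-9)
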