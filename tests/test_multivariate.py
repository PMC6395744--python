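"""PCA, closed-form Fisher LDA, discriminant weights and ranking, checked
against dense eigensolver / scikit-learn / brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from myodisc import (
    DEFAULT_CONTRASTS,
    ContrastSpec,
    SimulationConfig,
    compute_discriminant_weights,
    fit_lda_binary,
    fit_pca,
    generate_dataset,
    rank_genes,
    run_pcalda,
    standardize,
)

MLC_CONTRAST = next(c for c in DEFAULT_CONTRASTS if c.name == "MLC_vs_WT")


def _default_z(seed=1):
    return standardize(generate_dataset(SimulationConfig(seed=seed)))


class TestPca:
    def test_eigenvalues_match_dense_eigendecomposition(self):
        z = _default_z()
        model = fit_pca(z, n_components=27)
        cov = np.cov(z.z.to_numpy(), rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert np.allclose(model.explained_variance, eig, atol=1e-8)

    def test_matches_sklearn_full_svd_solver(self):
        sklearn = pytest.importorskip("sklearn.decomposition")
        z = _default_z()
        model = fit_pca(z, n_components=27)
        ref = sklearn.PCA(n_components=27, svd_solver="full").fit(z.z.to_numpy())
        assert np.allclose(model.explained_variance, ref.explained_variance_, atol=1e-8)
        assert np.allclose(
            model.explained_variance_ratio, ref.explained_variance_ratio_, atol=1e-8
        )
        # loading columns agree up to sign
        ours = model.loadings.to_numpy()
        theirs = ref.components_.T
        cos = np.abs(np.sum(ours * theirs, axis=0))
        assert np.allclose(cos, 1.0, atol=1e-8)

    def test_loadings_are_orthonormal(self):
        model = fit_pca(_default_z(), n_components=27)
        gram = model.loadings.to_numpy().T @ model.loadings.to_numpy()
        assert np.allclose(gram, np.eye(27), atol=1e-8)

    def test_scores_are_projections_and_reconstruct_z(self):
        z = _default_z()
        model = fit_pca(z, n_components=27)
        x = z.z.to_numpy() - z.z.to_numpy().mean(axis=0)
        assert np.allclose(model.scores.to_numpy(), x @ model.loadings.to_numpy(), atol=1e-8)
        recon = model.scores.to_numpy() @ model.loadings.to_numpy().T
        assert np.allclose(recon, x, atol=1e-8)

    def test_variance_is_conserved_and_ratios_sum_to_one(self):
        z = _default_z()
        model = fit_pca(z, n_components=27)
        total = z.z.to_numpy().var(axis=0, ddof=1).sum()
        assert np.sum(model.explained_variance) == pytest.approx(total, abs=1e-8)
        assert np.sum(model.explained_variance_ratio) == pytest.approx(1.0, abs=1e-8)
        assert (np.diff(model.explained_variance) <= 1e-12).all()

    def test_rank_one_data_concentrates_on_pc1(self, rng):
        direction = rng.standard_normal(27)
        coefs = rng.standard_normal(40)
        data = np.outer(coefs, direction) + 1e-8 * rng.standard_normal((40, 27))
        model = fit_pca(pd.DataFrame(data))
        assert model.explained_variance_ratio[0] > 0.999

    def test_sign_convention_largest_entry_positive(self):
        model = fit_pca(_default_z(), n_components=27)
        load = model.loadings.to_numpy()
        for j in range(load.shape[1]):
            assert load[np.argmax(np.abs(load[:, j])), j] > 0

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError, match="n_components"):
            fit_pca(_default_z(), n_components=28)


def _two_clouds(rng, delta=(1.0, 0.0, 0.0), n=200):
    a = rng.standard_normal((n, 3))
    b = rng.standard_normal((n, 3)) + np.asarray(delta)
    scores = pd.DataFrame(
        np.vstack([a, b]), columns=["PC1", "PC2", "PC3"],
        index=[f"WT_FVB_{i}" for i in range(n)] + [f"MLC_{i}" for i in range(n)],
    )
    labels = pd.Series(["WT_FVB"] * n + ["MLC"] * n, index=scores.index)
    return scores, labels


class TestLdaBinary:
    def test_recovers_separating_axis_of_gaussian_clouds(self, rng):
        # identity covariance, means differ along the first axis; at n=5000
        # per class the sampling error of the mean difference keeps the
        # estimated direction within 0.05 rad of the true axis
        scores, labels = _two_clouds(rng, n=5000)
        model = fit_lda_binary(scores, labels, MLC_CONTRAST)
        angle = np.arccos(np.clip(abs(model.ld_coefficients @ [1, 0, 0]), -1, 1))
        assert angle < 0.05

    def test_direction_is_collinear_with_pinv_oracle(self, rng):
        # independent route: per-class covariance + pseudo-inverse
        for _ in range(25):
            scores, labels = _two_clouds(rng, delta=rng.standard_normal(3), n=20)
            model = fit_lda_binary(scores, labels, MLC_CONTRAST)
            a = scores[labels == "WT_FVB"].to_numpy()
            b = scores[labels == "MLC"].to_numpy()
            sw = np.cov(a.T) * (len(a) - 1) + np.cov(b.T) * (len(b) - 1)
            ref = np.linalg.pinv(sw) @ (b.mean(0) - a.mean(0))
            ref /= np.linalg.norm(ref)
            assert abs(model.ld_coefficients @ ref) > 1 - 1e-6

    def test_direction_agrees_with_sklearn_lda(self, rng):
        da = pytest.importorskip("sklearn.discriminant_analysis")
        scores, labels = _two_clouds(rng, delta=(0.8, -0.5, 0.3), n=50)
        model = fit_lda_binary(scores, labels, MLC_CONTRAST)
        ref = da.LinearDiscriminantAnalysis(solver="eigen").fit(
            scores.to_numpy(), (labels == "MLC").astype(int)
        )
        direction = ref.coef_.ravel() / np.linalg.norm(ref.coef_)
        assert abs(model.ld_coefficients @ direction) > 1 - 1e-6

    def test_fisher_ratio_beats_1000_random_directions(self, rng):
        scores, labels = _two_clouds(rng, delta=(0.6, 0.2, -0.4), n=30)
        model = fit_lda_binary(scores, labels, MLC_CONTRAST)

        def fisher(w):
            ld = scores.to_numpy() @ w
            a, b = ld[labels == "WT_FVB"], ld[labels == "MLC"]
            within = a.var(ddof=1) * (len(a) - 1) + b.var(ddof=1) * (len(b) - 1)
            return (a.mean() - b.mean()) ** 2 / within

        best = fisher(model.ld_coefficients)
        for _ in range(1000):
            w = rng.standard_normal(3)
            assert fisher(w / np.linalg.norm(w)) <= best + 1e-12

    def test_unit_norm_and_sign_convention(self, rng):
        scores, labels = _two_clouds(rng, delta=(-0.7, 0.1, 0.2), n=40)
        model = fit_lda_binary(scores, labels, MLC_CONTRAST)
        assert np.linalg.norm(model.ld_coefficients) == pytest.approx(1.0, abs=1e-9)
        assert model.class_mean_b > model.class_mean_a  # MLC above its WT

    def test_identical_classes_raise(self):
        scores = pd.DataFrame(
            np.tile([[1.0, 2.0, 3.0]], (6, 1)), columns=["PC1", "PC2", "PC3"],
            index=[f"WT_FVB_{i}" for i in range(3)] + [f"MLC_{i}" for i in range(3)],
        )
        labels = pd.Series(["WT_FVB"] * 3 + ["MLC"] * 3, index=scores.index)
        with pytest.raises(ValueError, match="identical class means"):
            fit_lda_binary(scores, labels, MLC_CONTRAST)

    def test_tiny_class_rejected(self, rng):
        scores, labels = _two_clouds(rng, n=2)
        with pytest.raises(ValueError, match=">= 2 samples"):
            fit_lda_binary(scores.iloc[1:], labels.iloc[1:], MLC_CONTRAST)


class TestWeightsAndRanking:
    def test_basis_coefficients_return_loading_column(self):
        model = fit_pca(_default_z(), n_components=3)
        weights = compute_discriminant_weights(model.loadings, np.array([1.0, 0.0, 0.0]))
        assert np.allclose(weights.to_numpy(), model.loadings["PC1"].to_numpy())

    def test_default_design_gives_27_weights(self):
        result = run_pcalda(generate_dataset(SimulationConfig(seed=1)))
        for gl in result.gene_lists.values():
            assert len(gl.table) == 27

    def test_matches_naive_loop_oracle(self, rng):
        loadings = pd.DataFrame(rng.standard_normal((4, 3)), index=list("abcd"))
        coef = rng.standard_normal(3)
        weights = compute_discriminant_weights(loadings, coef)
        for i, gene in enumerate("abcd"):
            expected = sum(loadings.iloc[i, j] * coef[j] for j in range(3))
            assert weights[gene] == pytest.approx(expected, abs=1e-12)

    def test_dimension_mismatch_rejected(self):
        model = fit_pca(_default_z(), n_components=3)
        with pytest.raises(ValueError, match="mismatch"):
            compute_discriminant_weights(model.loadings, np.ones(4))

    def test_rank_orders_by_absolute_weight(self):
        weights = pd.Series([0.1, -0.5, 0.3], index=["g1", "g2", "g3"])
        ranked = rank_genes(weights, "c")
        assert list(ranked.table["gene"]) == ["g1", "g3", "g2"]
        assert list(ranked.table["rank"]) == [1, 2, 3]
        assert ranked.top(1) == ["g2"]

    def test_ties_keep_input_gene_order(self):
        weights = pd.Series([0.5, -0.5, 0.5], index=["g1", "g2", "g3"])
        ranked = rank_genes(weights, "c")
        assert list(ranked.table["gene"]) == ["g1", "g2", "g3"]

    def test_ranking_is_permutation_invariant(self, rng):
        weights = pd.Series(rng.standard_normal(27), index=[f"g{i}" for i in range(27)])
        ranked = rank_genes(weights, "c")
        perm = rng.permutation(27)
        ranked_perm = rank_genes(weights.iloc[perm], "c")
        pd.testing.assert_frame_equal(ranked.table, ranked_perm.table)

    def test_nonfinite_weights_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            rank_genes(pd.Series([0.1, np.inf], index=["a", "b"]))


class TestPipeline:
    def test_largest_mlc_effects_are_most_discriminant(self):
        result = run_pcalda(generate_dataset(SimulationConfig(seed=1)))
        assert set(result.gene_lists["MLC_vs_WT"].top(3)) == {
            "Ampar2", "PKC_theta", "Irisin",
        }

    def test_first_three_pcs_carry_two_thirds_of_variance(self):
        result = run_pcalda(generate_dataset(SimulationConfig(seed=1)))
        assert result.pca.explained_variance_ratio[:3].sum() >= 2 / 3

    def test_zero_effect_dataset_shows_no_significant_separation(self):
        # all FC = 0: the LD class-mean gap should sit inside the
        # label-permutation null at the 5% level
        fc_map = {g: {} for g in ("WT_C57_90", "WT_C57_130", "SOD1_90",
                                  "SOD1_130", "WT_FVB", "MLC")}
        ds = generate_dataset(SimulationConfig(fc_map=fc_map, seed=4))
        result = run_pcalda(ds)
        rng = np.random.default_rng(0)
        contrast = MLC_CONTRAST
        scores = result.pca.scores.loc[ds.samples_in(contrast.groups), ["PC1", "PC2", "PC3"]]
        labels = ds.groups.loc[scores.index]
        observed = result.ldas[contrast.name].class_mean_b - result.ldas[
            contrast.name
        ].class_mean_a
        exceed = 0
        n_perm = 1000
        for _ in range(n_perm):
            perm = pd.Series(rng.permutation(labels.to_numpy()), index=labels.index)
            model = fit_lda_binary(scores, perm, contrast)
            if model.class_mean_b - model.class_mean_a >= observed:
                exceed += 1
        assert (exceed + 1) / (n_perm + 1) > 0.05

    def test_same_seed_runs_are_identical(self):
        a = run_pcalda(generate_dataset(SimulationConfig(seed=3)))
        b = run_pcalda(generate_dataset(SimulationConfig(seed=3)))
        for name in a.gene_lists:
            pd.testing.assert_frame_equal(a.gene_lists[name].table, b.gene_lists[name].table)
        assert np.array_equal(a.pca.explained_variance, b.pca.explained_variance)

    def test_missing_group_names_the_contrast(self):
        ds = generate_dataset(SimulationConfig(seed=1))
        keep = [s for s in ds.sample_ids if not s.startswith("MLC")]
        trimmed = type(ds)(ds.values.loc[keep], ds.groups.loc[keep])
        with pytest.raises(ValueError, match="MLC_vs_WT"):
            run_pcalda(trimmed)

    def test_weights_and_ranks_invariant_to_pc_sign_flip(self):
        ds = generate_dataset(SimulationConfig(seed=2))
        result = run_pcalda(ds)
        pca = result.pca
        flipped_loadings = pca.loadings.copy()
        flipped_scores = pca.scores.copy()
        flipped_loadings["PC2"] *= -1
        flipped_scores["PC2"] *= -1
        contrast = MLC_CONTRAST
        samples = ds.samples_in(contrast.groups)
        lda = fit_lda_binary(
            flipped_scores.loc[samples, ["PC1", "PC2", "PC3"]],
            ds.groups.loc[samples], contrast,
        )
        weights = compute_discriminant_weights(
            flipped_loadings[["PC1", "PC2", "PC3"]], lda.ld_coefficients, contrast.name
        )
        original = rank_genes(
            compute_discriminant_weights(
                pca.loadings[["PC1", "PC2", "PC3"]],
                result.ldas[contrast.name].ld_coefficients, contrast.name,
            ),
            contrast.name,
        )
        flipped = rank_genes(weights, contrast.name)
        assert list(original.table["gene"]) == list(flipped.table["gene"])
        assert np.allclose(original.table["abs_weight"], flipped.table["abs_weight"])
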