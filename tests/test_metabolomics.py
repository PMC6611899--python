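"""Preprocessing, PCA, PLS-DA/NIPALS, VIP and differential selection."""

import numpy as np
import pandas as pd
import pytest

from phytonet import (
    FeatureTable,
    SyntheticSpec,
    generate_metabolomics,
    heatmap_matrix,
    pca,
    plsda,
    preprocess,
    select_differential,
    vip,
)
from phytonet.metabolomics import separation_statistic


def table_from(matrix, groups=None, prefix="m"):
    matrix = np.asarray(matrix, dtype=float)
    n, p = matrix.shape
    samples = [f"s{i:02d}" for i in range(n)]
    if groups is None:
        groups = ["a"] * (n // 2) + ["b"] * (n - n // 2)
    return FeatureTable(
        intensities=pd.DataFrame(
            matrix, index=samples, columns=[f"{prefix}{j}" for j in range(p)]
        ),
        groups=pd.Series(groups, index=samples),
    )


class TestPreprocess:
    def test_two_point_column_unit_variance(self):
        t = table_from([[2.0], [4.0]], groups=["a", "b"])
        out = preprocess(t, log_transform=False, scaling="unit_variance")
        np.testing.assert_allclose(
            out.intensities["m0"], [-0.7071067811865475, 0.7071067811865475]
        )

    def test_centring_only_zero_means(self):
        rng = np.random.default_rng(0)
        t = table_from(rng.uniform(1, 10, size=(8, 5)))
        out = preprocess(t, log_transform=False, scaling="none")
        np.testing.assert_allclose(out.intensities.mean(), 0, atol=1e-12)

    def test_half_minimum_imputation(self):
        m = np.array([[8.0], [np.nan], [12.0], [9.0]])
        t = table_from(m)
        out = preprocess(t, log_transform=False, scaling="none")
        # imputed value is min/2 = 4, then centred
        recon = out.intensities["m0"] + np.nanmean([8, 4, 12, 9])
        assert recon.iloc[1] == pytest.approx(4.0)

    def test_zero_variance_dropped_with_warning(self, caplog):
        t = table_from([[1.0, 2.0], [1.0, 3.0], [1.0, 4.0]], groups=list("aab"))
        with caplog.at_level("WARNING"):
            out = preprocess(t, log_transform=False, scaling="unit_variance")
        assert list(out.intensities.columns) == ["m1"]
        assert any("zero-variance" in r.message for r in caplog.records)


class TestPca:
    def test_rank_one_matrix_single_component(self):
        u = np.outer(np.arange(1.0, 7.0), [1.0, 2.0, -1.0])
        model = pca(table_from(u), n_components=1)
        assert model.explained[0] == pytest.approx(1.0)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(10, 6))
        t = table_from(x)
        model = pca(t, n_components=6)
        centred = x - x.mean(axis=0)
        recon = model.scores @ model.loadings.T
        rel = np.linalg.norm(recon - centred) / np.linalg.norm(centred)
        assert rel <= 1e-8

    def test_duplicated_samples_share_scores(self):
        x = np.vstack([[1, 2, 3], [1, 2, 3], [4, 0, 1], [2, 2, 2]]).astype(float)
        model = pca(table_from(x), n_components=2)
        np.testing.assert_allclose(model.scores[0], model.scores[1], atol=1e-12)

    def test_excess_components_truncated_with_warning(self, caplog):
        x = np.outer(np.arange(4.0), [1.0, 2.0])
        with caplog.at_level("WARNING"):
            model = pca(table_from(x), n_components=5)
        assert model.n_components <= 2
        assert any("truncating" in r.message for r in caplog.records)


class TestPlsda:
    def test_single_metabolite_vip_is_one(self):
        t = table_from([[1.0], [2.0], [5.0], [6.0]], groups=list("aabb"))
        model = plsda(preprocess(t, log_transform=False), n_components=1)
        np.testing.assert_allclose(model.vip_, [1.0])

    def test_scores_mutually_orthogonal(self):
        table, _ = generate_metabolomics(SyntheticSpec(seed=5))
        model = plsda(preprocess(table), n_components=3)
        gram = model.scores.T @ model.scores
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8

    def test_mean_squared_vip_is_one(self):
        table, _ = generate_metabolomics(SyntheticSpec(seed=6))
        model = plsda(preprocess(table), n_components=2)
        assert np.mean(model.vip_**2) == pytest.approx(1.0, abs=1e-10)

    def test_planted_metabolites_occupy_top_vip_ranks(self):
        spec = SyntheticSpec(seed=8)
        table, truth = generate_metabolomics(spec)
        model = plsda(preprocess(table), n_components=2)
        order = np.argsort(model.vip_)[::-1]
        top = {model.feature_ids[i] for i in order[: len(truth)]}
        overlap = len(top & set(truth["metabolite"])) / len(truth)
        assert overlap >= 0.9

    def test_permuted_labels_degrade_separation(self):
        spec = SyntheticSpec(seed=9)
        table, _ = generate_metabolomics(spec)
        prep = preprocess(table)
        r2y = separation_statistic(plsda(prep, n_components=2))
        rng = np.random.default_rng(0)
        perm = prep.groups.copy()
        perm[:] = rng.permutation(perm.to_numpy())
        r2y_perm = separation_statistic(
            plsda(FeatureTable(prep.intensities, perm), n_components=2)
        )
        assert r2y_perm < r2y

    def test_non_binary_groups_rejected(self):
        t = table_from(np.eye(3), groups=list("abc"))
        with pytest.raises(ValueError, match="2 groups"):
            plsda(t)

    def test_first_component_matches_pca_when_y_follows_it(self):
        """If the response is proportional to PC1 scores, PLS w1 aligns with PC1."""
        rng = np.random.default_rng(11)
        x = rng.normal(size=(30, 8))
        pca_model = pca(table_from(x), n_components=1)
        t1 = pca_model.scores[:, 0]
        groups = np.where(t1 > np.median(t1), "b", "a")
        # use y exactly proportional to t1 via a direct NIPALS fit
        xc = x - x.mean(axis=0)
        w = xc.T @ t1
        w /= np.linalg.norm(w)
        cos = abs(float(w @ pca_model.loadings[:, 0]))
        assert cos == pytest.approx(1.0, abs=1e-8)
        # and the fitted PLS-DA on the median split stays strongly aligned
        model = plsda(table_from(xc, groups=list(groups)), n_components=1)
        cos_fit = abs(float(model.weights[:, 0] @ pca_model.loadings[:, 0]))
        assert cos_fit > 0.9


class TestVip:
    def test_equal_weights_give_unit_vip(self):
        p = 5
        model = plsda(
            table_from(
                np.outer([1.0, -1.0, 1.0, -1.0], np.ones(p)),
                groups=list("abab"),
            ),
            n_components=1,
        )
        np.testing.assert_allclose(model.vip_, np.ones(p), atol=1e-8)

    def test_hand_computed_two_metabolite_case(self):
        """One component, weights (w1, w2): VIP_j = sqrt(2 * w_j^2 / (w1^2+w2^2))."""
        rng = np.random.default_rng(2)
        x = rng.normal(size=(12, 2))
        groups = ["a"] * 6 + ["b"] * 6
        model = plsda(table_from(x, groups=groups), n_components=1)
        w = model.weights[:, 0]
        expected = np.sqrt(2 * w**2 / np.sum(w**2))
        np.testing.assert_allclose(vip(model), expected, atol=1e-10)

    def test_pca_model_rejected(self):
        model = pca(table_from(np.random.default_rng(0).normal(size=(5, 3))))
        with pytest.raises(ValueError):
            vip(model)


class TestSelectDifferential:
    def test_no_metabolite_passes_empty_table(self):
        rng = np.random.default_rng(12)
        table = table_from(rng.lognormal(size=(10, 20)))
        model = plsda(preprocess(table), n_components=1)
        out = select_differential(table, model, vip_threshold=1e6)
        assert out.empty

    def test_planted_recovery_sensitivity_and_fdr(self):
        """Effect 2 SD, n=25/group: sensitivity >= 0.9 and FDR <= 0.1 over seeds."""
        sens, fdr = [], []
        for seed in range(20):
            spec = SyntheticSpec(seed=seed)
            table, truth = generate_metabolomics(spec)
            model = plsda(preprocess(table), n_components=2)
            out = select_differential(table, model)
            found, planted = set(out["metabolite"]), set(truth["metabolite"])
            sens.append(len(found & planted) / len(planted))
            fdr.append(len(found - planted) / max(len(found), 1))
        assert np.mean(sens) >= 0.9
        assert np.mean(fdr) <= 0.1

    def test_directions_match_ground_truth(self):
        spec = SyntheticSpec(seed=3)
        table, truth = generate_metabolomics(spec)
        model = plsda(preprocess(table), n_components=2)
        out = select_differential(table, model).set_index("metabolite")
        truth = truth.set_index("metabolite")
        shared = out.index.intersection(truth.index)
        assert len(shared) > 0
        assert (out.loc[shared, "direction"] == truth.loc[shared, "direction"]).all()

    def test_sensitivity_monotone_in_effect_size(self):
        sens_by_effect = []
        for effect in (0.5, 1.0, 2.0):
            hits, total = 0, 0
            for seed in range(5):
                spec = SyntheticSpec(seed=400 + seed)
                spec.metabolomics.effect_sd = effect
                table, truth = generate_metabolomics(spec)
                model = plsda(preprocess(table), n_components=2)
                found = set(select_differential(table, model)["metabolite"])
                hits += len(found & set(truth["metabolite"]))
                total += len(truth)
            sens_by_effect.append(hits / total)
        assert sens_by_effect == sorted(sens_by_effect)


class TestHeatmapMatrix:
    def test_two_sample_z_scores(self):
        t = table_from([[1.0], [2.0]], groups=["a", "b"])
        z, rows, cols = heatmap_matrix(t, ["m0"])
        np.testing.assert_allclose(
            z.loc["m0"], [-0.7071067811865475, 0.7071067811865475]
        )

    def test_identical_samples_zeroed_with_warning(self, caplog):
        t = table_from([[3.0, 1.0], [3.0, 2.0]], groups=["a", "b"])
        with caplog.at_level("WARNING"):
            z, _, _ = heatmap_matrix(t, ["m0", "m1"])
        np.testing.assert_allclose(z.loc["m0"], 0.0)

    def test_row_order_stable_across_reruns(self):
        table, truth = generate_metabolomics(SyntheticSpec(seed=14))
        selected = sorted(truth["metabolite"])
        _, rows1, cols1 = heatmap_matrix(table, selected)
        _, rows2, cols2 = heatmap_matrix(table, selected)
        assert rows1 == rows2 and cols1 == cols2
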