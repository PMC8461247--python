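import numpy as np
import pytest

import tensoromics.classify as classify_mod
from tensoromics.classify import (
    EvalConfig,
    build_classifier_input,
    cross_validate,
    evaluate_pipeline,
    macro_f1,
    omics_ablation,
    project_samples,
)
from tensoromics.features import GeneFeatureAssignment
from tensoromics.genecentric import OmicsTensor
from tensoromics.pipeline import load_gene_centric_matrices


def _toy_tensor(rng, n=8, m=6, k=3):
    return OmicsTensor(
        gene_ids=[f"g{i}" for i in range(n)],
        sample_ids=[f"s{j}" for j in range(m)],
        omics_names=["GE", "ME", "MI"][:k],
        values=rng.uniform(0, 1, (n, m, k)),
    )


def _assignment(gene_feature):
    return GeneFeatureAssignment(
        gene_feature=np.asarray(gene_feature), feature_omics=np.zeros(8, int)
    )


class TestBuildInput:
    def test_gene_values_column_count_scales_with_subset(self, rng):
        tensor = _toy_tensor(rng)
        # 5 genes assigned to feature 0, the rest to feature 7
        assignment = _assignment([0] * 5 + [7] * 3)
        for subset, expected in ((("GE", "ME"), 10), (("GE",), 5)):
            cfg = EvalConfig(omics_subset=subset, n_folds=2)
            X = build_classifier_input(tensor, assignment, [0], cfg)
            assert X.shape == (6, expected)

    def test_patient_features_uses_cp_columns(self, rng):
        cfg = EvalConfig(input_kind="patient_features", n_folds=2)
        C_p = rng.uniform(0, 1, (6, 30))
        X = build_classifier_input(
            _toy_tensor(rng), _assignment([0] * 8), list(range(26)), cfg, C_p=C_p
        )
        assert X.shape == (6, 26)

    def test_empty_selection_rejected(self, rng):
        cfg = EvalConfig(n_folds=2)
        with pytest.raises(ValueError, match="empty"):
            build_classifier_input(_toy_tensor(rng), _assignment([3] * 8), [0], cfg)


class TestMacroF1:
    def test_hand_computed_confusion(self):
        # class A: TP=2, FP=1, FN=0 -> F1=0.8; class B: TP=1, FP=0, FN=1 -> 2/3
        confusion = np.array([[2, 0], [1, 1]])
        assert macro_f1(confusion) == pytest.approx((0.8 + 2 / 3) / 2)

    def test_perfect_prediction(self):
        assert macro_f1(np.diag([5, 3, 2])) == 1.0

    def test_absent_prediction_scores_zero_for_class(self):
        confusion = np.array([[4, 0], [2, 0]])
        f1_a = 2 * (4 / 6) * 1.0 / (4 / 6 + 1.0)
        assert macro_f1(confusion) == pytest.approx(f1_a / 2)


class TestCrossValidate:
    def test_separable_classes_reach_perfect_f1(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (20, 3)), rng.normal(5, 0.1, (20, 3))])
        y = np.array(["A"] * 20 + ["B"] * 20, dtype=object)
        cfg = EvalConfig(n_folds=5, seed=0, hidden_units=20, mlp_max_epochs=300)
        result = cross_validate(X, y, cfg)
        assert result.mean_f1 == 1.0

    def test_permuted_labels_score_near_chance(self, rng):
        X = rng.normal(0, 1, (100, 5))
        y = np.array(["A", "B"] * 50, dtype=object)
        cfg = EvalConfig(n_folds=5, seed=1, hidden_units=20, mlp_max_epochs=200)
        result = cross_validate(X, y, cfg)
        assert abs(result.mean_f1 - 0.5) <= 0.15

    def test_fold_assignment_depends_only_on_labels_and_seed(self, rng):
        X = rng.normal(0, 1, (30, 4))
        y = np.array(["A", "B", "C"] * 10, dtype=object)
        cfg = EvalConfig(n_folds=3, seed=4, hidden_units=10, mlp_max_epochs=50)
        a = cross_validate(X, y, cfg)
        b = cross_validate(X, y, cfg)
        assert a.fold_scores == b.fold_scores
        np.testing.assert_array_equal(a.confusion, b.confusion)

    def test_small_class_reduces_folds(self, rng):
        X = rng.normal(0, 1, (13, 3))
        y = np.array(["A"] * 10 + ["B"] * 3, dtype=object)
        cfg = EvalConfig(n_folds=10, seed=0, hidden_units=5, mlp_max_epochs=50)
        result = cross_validate(X, y, cfg)
        assert result.n_folds_used == 3

    def test_confusion_row_sums_are_class_counts(self, rng):
        X = rng.normal(0, 1, (30, 4))
        y = np.array(["A"] * 18 + ["B"] * 12, dtype=object)
        cfg = EvalConfig(n_folds=3, seed=0, hidden_units=5, mlp_max_epochs=50)
        result = cross_validate(X, y, cfg)
        np.testing.assert_array_equal(result.confusion.sum(axis=1), [18, 12])


class TestProjection:
    def test_training_sample_loadings_recovered(self, rng):
        G = rng.uniform(0, 1, (20, 3))
        P = rng.uniform(0.2, 1, (10, 3))
        O = rng.uniform(0.2, 1, (2, 3))
        T = np.einsum("ir,jr,kr->ijk", G, P, O)
        loadings, resid = project_samples(G, O, np.transpose(T, (1, 0, 2)))
        rel = np.linalg.norm(loadings - P) / np.linalg.norm(P)
        assert rel <= 1e-4
        assert np.all(resid <= 1e-8)

    def test_zero_slice_gives_zero_loadings(self, rng):
        G, O = rng.uniform(0, 1, (5, 2)), rng.uniform(0, 1, (2, 2))
        loadings, _ = project_samples(G, O, np.zeros((5, 2)))
        np.testing.assert_allclose(loadings, 0.0)

    def test_loadings_always_nonnegative(self, rng):
        G, O = rng.uniform(0, 1, (6, 2)), rng.uniform(0, 1, (2, 2))
        X = rng.normal(0, 1, (4, 6, 2))  # even for noisy, signed input
        loadings, _ = project_samples(G, O, X)
        assert loadings.min() >= 0.0


class TestStrictMode:
    def test_strict_fit_never_sees_test_samples(self, ge_me_fixture_dir, monkeypatch):
        """Instrumentation: decomposition and selection inside strict CV
        only ever receive training-fold sample counts."""
        data_dir, *_ = ge_me_fixture_dir
        matrices, labels = load_gene_centric_matrices(data_dir)
        n_total = len(matrices[0].sample_ids)
        seen_decomp_sizes, seen_select_sizes = [], []

        real_parafac = classify_mod.parafac_nn
        real_select = classify_mod.select_all_labels

        def spy_parafac(tensor, rank, **kw):
            seen_decomp_sizes.append(len(tensor.sample_ids))
            return real_parafac(tensor, rank, **kw)

        def spy_select(C_p, y, **kw):
            seen_select_sizes.append(np.asarray(C_p).shape[0])
            return real_select(C_p, y, **kw)

        monkeypatch.setattr(classify_mod, "parafac_nn", spy_parafac)
        monkeypatch.setattr(classify_mod, "select_all_labels", spy_select)
        cfg = EvalConfig(mode="strict", n_folds=2, rank=4, seed=0,
                         n_starts=1, max_iter=60, hidden_units=10,
                         mlp_max_epochs=50)
        evaluate_pipeline(matrices, labels, cfg)
        assert seen_decomp_sizes and seen_select_sizes
        assert all(s < n_total for s in seen_decomp_sizes)
        assert all(s < n_total for s in seen_select_sizes)

    def test_ablation_enumerates_all_subsets(self, ge_me_fixture_dir):
        data_dir, *_ = ge_me_fixture_dir
        matrices, labels = load_gene_centric_matrices(data_dir)
        cfg = EvalConfig(mode="transductive", n_folds=2, rank=8, seed=0,
                         n_starts=2, max_iter=200, hidden_units=20,
                         mlp_max_epochs=100)
        table = omics_ablation(matrices, labels, cfg)
        assert len(table) == 7
        assert set(table) == {
            "GE", "ME", "MI", "GE+ME", "GE+MI", "ME+MI", "GE+ME+MI"
        }
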