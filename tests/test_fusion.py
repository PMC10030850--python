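import itertools

import numpy as np
import pytest

from omicsubtyper.fusion import (
    BaseLearnerSpec,
    FusedModel,
    FusionWeights,
    ModelBundle,
    ModelVariant,
    ProbabilityMatrix,
    concat_probabilities,
    enumerate_weight_grid,
    evaluate_accuracy,
    feature_level_fuse,
    grid_search_weights,
    linear_fuse,
    split_train_test,
    train_base,
    train_fused,
)
from omicsubtyper.types import OmicKind, OmicMatrix

from .conftest import make_omic


def fast_spec(kind="svm_rbf", seed=0):
    return BaseLearnerSpec(
        kind=kind,
        cv_folds=3,
        cv_repeats=1,
        svm_costs=(1.0, 10.0),
        svm_gamma_factors=(1.0,),
        rf_trees=(30,),
        rf_max_features=("sqrt",),
        ffnn_learning_rates=(1e-2, 1e-3),
        ffnn_epochs=30,
        seed=seed,
    )


def separable_data(n_per=30, n_classes=2, sep=8.0, d=6, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n_per * n_classes, d))
    y = np.repeat(np.arange(1, n_classes + 1), n_per)
    for k in range(n_classes):
        x[y == k + 1, k % d] += sep * (k + 1)
    return x, y


def prob_matrix(values, role="P_SVM", classes=None):
    values = np.asarray(values, dtype=float)
    classes = classes or list(range(1, values.shape[1] + 1))
    return ProbabilityMatrix(
        sample_ids=[f"s{i}" for i in range(values.shape[0])],
        classes=classes,
        values=values,
        role=role,
    )


class TestProbabilityMatrix:
    def test_rows_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            prob_matrix([[0.5, 0.4]])

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            prob_matrix([[1.2, -0.2]])

    def test_pc_width(self):
        p = prob_matrix(np.full((2, 6), 1 / 6), role="P_C", classes=[1, 2])
        assert p.values.shape[1] == 6

    def test_argmax_tie_lowest_class(self):
        p = prob_matrix([[0.5, 0.5]])
        assert p.predicted_labels()[0] == 1


class TestFusionWeights:
    def test_simplex_enforced(self):
        with pytest.raises(ValueError):
            FusionWeights(0.5, 0.5, 0.5)
        with pytest.raises(ValueError):
            FusionWeights(-0.1, 0.6, 0.5)

    def test_valid(self):
        w = FusionWeights(0.2, 0.3, 0.5)
        assert w.as_tuple() == (0.2, 0.3, 0.5)


class TestSplitTrainTest:
    def test_90_10_balanced_five_classes(self):
        rng = np.random.default_rng(0)
        y = np.repeat([1, 2, 3, 4, 5], 20)
        x = rng.normal(size=(100, 2))
        tr, te = split_train_test(x, y, 0.1, seed=0)
        assert len(tr) == 90 and len(te) == 10
        _, counts = np.unique(y[te], return_counts=True)
        assert (counts == 2).all()

    def test_deterministic(self):
        x, y = separable_data()
        a = split_train_test(x, y, 0.2, seed=3)
        b = split_train_test(x, y, 0.2, seed=3)
        np.testing.assert_array_equal(a[0], b[0])

    def test_fraction_zero_rejected(self):
        x, y = separable_data()
        with pytest.raises(ValueError):
            split_train_test(x, y, 0.0, seed=0)

    def test_singleton_class_rejected(self):
        x = np.zeros((3, 2))
        y = np.array([1, 1, 2])
        with pytest.raises(ValueError, match="single sample"):
            split_train_test(x, y, 0.3, seed=0)


class TestTrainBase:
    @pytest.mark.parametrize("kind", ["svm_rbf", "random_forest", "ffnn"])
    def test_separable_training_accuracy(self, kind):
        x, y = separable_data(n_per=30, sep=8.0)
        model = train_base(x, y, fast_spec(kind))
        assert evaluate_accuracy(model.predict(x), y) == 1.0

    @pytest.mark.parametrize("kind", ["svm_rbf", "random_forest", "ffnn"])
    def test_probability_rows_sum_to_one(self, kind, rng):
        x, y = separable_data(n_per=20, sep=2.0, seed=4)
        model = train_base(x, y, fast_spec(kind))
        proba = model.predict_proba(rng.normal(size=(10, x.shape[1])))
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)
        assert (proba >= 0).all()

    def test_selected_hyperparameters_deterministic(self):
        x, y = separable_data(n_per=15, sep=1.0, seed=8)
        a = train_base(x, y, fast_spec("svm_rbf"))
        b = train_base(x, y, fast_spec("svm_rbf"))
        assert a.selected_params_ == b.selected_params_

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            train_base(np.zeros((5, 2)), np.ones(5), fast_spec())


class TestLinearFuse:
    def test_identity_corner(self, rng):
        p = rng.dirichlet(np.ones(3), size=8)
        ps = prob_matrix(p, "P_SVM")
        pr = prob_matrix(rng.dirichlet(np.ones(3), size=8), "P_RF")
        pf = prob_matrix(rng.dirichlet(np.ones(3), size=8), "P_FFNN")
        fused = linear_fuse(ps, pr, pf, FusionWeights(1, 0, 0))
        np.testing.assert_array_equal(fused.values, ps.values)

    def test_uniform_average(self):
        ps = prob_matrix([[1.0, 0.0]])
        pr = prob_matrix([[0.0, 1.0]], "P_RF")
        pf = prob_matrix([[0.5, 0.5]], "P_FFNN")
        fused = linear_fuse(ps, pr, pf, FusionWeights(1 / 3, 1 / 3, 1 / 3))
        np.testing.assert_allclose(fused.values, [[0.5, 0.5]])

    def test_rows_sum_to_one_algebraic(self, rng):
        mats = [prob_matrix(rng.dirichlet(np.ones(4), size=20), r)
                for r in ("P_SVM", "P_RF", "P_FFNN")]
        w = rng.dirichlet(np.ones(3))
        fused = linear_fuse(*mats, FusionWeights(*w))
        np.testing.assert_allclose(fused.values.sum(axis=1), 1.0, atol=1e-9)

    def test_invalid_input_rejected(self, rng):
        with pytest.raises(ValueError):
            prob_matrix([[1.5, -0.5]])

    def test_misaligned_rejected(self, rng):
        a = prob_matrix(rng.dirichlet(np.ones(2), size=3))
        b = ProbabilityMatrix(["x0", "x1", "x2"], [1, 2],
                              rng.dirichlet(np.ones(2), size=3), "P_RF")
        c = prob_matrix(rng.dirichlet(np.ones(2), size=3), "P_FFNN")
        with pytest.raises(ValueError, match="share sample"):
            linear_fuse(a, b, c, FusionWeights(1 / 3, 1 / 3, 1 / 3))


def brute_force_grid(step):
    s = round(1 / step)
    out = []
    for a in range(s + 1):
        for b in range(s + 1 - a):
            out.append((a / s, b / s, (s - a - b) / s))
    return out


class TestWeightGrid:
    def test_step_005_gives_231(self):
        grid = enumerate_weight_grid(0.05)
        assert len(grid) == 231
        brute = set(brute_force_grid(0.05))
        assert {w.as_tuple() for w in grid} == brute

    @pytest.mark.parametrize("step", [0.5, 0.25, 0.1, 0.05])
    def test_count_matches_stars_and_bars(self, step):
        s = round(1 / step)
        expected = (s + 1) * (s + 2) // 2  # C(s+2, 2)
        assert len(enumerate_weight_grid(step)) == expected
        assert len(brute_force_grid(step)) == expected

    def test_bad_step_rejected(self):
        with pytest.raises(ValueError, match="divide 1"):
            enumerate_weight_grid(0.3)

    def test_perfect_learner_corner_selected(self, rng):
        y = rng.integers(1, 4, size=40)
        perfect = np.eye(3)[y - 1]
        noise1 = rng.dirichlet(np.ones(3), size=40)
        noise2 = rng.dirichlet(np.ones(3), size=40)
        w, acc = grid_search_weights(
            prob_matrix(perfect, "P_SVM"),
            prob_matrix(noise1, "P_RF"),
            prob_matrix(noise2, "P_FFNN"),
            y,
        )
        assert acc == 1.0
        # brute-force oracle with the same lexicographic tie-break
        best = None
        for a, b, c in brute_force_grid(0.05):
            fused = a * perfect + b * noise1 + c * noise2
            pred = np.argmin(-fused, axis=1) + 1  # argmax, ties -> lowest class
            bf_acc = float((pred == y).mean())
            if best is None or bf_acc > best[1]:
                best = ((a, b, c), bf_acc)
        assert w.as_tuple() == best[0]
        assert acc == best[1]

    def test_selected_at_least_as_good_as_corners(self, rng):
        y = rng.integers(1, 4, size=30)
        mats = [prob_matrix(rng.dirichlet(np.ones(3), size=30), r)
                for r in ("P_SVM", "P_RF", "P_FFNN")]
        _, acc = grid_search_weights(*mats, y)
        for corner in ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
            fused = linear_fuse(*mats, FusionWeights(*corner))
            assert acc >= evaluate_accuracy(fused.predicted_labels(), y)

    def test_tie_break_lexicographic(self):
        y = np.array([1, 2])
        same = prob_matrix(np.eye(2))
        w, acc = grid_search_weights(
            same,
            prob_matrix(np.eye(2), "P_RF"),
            prob_matrix(np.eye(2), "P_FFNN"),
            y,
            step=0.5,
        )
        assert acc == 1.0
        assert w.as_tuple() == (0.0, 0.0, 1.0)  # first in enumeration order


class TestConcatProbabilities:
    def test_width_is_3k(self, rng):
        mats = [prob_matrix(rng.dirichlet(np.ones(5), size=4), r)
                for r in ("P_SVM", "P_RF", "P_FFNN")]
        pc = concat_probabilities(*mats)
        assert pc.values.shape == (4, 15)
        assert pc.role == "P_C"

    def test_blocks_split_back(self, rng):
        mats = [prob_matrix(rng.dirichlet(np.ones(3), size=6), r)
                for r in ("P_SVM", "P_RF", "P_FFNN")]
        pc = concat_probabilities(*mats)
        for b, m in enumerate(mats):
            block = pc.values[:, b * 3 : (b + 1) * 3]
            np.testing.assert_array_equal(block, m.values)
            np.testing.assert_allclose(block.sum(axis=1), 1.0)

    def test_sample_order_preserved(self, rng):
        mats = [prob_matrix(rng.dirichlet(np.ones(2), size=3), r)
                for r in ("P_SVM", "P_RF", "P_FFNN")]
        pc = concat_probabilities(*mats)
        assert pc.sample_ids == mats[0].sample_ids


class TestEvaluateAccuracy:
    def test_identical(self):
        assert evaluate_accuracy([1, 2, 3], [1, 2, 3]) == 1.0

    def test_complete_mismatch(self):
        assert evaluate_accuracy([1, 1], [2, 2]) == 0.0

    def test_nine_of_ten(self):
        pred = [1] * 9 + [2]
        truth = [1] * 10
        assert evaluate_accuracy(pred, truth) == 0.9

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            evaluate_accuracy([1], [1, 2])


class TestFeatureLevelFuse:
    def test_paper_widths_719_153(self, rng):
        f3 = make_omic(np.clip(rng.random((4, 719)), 0, 1), kind=OmicKind.F3_METHYLATION)
        f4 = make_omic(rng.normal(size=(4, 153)), kind=OmicKind.F4_PROTEIN)
        _, x, ids = feature_level_fuse([f4, f3])
        assert x.shape[1] == 872
        assert len(ids) == 872

    def test_paper_widths_672_719(self, rng):
        f1 = make_omic(rng.random((3, 672)), kind=OmicKind.F1_MRNA)
        f3 = make_omic(np.clip(rng.random((3, 719)), 0, 1), kind=OmicKind.F3_METHYLATION)
        _, x, _ = feature_level_fuse([f1, f3])
        assert x.shape[1] == 1391

    def test_single_block_identity(self, rng):
        a = make_omic(rng.normal(size=(5, 4)))
        sids, x, _ = feature_level_fuse([a])
        np.testing.assert_array_equal(x, a.values)
        assert sids == a.sample_ids

    def test_empty_intersection(self, rng):
        a = OmicMatrix(["A"], ["x"], rng.random((1, 1)), OmicKind.F1_MRNA)
        b = OmicMatrix(["B"], ["y"], rng.random((1, 1)), OmicKind.F4_PROTEIN)
        with pytest.raises(ValueError, match="intersection"):
            feature_level_fuse([a, b])


class TestTrainFused:
    def test_holdout_sizes_60_40(self):
        x, y = separable_data(n_per=50, n_classes=2, seed=1)
        model = train_fused(x, y, fast_spec(), mode="stacked_lr", holdout=True, seed=0)
        assert model.holdout
        # indirectly verified via split function used with fraction 0.4
        tr, te = split_train_test(x, y, 0.4, seed=0)
        assert len(tr) == 60 and len(te) == 40

    def test_perfect_l0_stacked_accuracy_one(self):
        x, y = separable_data(n_per=40, sep=10.0, seed=2)
        model = train_fused(x, y, fast_spec(), mode="stacked_lr", holdout=False, seed=0)
        assert evaluate_accuracy(model.predict(x), y) == 1.0

    def test_same_seed_same_model(self):
        x, y = separable_data(n_per=20, sep=3.0, seed=3)
        a = train_fused(x, y, fast_spec(), mode="linear", seed=5)
        b = train_fused(x, y, fast_spec(), mode="linear", seed=5)
        assert a.weights.as_tuple() == b.weights.as_tuple()
        np.testing.assert_array_equal(a.predict(x), b.predict(x))

    def test_stacked_holdout_agrees_when_l0_perfect(self):
        x, y = separable_data(n_per=50, sep=12.0, seed=4)
        with_h = train_fused(x, y, fast_spec(), mode="stacked_lr", holdout=True, seed=0)
        without = train_fused(x, y, fast_spec(), mode="stacked_lr", holdout=False, seed=0)
        np.testing.assert_array_equal(with_h.predict(x), without.predict(x))

    def test_linear_weights_on_simplex(self):
        x, y = separable_data(n_per=20, sep=2.0, seed=6)
        model = train_fused(x, y, fast_spec(), mode="linear", seed=0)
        w = model.weights.as_tuple()
        assert abs(sum(w) - 1.0) < 1e-9

    def test_unknown_mode_rejected(self):
        x, y = separable_data(n_per=10)
        with pytest.raises(ValueError, match="fusion mode"):
            train_fused(x, y, fast_spec(), mode="bogus", seed=0)


class TestPredictNew:
    def build_bundle(self, seed=0):
        x, y = separable_data(n_per=25, n_classes=2, d=6, seed=seed)
        model = train_fused(x, y, fast_spec(), mode="linear", seed=seed)
        variant = ModelVariant(
            name="F3_only",
            omic_kinds=[OmicKind.F3_METHYLATION],
            feature_ids={OmicKind.F3_METHYLATION: [f"f{j}" for j in range(6)]},
            minmax={},
            model=model,
        )
        bundle = ModelBundle()
        bundle.add(variant)
        return bundle, x, y

    def test_training_sample_label_stable(self):
        bundle, x, y = self.build_bundle()
        m = make_omic(np.clip(np.abs(x) / np.abs(x).max(), 0, 1),
                      kind=OmicKind.F3_METHYLATION)
        labels1, _ = bundle.predict_new({OmicKind.F3_METHYLATION: m})
        labels2, _ = bundle.predict_new({OmicKind.F3_METHYLATION: m})
        np.testing.assert_array_equal(labels1, labels2)

    def test_routing_to_single_omic_model(self):
        bundle, x, y = self.build_bundle()
        m = make_omic(np.clip(np.abs(x[:5]) / np.abs(x).max(), 0, 1),
                      kind=OmicKind.F3_METHYLATION)
        labels, proba = bundle.predict_new({OmicKind.F3_METHYLATION: m})
        assert len(labels) == 5
        assert proba.role == "P_L"

    def test_no_matching_schema_error(self):
        bundle, x, _ = self.build_bundle()
        m = make_omic(np.abs(x[:2]), kind=OmicKind.F1_MRNA)
        with pytest.raises(ValueError, match="no trained variant"):
            bundle.predict_new({OmicKind.F1_MRNA: m})

    def test_missing_feature_error(self):
        bundle, x, _ = self.build_bundle()
        m = make_omic(np.clip(np.abs(x[:2, :4]), 0, 1), kind=OmicKind.F3_METHYLATION)
        with pytest.raises(ValueError, match="schema mismatch"):
            bundle.predict_new({OmicKind.F3_METHYLATION: m})
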