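"""Linear SVM training contract, MCC/AUROC metrics and cross-validation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ensift import (
    ConfusionCounts,
    FeatureMatrix,
    compute_auroc,
    compute_mcc,
    cross_validate,
    train_linear_svm,
)
from ensift.screening_ml import DEFAULT_C_GRID

from ._oracles import auroc_pair_count, qp_dual_optimum


def _matrix(X, y):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return FeatureMatrix(X, np.asarray(y), [f"r{i}" for i in range(len(y))])


class TestTrainLinearSvm:
    def test_symmetric_pair_puts_boundary_at_zero(self):
        data = _matrix([-1.0, 1.0], [-1, 1])
        model = train_linear_svm(data, C=1e4)
        assert model.b == pytest.approx(0.0, abs=1e-6)
        assert list(model.predict(data.X)) == [-1, 1]

    @pytest.mark.parametrize("C", [0.1, 1.0, 10.0])
    def test_dual_objective_matches_enumeration_oracle(self, C):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(6, 2))
        y = np.array([1, 1, 1, -1, -1, -1])
        X[y == 1] += 1.0  # partially separable
        model = train_linear_svm(_matrix(X, y), C)
        achieved = model.dual_objective(X, y)
        optimum = qp_dual_optimum(X, y, C)
        assert achieved == pytest.approx(optimum, abs=1e-4)

    @pytest.mark.parametrize("seed", range(5))
    def test_dual_feasibility_on_random_data(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(30, 4))
        y = np.where(rng.random(30) < 0.5, 1, -1)
        y[:2] = [1, -1]  # both classes guaranteed
        C = 10.0
        model = train_linear_svm(_matrix(X, y), C)
        assert abs(model.support_alphas @ y) < 1e-6 * max(1, model.support_alphas.sum())
        assert (model.support_alphas >= -1e-9).all()
        assert (model.support_alphas <= C + 1e-9).all()
        # w is the support expansion Σ α_i y_i x_i
        np.testing.assert_allclose(
            model.w, (model.support_alphas * y) @ X, atol=1e-6
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            train_linear_svm(_matrix([1.0, 2.0], [1, 1]), C=1.0)

    def test_nonfinite_features_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            _matrix([np.nan, 1.0], [-1, 1])

    def test_training_mcc_reaches_one_on_separable_data_as_C_grows(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(-2, 0.3, (20, 3)), rng.normal(2, 0.3, (20, 3))])
        y = np.array([-1] * 20 + [1] * 20)
        model = train_linear_svm(_matrix(X, y), C=1e4)
        counts = ConfusionCounts.from_predictions(y, model.predict(X))
        assert compute_mcc(counts) == 1.0


class TestMcc:
    @pytest.mark.parametrize("counts,expected", [
        (ConfusionCounts(10, 10, 0, 0), 1.0),
        (ConfusionCounts(0, 0, 5, 5), -1.0),
        (ConfusionCounts(6, 4, 2, 3), 18 / np.sqrt(3024)),
        (ConfusionCounts(0, 10, 0, 0), 0.0),  # zero-denominator convention
    ])
    def test_printed_formula_values(self, counts, expected):
        assert compute_mcc(counts) == pytest.approx(expected, abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(*(st.integers(0, 50) for _ in range(4)))
    def test_class_swap_symmetry_and_prediction_inversion(self, tp, tn, fp, fn):
        mcc = compute_mcc(ConfusionCounts(tp, tn, fp, fn))
        swapped = compute_mcc(ConfusionCounts(tn, tp, fn, fp))
        inverted = compute_mcc(ConfusionCounts(fn, fp, tn, tp))
        assert mcc == pytest.approx(swapped, abs=1e-12)
        assert mcc == pytest.approx(-inverted, abs=1e-12)
        assert -1.0 <= mcc <= 1.0


class TestAuroc:
    @pytest.mark.parametrize("pos,neg,expected", [
        ([2, 3], [0, 1], 1.0),
        ([0.9, 0.4], [0.8, 0.1], 0.75),
        ([0.5], [0.5], 0.5),
        ([0, 1], [2, 3], 0.0),
    ])
    def test_enumerable_examples(self, pos, neg, expected):
        assert compute_auroc(pos, neg) == pytest.approx(expected)
        assert compute_auroc(pos, neg) == pytest.approx(auroc_pair_count(pos, neg))

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.integers(-5, 5), min_size=1, max_size=8),
        st.lists(st.integers(-5, 5), min_size=1, max_size=8),
    )
    def test_matches_pair_count_and_reversal(self, pos, neg):
        auroc = compute_auroc(pos, neg)
        assert auroc == pytest.approx(auroc_pair_count(pos, neg))
        reversed_auroc = compute_auroc([-p for p in pos], [-q for q in neg])
        assert reversed_auroc == pytest.approx(1.0 - auroc)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            compute_auroc([], [1.0])


def _separable_dataset(n_per_class=30, n_features=12, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([
        rng.normal(0.0, 0.05, (n_per_class, n_features)),
        rng.normal(1.0, 0.05, (n_per_class, n_features)),
    ])
    y = np.array([-1] * n_per_class + [1] * n_per_class)
    return _matrix(X, y)


class TestCrossValidate:
    def test_separable_data_scores_perfect_mcc_for_large_C(self):
        result = cross_validate(_separable_dataset(), k_folds=10, seed=0)
        assert result.pooled_mcc == 1.0
        for C, mcc in result.per_C_results.items():
            if C >= 1:
                assert mcc == 1.0

    def test_default_grid_has_seven_entries(self):
        result = cross_validate(_separable_dataset(), k_folds=5, seed=1)
        assert len(result.per_C_results) == 7
        assert tuple(result.per_C_results) == DEFAULT_C_GRID

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(60, 10))
        X[30:] += 0.6
        y = np.array([-1] * 30 + [1] * 30)
        a = cross_validate(_matrix(X, y), k_folds=10, seed=42)
        b = cross_validate(_matrix(X, y), k_folds=10, seed=42)
        assert a.per_C_results == b.per_C_results
        assert a.best_C == b.best_C and a.pooled_mcc == b.pooled_mcc
        assert a.pooled_auroc == b.pooled_auroc

    def test_ties_resolve_to_smaller_C(self):
        result = cross_validate(_separable_dataset(), k_folds=5, seed=0)
        perfect = [C for C, mcc in result.per_C_results.items()
                   if mcc == result.pooled_mcc]
        assert result.best_C == min(perfect)

    def test_class_too_small_for_stratification(self):
        data = _matrix(np.arange(8.0), [1, 1, 1, 1, -1, -1, -1, -1])
        with pytest.raises(ValueError, match="stratification impossible"):
            cross_validate(data, k_folds=5, seed=0)

    def test_grouped_instances_stay_in_one_fold(self):
        # 20 parents, 2 instances each: folds must never split a parent
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 4))
        y = np.repeat(np.array([1, -1] * 10), 2)
        ids = [f"p{i // 2}_inst{i % 2}" for i in range(40)]
        groups = [f"p{i // 2}" for i in range(40)]
        data = FeatureMatrix(X, y, ids, groups)
        from ensift.screening_ml import _make_folds
        for _, test_idx in _make_folds(data, 5, seed=0):
            held_out_groups = {groups[i] for i in test_idx}
            all_members = [i for i in range(40) if groups[i] in held_out_groups]
            assert sorted(all_members) == sorted(test_idx)
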