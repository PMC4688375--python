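"""Dataset assembly, scaling, the max-margin classifier, LOROCV, permutation test."""

import numpy as np
import pytest

from scandecode.mvpa import (
    EmptyDatasetError,
    FeatureScaler,
    LabeledScanSet,
    SvmConfig,
    assemble_dataset,
    balanced_block_permutation_test,
    evaluate_classifier,
    load_classifier,
    loro_cv,
    minmax_scale,
    save_classifier,
    train_classifier,
)
from scandecode.preprocess import preprocess_day
from scandecode.synthsim import ExperimentProtocol, simulate_experiment
from conftest import NOISELESS


class TestAssembleDataset:
    def test_full_acknowledgement_gives_384_per_class(self, preprocessed_day1, truth):
        ds = assemble_dataset(preprocessed_day1, truth.brain_mask)
        assert (ds.y == 1).sum() == 384
        assert (ds.y == -1).sum() == 384

    def test_screening_drops_block_and_counterpart(self, truth):
        proto = ExperimentProtocol(missed_acknowledgements=(("day1", 2, (0,)),))
        exp = simulate_experiment(proto, truth, seed=11)
        day1 = preprocess_day(exp.day1, truth.brain_mask)
        ds = assemble_dataset(day1, truth.brain_mask)
        # one task-A block unacknowledged: 16 + 16 scans leave (block + same-ordinal partner)
        assert (ds.y == 1).sum() == 368
        assert (ds.y == -1).sum() == 368

    def test_blocks_are_label_pure(self, preprocessed_day1, truth):
        ds = assemble_dataset(preprocessed_day1, truth.brain_mask)
        for b in np.unique(ds.block_id):
            sel = ds.block_id == b
            assert len(np.unique(ds.y[sel])) == 1
            assert len(np.unique(ds.run_id[sel])) == 1

    def test_all_blocks_unacknowledged_rejected(self, truth):
        proto = ExperimentProtocol(
            n_day1_runs=1, n_day2_alt_runs=0, n_day2_binary_runs=0,
            missed_acknowledgements=(("day1", 0, (0, 1, 2, 3, 4, 5)),),
        )
        exp = simulate_experiment(proto, truth, seed=0)
        day1 = preprocess_day(exp.day1, truth.brain_mask)
        with pytest.raises(EmptyDatasetError):
            assemble_dataset(day1, truth.brain_mask)


class TestMinmaxScale:
    def test_affine_map_examples(self):
        train = np.array([[2.0], [6.0]])
        test = np.array([[4.0], [8.0]])
        tr, te, scaler = minmax_scale(train, test)
        np.testing.assert_allclose(tr.ravel(), [-1.0, 1.0])
        assert te[0, 0] == pytest.approx(0.0)
        assert te[1, 0] == pytest.approx(2.0)  # out of range, no clipping

    def test_constant_feature_maps_to_zero(self):
        train = np.full((4, 2), 3.0)
        train[:, 1] = [0, 1, 2, 3]
        test = np.array([[9.0, 1.5]])
        tr, te, _ = minmax_scale(train, test)
        assert np.all(tr[:, 0] == 0.0)
        assert te[0, 0] == 0.0


def toy_qp_oracle(X, y, C=1.0, grid=151, span=3.0):
    """Brute-force primal search of the soft-margin objective on a 2-D grid.

    min 0.5 ||w||^2 + C sum max(0, 1 - y (w.x + b)) over w in R^2, b in R.
    """
    best, best_obj = None, np.inf
    ws = np.linspace(-span, span, grid)
    bs = np.linspace(-span, span, 31)
    for w1 in ws:
        for w2 in ws:
            w = np.array([w1, w2])
            margins = 1 - y * (X @ w[:, None]).ravel()
            for b in bs:
                hinge = np.maximum(0.0, margins - y * b).sum()
                obj = 0.5 * w @ w + C * hinge
                if obj < best_obj:
                    best_obj, best = obj, (w.copy(), b)
    return best, best_obj


class TestTrainClassifier:
    def test_separable_pair(self):
        ds = LabeledScanSet(
            X=np.array([[1.0], [-1.0]]), y=np.array([1, -1]),
            block_id=np.array([0, 1]), run_id=np.array([1, 2]),
        )
        clf = train_classifier(ds)
        assert clf.decision_values(np.array([[1.0]]))[0] > 0
        assert clf.decision_values(np.array([[-1.0]]))[0] < 0

    def test_symmetric_toy_matches_qp_oracle(self):
        # 4 symmetric points: optimum w is along the class-mean difference
        X = np.array([[1.0, 1.0], [1.0, -1.0], [-1.0, 1.0], [-1.0, -1.0]])
        y = np.array([1, 1, -1, -1])
        ds = LabeledScanSet(X, y, np.arange(4), np.arange(4))
        clf = train_classifier(ds)  # scaler is identity here: data already spans [-1, 1]
        (w_o, b_o), obj_o = toy_qp_oracle(X, y)
        obj = 0.5 * clf.w @ clf.w + np.maximum(
            0, 1 - y * (X @ clf.w + clf.b)
        ).sum()
        assert obj == pytest.approx(obj_o, abs=1e-4 + 0.05 * obj_o)
        # direction parallel to the class-mean difference (x-axis)
        assert abs(clf.w[1]) < 1e-6
        assert clf.w[0] > 0

    def test_label_flip_negates_solution(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(1, 1, (10, 3)), rng.normal(-1, 1, (10, 3))])
        y = np.r_[np.ones(10, int), -np.ones(10, int)]
        ds1 = LabeledScanSet(X, y, np.arange(20), np.arange(20))
        ds2 = LabeledScanSet(X, -y, np.arange(20), np.arange(20))
        cfg = SvmConfig(tolerance=1e-6)
        c1, c2 = train_classifier(ds1, cfg), train_classifier(ds2, cfg)
        np.testing.assert_allclose(c1.w, -c2.w, atol=1e-6)
        assert c1.b == pytest.approx(-c2.b, abs=1e-6)

    def test_single_class_rejected(self):
        ds = LabeledScanSet(
            np.zeros((2, 1)), np.array([1, -1]), np.arange(2), np.arange(2)
        )
        ds.y = np.array([1, 1])  # bypass balance check to hit the training guard
        with pytest.raises(ValueError, match="both classes"):
            train_classifier(ds)


class TestLoroCv:
    def test_separable_classes_give_perfect_pooled_accuracy(self):
        # distinct class patterns with a margin much wider than the spread
        rng = np.random.default_rng(0)
        n_per, runs = 12, 4
        X, y, block, run = [], [], [], []
        for r in range(1, runs + 1):
            for label, mu in ((1, 5.0), (-1, -5.0)):
                X.append(rng.normal(mu, 0.1, size=(n_per, 6)))
                y += [label] * n_per
                block += [2 * r + (label == 1)] * n_per
                run += [r] * n_per
        ds = LabeledScanSet(np.vstack(X), np.array(y), np.array(block), np.array(run))
        assert loro_cv(ds).pooled_accuracy == 1.0

    def test_pooled_equals_scan_weighted_mean(self, preprocessed_day1, truth):
        ds = assemble_dataset(preprocessed_day1[:3], truth.brain_mask)
        res = loro_cv(ds)
        weighted = np.average(res.fold_accuracies, weights=res.fold_n_scans)
        assert res.pooled_accuracy == pytest.approx(weighted, abs=1e-12)

    def test_single_run_rejected(self, preprocessed_day1, truth):
        ds = assemble_dataset(preprocessed_day1[:1], truth.brain_mask)
        with pytest.raises(ValueError, match="two distinct runs"):
            loro_cv(ds)


@pytest.fixture(scope="module")
def small_setup(truth):
    exp = simulate_experiment(
        ExperimentProtocol(n_day1_runs=2, n_day2_alt_runs=1, n_day2_binary_runs=0),
        truth, seed=21,
    )
    pre = preprocess_day(exp.day1 + exp.day2_alt, truth.brain_mask)
    ds = assemble_dataset(pre[:2], truth.brain_mask)
    ev = assemble_dataset(pre[2:], truth.brain_mask)
    return ds, ev


class TestPermutationTest:
    def test_identity_permutation_matches_observed(self, small_setup):
        ds, ev = small_setup
        res = balanced_block_permutation_test(
            ds, n_permutations=5, seed=0, eval_X=ev.X, eval_y=ev.y
        )
        clf = train_classifier(ds)
        assert res.observed_accuracy == pytest.approx(
            evaluate_classifier(clf, ev.X, ev.y), abs=0.02
        )

    def test_p_value_lower_bound(self, small_setup):
        ds, ev = small_setup
        res = balanced_block_permutation_test(
            ds, n_permutations=10, seed=1, eval_X=ev.X, eval_y=ev.y
        )
        assert res.p_value >= 1.0 / 11.0
        assert res.p_value <= 1.0

    def test_deterministic_given_seed(self, small_setup):
        ds, ev = small_setup
        r1 = balanced_block_permutation_test(ds, n_permutations=8, seed=3, eval_X=ev.X, eval_y=ev.y)
        r2 = balanced_block_permutation_test(ds, n_permutations=8, seed=3, eval_X=ev.X, eval_y=ev.y)
        np.testing.assert_array_equal(r1.null_accuracies, r2.null_accuracies)
        assert r1.p_value == r2.p_value

    def test_permutation_preserves_run_balance(self, small_setup):
        from scandecode.mvpa import _permute_block_labels

        ds, _ = small_setup
        rng = np.random.default_rng(0)
        for _ in range(20):
            y_new = _permute_block_labels(ds.y, ds.block_id, ds.run_id, rng)
            for rid in np.unique(ds.run_id):
                sel = ds.run_id == rid
                assert (y_new[sel] == 1).sum() == (ds.y[sel] == 1).sum()

    def test_invalid_iteration_count_rejected(self, small_setup):
        ds, ev = small_setup
        with pytest.raises(ValueError):
            balanced_block_permutation_test(ds, n_permutations=0, eval_X=ev.X, eval_y=ev.y)


class TestNoLeakage:
    def test_training_artifacts_ignore_heldout_mutation(self, truth):
        exp = simulate_experiment(
            ExperimentProtocol(n_day1_runs=2, n_day2_alt_runs=0, n_day2_binary_runs=1),
            truth, seed=31,
        )
        day1 = preprocess_day(exp.day1, truth.brain_mask)
        ds = assemble_dataset(day1, truth.brain_mask)
        clf1 = train_classifier(ds)
        # mutating held-out day-2 scans must not change any training artifact
        exp.day2_binary[0].data *= 100.0
        clf2 = train_classifier(assemble_dataset(day1, truth.brain_mask))
        np.testing.assert_array_equal(clf1.w, clf2.w)
        np.testing.assert_array_equal(clf1.scaler.minimum, clf2.scaler.minimum)


class TestSerialization:
    def test_round_trip(self, tmp_path, preprocessed_day1, truth):
        ds = assemble_dataset(preprocessed_day1[:2], truth.brain_mask)
        clf = train_classifier(ds, feature_mask=truth.brain_mask)
        path = tmp_path / "model.json"
        save_classifier(clf, path)
        back = load_classifier(path)
        np.testing.assert_allclose(back.w, clf.w)
        assert back.b == clf.b
        np.testing.assert_array_equal(back.feature_mask, clf.feature_mask)
        np.testing.assert_allclose(
            back.decision_values(ds.X[:5]), clf.decision_values(ds.X[:5])
        )
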