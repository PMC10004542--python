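"""Dataset splits, the three classifiers, and confusion-matrix bookkeeping."""

import numpy as np
import pytest

from discmotion.classify import (
    ConfusionMatrix,
    DatasetSplit,
    SplitError,
    confusion_from_predictions,
    evaluate,
    make_split,
    train_cnn3d,
    train_mlp,
    train_mslr,
)
from discmotion.cnn3d import CNN3DConfig, Conv3DNet
from discmotion.core import LABELS


def _gaussian_blobs(rng, n_per_class, d, sep):
    """Two spherical Gaussian classes separated by ``sep`` along one axis."""
    X0 = rng.normal(size=(n_per_class, d))
    X1 = rng.normal(size=(n_per_class, d))
    X1[:, 0] += sep
    X = np.vstack([X0, X1])
    y = np.array(["happy"] * n_per_class + ["sad"] * n_per_class)
    return X, y


class TestMakeSplit:
    def test_default_cohort_split_frame_counts(self, strong_sessions):
        """7 train + 3 test participants with 230 frames each."""
        pids = sorted(strong_sessions)
        split = make_split(strong_sessions, pids[:7], pids[7:])
        assert len(split.y_train) == 7 * 230 == 1610
        assert len(split.y_test) == 3 * 230 == 690
        counts = split.label_counts()
        assert counts["test"] == {"neutral": 90, "happy": 300, "sad": 300}

    def test_one_vs_one_split(self, strong_sessions):
        pids = sorted(strong_sessions)
        split = make_split(strong_sessions, [pids[0]], [pids[1]])
        assert len(split.y_train) == len(split.y_test) == 230

    def test_overlapping_ids_rejected(self, strong_sessions):
        pids = sorted(strong_sessions)
        with pytest.raises(SplitError, match="both train and test"):
            make_split(strong_sessions, pids[:3], pids[2:5])

    def test_empty_test_set_rejected(self, strong_sessions):
        with pytest.raises(SplitError):
            make_split(strong_sessions, sorted(strong_sessions), [])

    def test_split_hash_changes_when_a_participant_moves(self, strong_sessions):
        pids = sorted(strong_sessions)
        a = make_split(strong_sessions, pids[:7], pids[7:])
        b = make_split(strong_sessions, pids[:6], pids[6:])
        assert a.split_hash != b.split_hash

    def test_stack_row_sums_match_per_class_counts(self, strong_sessions):
        pids = sorted(strong_sessions)
        split = make_split(strong_sessions, pids[:7], pids[7:], stack_depth=3)
        # per block: first (depth-1) frames lack history
        # 3 test participants x 5 blocks x 2 dropped frames
        assert len(split.sy_test) == 690 - 3 * 5 * 2
        for lbl in LABELS:
            assert np.sum(split.sy_test == lbl) > 0


class TestMSLR:
    def test_separable_toy_reaches_99_percent(self):
        rng = np.random.default_rng(60)
        X, y = _gaussian_blobs(rng, 200, 10, sep=12.0)
        split = DatasetSplit.from_arrays(X, y, X, y)
        model = train_mslr(split, l1_strength=1.0, seed=0)
        assert (model.predict(X) == y).mean() >= 0.99
        assert model.info["n_nonzero_coef"] >= 1

    def test_extreme_penalty_zeroes_all_coefficients(self):
        rng = np.random.default_rng(61)
        X, y = _gaussian_blobs(rng, 100, 8, sep=6.0)
        split = DatasetSplit.from_arrays(X, y, X, y)
        model = train_mslr(split, l1_strength=1e-6, seed=0)
        assert model.info["n_nonzero_coef"] == 0

    def test_shuffled_labels_give_chance_level(self):
        rng = np.random.default_rng(62)
        X = rng.normal(size=(600, 10))
        y = np.array(list(LABELS) * 200)  # balanced three classes, no signal
        Xt = rng.normal(size=(300, 10))
        yt = np.array(list(LABELS) * 100)
        split = DatasetSplit.from_arrays(X, y, Xt, yt)
        model = train_mslr(split, l1_strength=1.0, seed=0)
        cm = evaluate(model, split)
        assert abs(cm.accuracy - 1 / 3) < 0.12

    def test_single_class_training_rejected(self):
        rng = np.random.default_rng(63)
        X = rng.normal(size=(20, 4))
        y = np.array(["happy"] * 20)
        split = DatasetSplit.from_arrays(X, y, X, y)
        with pytest.raises(ValueError, match="two classes"):
            train_mslr(split, l1_strength=1.0)


class TestMLP:
    def test_xor_labels_separate_mlp_from_linear_model(self):
        """The classic nonlinear construction: an MLP solves XOR-style labels
        that a linear (logistic) model cannot."""
        rng = np.random.default_rng(64)
        n = 250
        X = np.vstack(
            [
                rng.normal((s1 * 3, s2 * 3), 0.6, size=(n, 2))
                for s1, s2 in ((1, 1), (-1, -1), (1, -1), (-1, 1))
            ]
        )
        y = np.array(["happy"] * (2 * n) + ["sad"] * (2 * n))
        perm = rng.permutation(len(y))
        X, y = X[perm], y[perm]
        Xt, yt = X[:200], y[:200]
        split = DatasetSplit.from_arrays(X[200:], y[200:], Xt, yt)
        mlp = train_mlp(split, seed=0)
        mslr = train_mslr(split, l1_strength=1.0, seed=0)
        assert (mlp.predict(Xt) == yt).mean() >= 0.95
        assert (mslr.predict(Xt) == yt).mean() <= 0.60

    def test_fixed_seed_is_reproducible(self):
        rng = np.random.default_rng(65)
        X, y = _gaussian_blobs(rng, 150, 6, sep=3.0)
        split = DatasetSplit.from_arrays(X, y, X, y)
        p1 = train_mlp(split, seed=7).predict(X)
        p2 = train_mlp(split, seed=7).predict(X)
        assert np.array_equal(p1, p2)


@pytest.fixture(scope="module")
def stack_problem():
    rng = np.random.default_rng(66)
    X = rng.normal(size=(450, 1, 3, 8, 8))
    y = rng.integers(0, 3, 450)
    mouth = np.zeros((3, 8, 8))
    mouth[:, 6, 1:3] = 4.0
    brow = np.zeros((3, 8, 8))
    brow[:, 1, 3:5] = 4.0
    X[y == 1] += mouth
    X[y == 2] += brow
    return X, y


class TestCNN3D:
    def test_learns_localized_patterns(self, stack_problem):
        X, y = stack_problem
        net = Conv3DNet(CNN3DConfig(epochs=20, seed=1)).fit(X[:350], y[:350])
        assert (net.predict(X[350:]) == y[350:]).mean() >= 0.95

    def test_seeded_double_run_identical(self, stack_problem):
        X, y = stack_problem
        cfg = CNN3DConfig(epochs=5, seed=3)
        p1 = Conv3DNet(cfg).fit(X[:200], y[:200]).predict(X[200:])
        p2 = Conv3DNet(cfg).fit(X[:200], y[:200]).predict(X[200:])
        assert np.array_equal(p1, p2)

    def test_constant_input_collapses_to_priors(self):
        rng = np.random.default_rng(67)
        X = np.ones((120, 1, 3, 6, 6))
        y = np.array([0] * 80 + [1] * 30 + [2] * 10)
        net = Conv3DNet(CNN3DConfig(epochs=10, seed=2)).fit(X, y)
        pred = net.predict(X)
        assert np.all(pred == 0)  # majority class: constant input carries no signal

    def test_categorical_loss_option(self, stack_problem):
        X, y = stack_problem
        net = Conv3DNet(CNN3DConfig(epochs=15, seed=4, loss="ce")).fit(X[:350], y[:350])
        proba = net.predict_proba(X[350:])
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert (net.predict(X[350:]) == y[350:]).mean() >= 0.9


class TestConfusionMatrix:
    def test_perfect_predictor_gives_identity_percentages(self):
        y = np.array(["neutral"] * 30 + ["happy"] * 100 + ["sad"] * 100)
        cm = confusion_from_predictions(y, y)
        assert np.allclose(cm.percentages, np.eye(3) * 100.0)
        assert cm.accuracy == 1.0

    def test_majority_predictor_fills_one_column(self):
        y_true = np.array(["neutral"] * 30 + ["happy"] * 100 + ["sad"] * 100)
        y_pred = np.array(["happy"] * 230)
        cm = confusion_from_predictions(y_true, y_pred)
        assert np.all(cm.percentages[:, 1] == 100.0)
        assert cm.balanced_accuracy == pytest.approx(1 / 3)

    def test_random_predictor_diagonal_near_one_third(self):
        rng = np.random.default_rng(68)
        y_true = np.array(["neutral"] * 90 + ["happy"] * 300 + ["sad"] * 300)
        y_pred = rng.choice(LABELS, size=690)
        cm = confusion_from_predictions(y_true, y_pred)
        assert np.all(np.abs(cm.per_class_accuracy - 1 / 3) < 0.17)

    def test_row_sums_equal_per_class_counts_and_percent_rows_100(self):
        rng = np.random.default_rng(69)
        y_true = rng.choice(LABELS, size=200)
        y_pred = rng.choice(LABELS, size=200)
        cm = confusion_from_predictions(y_true, y_pred)
        for i, lbl in enumerate(LABELS):
            assert cm.counts[i].sum() == np.sum(y_true == lbl)
        rows = cm.percentages.sum(axis=1)
        present = cm.counts.sum(axis=1) > 0
        assert np.allclose(rows[present], 100.0, atol=0.1)
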