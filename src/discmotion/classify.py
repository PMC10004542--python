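"""Emotion classifiers over DISC features with leave-participants-out splits.

Three model families consume the displacement output in two forms:

* **MSLR** — multinomial logistic regression with an l1 penalty (sparse
  feature selection) on flattened per-frame displacement vectors;
* **MLP** — a feed-forward multi-layer perceptron on the same vectors;
* **3-D CNN** — a small convolutional network on stacks of ``k`` adjacent
  displacement-magnitude lattices, capturing spatial structure within a
  heatmap and temporal structure across neighboring frames.

Splits are made at the participant level (no individual contributes frames to
both train and test), the out-of-sample predictions are tallied into a 3x3
confusion matrix (true emotions on rows, predictions on columns), and each
row is also expressed as percentages summing to 100.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, GroupKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .cnn3d import CNN3DConfig, Conv3DNet
from .core import LABELS
from .embedding import flatten_field
from .session import Session

logger = logging.getLogger(__name__)

DEFAULT_SEED = 20230310


class SplitError(ValueError):
    """Train and test participant sets overlap or are empty."""


@dataclass
class DatasetSplit:
    """Participant-disjoint train/test features in vector and stack form.

    ``X_*`` are flattened (u, v) vectors, one row per frame; ``S_*`` are
    (N, 1, k, nx, ny) stacks of adjacent displacement-magnitude lattices for
    the 3-D network, built within blocks only (``n_dropped_stacks`` frames at
    block edges lack enough history and are dropped).  Labels are strings
    from ``LABELS``; ``groups_train`` carries the participant of each train
    row for grouped cross-validation.
    """

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    X_train: np.ndarray
    y_train: np.ndarray
    groups_train: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray
    S_train: np.ndarray | None = None
    sy_train: np.ndarray | None = None
    S_test: np.ndarray | None = None
    sy_test: np.ndarray | None = None
    n_dropped_stacks: int = 0

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise SplitError(f"participants in both train and test: {sorted(overlap)}")
        if len(self.train_ids) == 0 or len(self.X_train) == 0:
            raise SplitError("empty training set")
        if len(self.test_ids) == 0 or len(self.X_test) == 0:
            raise SplitError("empty test set")

    @property
    def split_hash(self) -> str:
        """Digest of the participant assignment; changes if any id moves."""
        payload = "train:" + ",".join(sorted(self.train_ids))
        payload += "|test:" + ",".join(sorted(self.test_ids))
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def label_counts(self) -> dict[str, dict[str, int]]:
        out = {}
        for name, y in (("train", self.y_train), ("test", self.y_test)):
            out[name] = {lbl: int(np.sum(y == lbl)) for lbl in LABELS}
        return out

    @classmethod
    def from_arrays(
        cls,
        X_train: np.ndarray,
        y_train: np.ndarray,
        X_test: np.ndarray,
        y_test: np.ndarray,
        groups_train: np.ndarray | None = None,
    ) -> "DatasetSplit":
        """Build a split directly from feature arrays (toy/benchmark use)."""
        if groups_train is None:
            groups_train = np.zeros(len(X_train), dtype=int)
        return cls(
            train_ids=("train",),
            test_ids=("test",),
            X_train=np.asarray(X_train),
            y_train=np.asarray(y_train),
            groups_train=np.asarray(groups_train),
            X_test=np.asarray(X_test),
            y_test=np.asarray(y_test),
        )


def _session_stacks(session: Session, k: int) -> tuple[np.ndarray, np.ndarray, int]:
    """(stacks, labels, n_dropped) of k adjacent magnitude lattices per frame.

    A stack for frame position i uses frames i-k+1 .. i of the same block;
    positions with fewer than k-1 in-block predecessors are dropped.
    """
    stacks = []
    labels = []
    dropped = 0
    positions = sorted(session.fields)
    for i in positions:
        b = session.block_ids[i]
        window = [j for j in range(i - k + 1, i + 1)]
        if any(j not in session.fields or session.block_ids[j] != b for j in window):
            dropped += 1
            continue
        mags = [np.nan_to_num(session.fields[j].magnitude, nan=0.0) for j in window]
        stacks.append(np.stack(mags)[None])  # (1, k, nx, ny)
        labels.append(session.frames[i].label)
    if not stacks:
        return np.empty((0, 1, k, 0, 0)), np.asarray(labels), dropped
    return np.stack(stacks), np.asarray(labels), dropped


def make_split(
    sessions: Mapping[str, Session],
    train_ids: Sequence[str],
    test_ids: Sequence[str],
    stack_depth: int = 3,
) -> DatasetSplit:
    """Assemble a leave-participants-out split from computed sessions.

    Features are built deterministically in (participant, frame) order; per
    label frame counts are logged.  Raises :class:`SplitError` on overlapping
    or missing ids and on an empty test set.
    """
    overlap = set(train_ids) & set(test_ids)
    if overlap:
        raise SplitError(f"participants in both train and test: {sorted(overlap)}")
    for pid in list(train_ids) + list(test_ids):
        if pid not in sessions:
            raise SplitError(f"unknown participant id {pid!r}")

    def collect(ids: Sequence[str]):
        X, y, groups = [], [], []
        S, sy = [], []
        dropped = 0
        for pid in ids:
            sess = sessions[pid]
            for i in sorted(sess.fields):
                X.append(flatten_field(sess.fields[i]))
                y.append(sess.frames[i].label)
                groups.append(pid)
            st, sl, dr = _session_stacks(sess, stack_depth)
            if len(st):
                S.append(st)
                sy.append(sl)
            dropped += dr
        Xa = np.asarray(X)
        return (
            Xa,
            np.asarray(y),
            np.asarray(groups),
            np.concatenate(S) if S else None,
            np.concatenate(sy) if sy else None,
            dropped,
        )

    Xtr, ytr, gtr, Str, sytr, dtr = collect(list(train_ids))
    Xte, yte, _, Ste, syte, dte = collect(list(test_ids))
    split = DatasetSplit(
        train_ids=tuple(train_ids),
        test_ids=tuple(test_ids),
        X_train=Xtr,
        y_train=ytr,
        groups_train=gtr,
        X_test=Xte,
        y_test=yte,
        S_train=Str,
        sy_train=sytr,
        S_test=Ste,
        sy_test=syte,
        n_dropped_stacks=dtr + dte,
    )
    logger.info(
        "split %s: %d train / %d test frames, %d stack samples dropped at block edges",
        split.split_hash,
        len(ytr),
        len(yte),
        split.n_dropped_stacks,
    )
    return split


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------


@dataclass
class TrainedModel:
    """A fitted classifier plus training diagnostics."""

    kind: str
    model: object
    info: dict = field(default_factory=dict)
    uses_stacks: bool = False

    def predict(self, X: np.ndarray) -> np.ndarray:
        pred = self.model.predict(X)
        if self.kind == "cnn3d":
            return np.asarray(LABELS)[pred]
        return pred


def train_mslr(
    split: DatasetSplit,
    l1_strength: float | None = None,
    seed: int = DEFAULT_SEED,
    max_iter: int = 3000,
) -> TrainedModel:
    """Multiclass sparse logistic regression (l1-penalized, saga solver).

    When ``l1_strength`` (the inverse regularization C) is not given it is
    chosen by grid search with participant-grouped folds over the training
    set only.  Non-convergence is surfaced as a warning with iteration
    diagnostics; the nonzero-coefficient count is reported in ``info``.
    """
    if len(np.unique(split.y_train)) < 2:
        raise ValueError("training data must contain at least two classes")

    def make(C: float) -> Pipeline:
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "mslr",
                    LogisticRegression(
                        l1_ratio=1.0,  # pure l1 penalty (sparse coefficients)
                        C=C,
                        solver="saga",
                        max_iter=max_iter,
                        tol=1e-3,
                        random_state=seed,
                    ),
                ),
            ]
        )

    info: dict = {}
    if l1_strength is None:
        n_groups = len(np.unique(split.groups_train))
        if n_groups >= 2:
            grid = GridSearchCV(
                make(1.0),
                {"mslr__C": [0.1, 1.0, 10.0]},
                cv=GroupKFold(n_splits=min(3, n_groups)),
                n_jobs=None,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                grid.fit(split.X_train, split.y_train, groups=split.groups_train)
            l1_strength = float(grid.best_params_["mslr__C"])
            info["cv_best_C"] = l1_strength
        else:
            l1_strength = 1.0
    pipe = make(l1_strength)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        pipe.fit(split.X_train, split.y_train)
    clf: LogisticRegression = pipe.named_steps["mslr"]
    if any(issubclass(w.category, ConvergenceWarning) for w in caught):
        logger.warning(
            "MSLR did not converge in %d iterations (n_iter_=%s); results kept "
            "but inspect info['converged']",
            max_iter,
            clf.n_iter_,
        )
    info.update(
        C=l1_strength,
        n_nonzero_coef=int(np.sum(clf.coef_ != 0.0)),
        n_iter=int(np.max(clf.n_iter_)),
        converged=bool(np.max(clf.n_iter_) < max_iter),
    )
    return TrainedModel("mslr", pipe, info)


def train_mlp(
    split: DatasetSplit,
    hidden_layer_sizes: tuple[int, ...] = (128, 64),
    seed: int = DEFAULT_SEED,
    max_iter: int = 400,
) -> TrainedModel:
    """Feed-forward MLP with rectifier activations and early stopping.

    Early stopping monitors a 10% validation split carved from the training
    data; a fixed seed makes training reproducible run-to-run.
    """
    if len(np.unique(split.y_train)) < 2:
        raise ValueError("training data must contain at least two classes")
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "mlp",
                MLPClassifier(
                    hidden_layer_sizes=hidden_layer_sizes,
                    early_stopping=True,
                    validation_fraction=0.1,
                    max_iter=max_iter,
                    random_state=seed,
                ),
            ),
        ]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        pipe.fit(split.X_train, split.y_train)
    mlp: MLPClassifier = pipe.named_steps["mlp"]
    info = {"n_iter": int(mlp.n_iter_), "best_validation_score": float(mlp.best_validation_score_)}
    return TrainedModel("mlp", pipe, info)


def train_cnn3d(
    split: DatasetSplit,
    config: CNN3DConfig | None = None,
    seed: int | None = None,
) -> TrainedModel:
    """The 3-D convolutional classifier on heatmap-lattice stacks."""
    if split.S_train is None or split.sy_train is None:
        raise ValueError("split carries no stack features; rebuild with make_split")
    cfg = config or CNN3DConfig()
    if seed is not None:
        cfg = CNN3DConfig(**{**cfg.__dict__, "seed": seed})
    label_to_idx = {lbl: i for i, lbl in enumerate(LABELS)}
    y_idx = np.asarray([label_to_idx[lbl] for lbl in split.sy_train])
    net = Conv3DNet(cfg, n_classes=len(LABELS))
    net.fit(split.S_train, y_idx)
    info = {"final_loss": float(net.loss_history_[-1]), "epochs": cfg.epochs,
            "n_train_stacks": len(split.S_train)}
    return TrainedModel("cnn3d", net, info, uses_stacks=True)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionMatrix:
    """3x3 counts with true labels on rows and predictions on columns."""

    counts: np.ndarray
    labels: tuple[str, ...] = LABELS

    @property
    def percentages(self) -> np.ndarray:
        """Row-normalized view; each row sums to 100 (empty rows stay 0)."""
        sums = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * self.counts / sums
        return np.nan_to_num(pct, nan=0.0)

    @property
    def accuracy(self) -> float:
        total = self.counts.sum()
        return float(np.trace(self.counts) / total) if total else 0.0

    @property
    def per_class_accuracy(self) -> np.ndarray:
        """Diagonal of the row-normalized matrix, as fractions (recall)."""
        return np.diag(self.percentages) / 100.0

    @property
    def balanced_accuracy(self) -> float:
        """Mean per-class accuracy over non-empty classes; chance level 1/3."""
        present = self.counts.sum(axis=1) > 0
        return float(self.per_class_accuracy[present].mean())


def confusion_from_predictions(
    y_true: Sequence[str], y_pred: Sequence[str]
) -> ConfusionMatrix:
    idx = {lbl: i for i, lbl in enumerate(LABELS)}
    counts = np.zeros((len(LABELS), len(LABELS)), dtype=int)
    for t, p in zip(y_true, y_pred):
        counts[idx[t], idx[p]] += 1
    return ConfusionMatrix(counts)


def evaluate(model: TrainedModel, split: DatasetSplit) -> ConfusionMatrix:
    """Out-of-sample confusion matrix of a trained model on the split's test set."""
    if model.uses_stacks:
        if split.S_test is None or not len(split.S_test):
            raise ValueError("split carries no test stacks")
        y_true = split.sy_test
        y_pred = model.predict(split.S_test)
    else:
        y_true = split.y_test
        y_pred = model.predict(split.X_test)
    empty = [lbl for lbl in LABELS if not np.any(np.asarray(y_true) == lbl)]
    if empty:
        logger.warning("test set has no frames for classes: %s", empty)
    return confusion_from_predictions(y_true, y_pred)
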