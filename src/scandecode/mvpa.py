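"""Balanced scan sets, the linear max-margin classifier, and the permutation test.

Training scans come from the hemodynamically shifted task-block windows
of the alternating runs. Balance is enforced by a strict screening
rule: if a block's start cue went unacknowledged, that block AND its
same-ordinal counterpart block of the other task in the same run are
both dropped, so class counts stay equal by construction.

The classifier is the standard L2-regularized hinge-loss soft-margin
linear SVM with C = 1 (LIBSVM, via scikit-learn); features are min-max
scaled to [-1, 1] with parameters fitted on training data only.
Significance of held-out accuracy is assessed with a balanced-block
permutation test: labels are reshuffled at block granularity within
each run -- preserving run structure, block structure and balance --
and the classifier is retrained per permutation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.svm import SVC

from .paradigm import BlockLabel, task_block_scan_indices
from .synthsim import BoldRun

__all__ = [
    "LabeledScanSet",
    "SvmConfig",
    "FeatureScaler",
    "ScanClassifier",
    "CvResult",
    "PermutationResult",
    "EmptyDatasetError",
    "assemble_dataset",
    "minmax_scale",
    "train_classifier",
    "evaluate_classifier",
    "loro_cv",
    "balanced_block_permutation_test",
    "save_classifier",
    "load_classifier",
]


class EmptyDatasetError(ValueError):
    """Raised when screening removes every scan."""


@dataclass
class LabeledScanSet:
    """Scans x features matrix with class, block, and run labels.

    y is +1 for task A (countdown / yes), -1 for task B (memory / no).
    """

    X: np.ndarray
    y: np.ndarray
    block_id: np.ndarray
    run_id: np.ndarray
    mask_ref: str = ""

    def __post_init__(self) -> None:
        n = self.X.shape[0]
        if not (len(self.y) == len(self.block_id) == len(self.run_id) == n):
            raise ValueError("label arrays must match the number of scans")
        if (self.y == 1).sum() != (self.y == -1).sum():
            raise ValueError("dataset must be balanced between the two classes")

    @property
    def n_scans(self) -> int:
        return self.X.shape[0]

    def subset(self, keep: np.ndarray) -> "LabeledScanSet":
        return LabeledScanSet(
            self.X[keep], self.y[keep], self.block_id[keep], self.run_id[keep], self.mask_ref
        )


@dataclass(frozen=True)
class SvmConfig:
    C: float = 1.0
    tolerance: float = 1e-3
    max_iter: int = -1

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")


@dataclass
class FeatureScaler:
    """Per-feature affine map onto [-1, 1] from training min/max.

    Test values outside the training range extrapolate (no clipping);
    a constant training feature maps to 0 everywhere.
    """

    minimum: np.ndarray
    maximum: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "FeatureScaler":
        if X.shape[0] == 0:
            raise ValueError("cannot fit a scaler on an empty set")
        return cls(X.min(axis=0), X.max(axis=0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        span = self.maximum - self.minimum
        safe = np.where(span == 0, 1.0, span)
        out = 2.0 * (X - self.minimum) / safe - 1.0
        out[:, span == 0] = 0.0
        return out


def minmax_scale(train_X: np.ndarray, other_X: np.ndarray) -> tuple[np.ndarray, np.ndarray, FeatureScaler]:
    """Scale train to [-1, 1] per feature; apply the same parameters to the other set."""
    scaler = FeatureScaler.fit(train_X)
    return scaler.transform(train_X), scaler.transform(other_X), scaler


@dataclass
class ScanClassifier:
    """Trained linear decision rule f(x) = w'x + b on scaled features.

    The sign of the decision value gives the class; positive is task A
    (yes). ``feature_mask`` records which voxels the feature axis maps to.
    """

    w: np.ndarray
    b: float
    scaler: FeatureScaler
    config: SvmConfig
    mask_ref: str = ""
    feature_mask: np.ndarray | None = None

    def decision_values(self, X_raw: np.ndarray) -> np.ndarray:
        return self.scaler.transform(X_raw) @ self.w + self.b

    def predict(self, X_raw: np.ndarray) -> np.ndarray:
        """Class labels; a decision value of exactly 0 is labeled +1."""
        return np.where(self.decision_values(X_raw) >= 0, 1, -1)


def assemble_dataset(
    runs: list[BoldRun],
    feature_mask: np.ndarray,
    shift_seconds: float = 4.0,
    mask_ref: str = "",
) -> LabeledScanSet:
    """Extract labeled task-block scans from preprocessed alternating runs.

    Scans come from the windows [onset+shift, onset+duration+shift).
    The strict screening rule drops every unacknowledged block together
    with the same-ordinal block of the counterpart task in the same run.
    """
    for run in runs:
        if run.data.shape[:3] != feature_mask.shape:
            raise ValueError("runs and feature mask must share a grid")
    X_rows, ys, blocks, run_ids = [], [], [], []
    next_block = 0
    for run in runs:
        sched = run.schedule
        vox = run.data[feature_mask]  # (n_features, t)
        windows = task_block_scan_indices(sched, shift_seconds)
        by_task: dict[BlockLabel, list] = {BlockLabel.TASK_A: [], BlockLabel.TASK_B: []}
        for ev, idx in windows:
            by_task[ev.label].append((ev, idx))
        n_pairs = min(len(by_task[BlockLabel.TASK_A]), len(by_task[BlockLabel.TASK_B]))
        for k in range(n_pairs):
            ev_a, idx_a = by_task[BlockLabel.TASK_A][k]
            ev_b, idx_b = by_task[BlockLabel.TASK_B][k]
            if not (ev_a.acknowledged and ev_b.acknowledged):
                continue  # screening: both ordinal partners go
            for ev, idx, label in ((ev_a, idx_a, 1), (ev_b, idx_b, -1)):
                rows = [vox[:, i - run.t_offset_scans] for i in idx
                        if 0 <= i - run.t_offset_scans < vox.shape[1]]
                X_rows.extend(rows)
                ys.extend([label] * len(rows))
                blocks.extend([next_block] * len(rows))
                run_ids.extend([sched.run_id] * len(rows))
                next_block += 1
    if not X_rows:
        raise EmptyDatasetError("screening removed every scan")
    return LabeledScanSet(
        X=np.asarray(X_rows), y=np.asarray(ys), block_id=np.asarray(blocks),
        run_id=np.asarray(run_ids), mask_ref=mask_ref,
    )


def _fit_svm(X_scaled: np.ndarray, y: np.ndarray, cfg: SvmConfig) -> tuple[np.ndarray, float]:
    svc = SVC(kernel="linear", C=cfg.C, tol=cfg.tolerance, max_iter=cfg.max_iter)
    svc.fit(X_scaled, y)
    # classes_ is sorted [-1, +1], so positive decision values mean +1 (task A)
    return svc.coef_[0].copy(), float(svc.intercept_[0])


def train_classifier(
    dataset: LabeledScanSet,
    cfg: SvmConfig | None = None,
    feature_mask: np.ndarray | None = None,
) -> ScanClassifier:
    """Fit the scaler on the training set, then the C=1 linear soft-margin classifier."""
    cfg = cfg or SvmConfig()
    classes = np.unique(dataset.y)
    if len(classes) < 2:
        raise ValueError("training data must contain both classes")
    scaler = FeatureScaler.fit(dataset.X)
    w, b = _fit_svm(scaler.transform(dataset.X), dataset.y, cfg)
    return ScanClassifier(
        w=w, b=b, scaler=scaler, config=cfg, mask_ref=dataset.mask_ref,
        feature_mask=feature_mask,
    )


def evaluate_classifier(clf: ScanClassifier, X_raw: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean(clf.predict(X_raw) == y))


@dataclass
class CvResult:
    fold_run_ids: list[int]
    fold_accuracies: list[float]
    fold_n_scans: list[int]
    pooled_accuracy: float


def loro_cv(dataset: LabeledScanSet, cfg: SvmConfig | None = None) -> CvResult:
    """Leave-one-run-out cross-validation.

    Per fold the scaler and classifier are fitted on the training runs
    only. The pooled accuracy divides the total number of correctly
    classified scans accumulated over folds by the total scan count.
    """
    cfg = cfg or SvmConfig()
    run_ids = np.unique(dataset.run_id)
    if len(run_ids) < 2:
        raise ValueError("LOROCV needs at least two distinct runs")
    fold_acc, fold_n, total_correct = [], [], 0
    for rid in run_ids:
        test = dataset.run_id == rid
        clf = train_classifier(dataset.subset(~test), cfg)
        acc = evaluate_classifier(clf, dataset.X[test], dataset.y[test])
        fold_acc.append(acc)
        fold_n.append(int(test.sum()))
        total_correct += int(round(acc * test.sum()))
    return CvResult(
        fold_run_ids=[int(r) for r in run_ids],
        fold_accuracies=fold_acc,
        fold_n_scans=fold_n,
        pooled_accuracy=total_correct / dataset.n_scans,
    )


@dataclass
class PermutationResult:
    observed_accuracy: float
    null_accuracies: np.ndarray
    p_value: float
    n_permutations: int
    seed: int


def _permute_block_labels(
    y: np.ndarray, block_id: np.ndarray, run_id: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Permute class labels at block granularity, independently within each run."""
    y_new = y.copy()
    for rid in np.unique(run_id):
        in_run = run_id == rid
        blocks = np.unique(block_id[in_run])
        block_labels = np.array([y[block_id == b][0] for b in blocks])
        permuted = rng.permutation(block_labels)
        for b, lab in zip(blocks, permuted):
            y_new[block_id == b] = lab
    return y_new


def balanced_block_permutation_test(
    dataset: LabeledScanSet,
    cfg: SvmConfig | None = None,
    n_permutations: int = 5000,
    seed: int = 0,
    *,
    eval_X: np.ndarray,
    eval_y: np.ndarray,
    solver_tolerance: float = 1e-2,
) -> PermutationResult:
    """Balanced-block permutation test of held-out classification accuracy.

    Each permutation reshuffles the training labels across blocks within
    each run (every scan inherits its block's permuted label, per-run
    balance is preserved), retrains the classifier, and scores it on the
    same evaluation scans. p = (1 + #{null >= observed}) / (1 + n),
    the add-one estimator, so p is never 0.

    ``solver_tolerance`` is applied to every fit inside the test —
    observed and null alike, so the comparison stays consistent — and
    is looser than the training default: label-shuffled problems
    converge slowly, and accuracy is insensitive at this precision.
    """
    cfg = cfg or SvmConfig()
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    scaler = FeatureScaler.fit(dataset.X)  # scaling depends on X only, never labels
    Xs = scaler.transform(dataset.X)
    Es = scaler.transform(eval_X)
    # the linear kernel never changes across permutations: compute it once
    K_train = Xs @ Xs.T
    K_eval = Es @ Xs.T

    def accuracy_for(labels: np.ndarray) -> float:
        if len(np.unique(labels)) < 2:  # degenerate permutation: all one class
            return float(np.mean(eval_y == labels[0]))
        svc = SVC(kernel="precomputed", C=cfg.C, tol=solver_tolerance, max_iter=cfg.max_iter)
        svc.fit(K_train, labels)
        pred = np.where(svc.decision_function(K_eval) >= 0, 1, -1)
        return float(np.mean(pred == eval_y))

    observed = accuracy_for(dataset.y)
    null = np.array([
        accuracy_for(_permute_block_labels(dataset.y, dataset.block_id, dataset.run_id, rng))
        for _ in range(n_permutations)
    ])
    p = (1 + int(np.sum(null >= observed))) / (1 + n_permutations)
    return PermutationResult(
        observed_accuracy=observed, null_accuracies=null, p_value=p,
        n_permutations=n_permutations, seed=seed,
    )


def save_classifier(clf: ScanClassifier, path: str | Path) -> None:
    """Serialize weights, bias, scaler, config, and feature mask as JSON."""
    payload = {
        "w": clf.w.tolist(),
        "b": clf.b,
        "scaler": {"minimum": clf.scaler.minimum.tolist(), "maximum": clf.scaler.maximum.tolist()},
        "config": {"C": clf.config.C, "tolerance": clf.config.tolerance, "max_iter": clf.config.max_iter},
        "mask_ref": clf.mask_ref,
        "feature_mask_shape": list(clf.feature_mask.shape) if clf.feature_mask is not None else None,
        "feature_mask_flat": clf.feature_mask.ravel().astype(int).tolist()
        if clf.feature_mask is not None else None,
    }
    Path(path).write_text(json.dumps(payload))


def load_classifier(path: str | Path) -> ScanClassifier:
    d = json.loads(Path(path).read_text())
    fm = None
    if d["feature_mask_flat"] is not None:
        fm = np.asarray(d["feature_mask_flat"], dtype=bool).reshape(d["feature_mask_shape"])
    return ScanClassifier(
        w=np.asarray(d["w"]),
        b=float(d["b"]),
        scaler=FeatureScaler(np.asarray(d["scaler"]["minimum"]), np.asarray(d["scaler"]["maximum"])),
        config=SvmConfig(**d["config"]),
        mask_ref=d["mask_ref"],
        feature_mask=fm,
    )
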