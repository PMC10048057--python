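"""Cross-validated training, evaluation, and the kernel-size sweep.

The protocol is stratified k-fold cross-validation (default k=4) over
the trials of one session/subject: each fold trains a fresh
:class:`~forcemi.estimator.MSTCNAMClassifier` and is scored on its
held-out fold.  Accuracy is reported both as plain fraction-correct and
in the one-vs-rest macro-averaged (TP+TN)/(TP+TN+FP+FN) form (the two
coincide only for binary problems).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold

from .containers import TrialSet
from .estimator import MSTCNAMClassifier


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol parameters (one iteration = one epoch)."""

    n_iterations: int = 500
    batch_size: int = 16
    lr: float = 0.001
    optimizer: str = "adam"
    seed: int = 0
    folds: int = 4

    def __post_init__(self) -> None:
        if self.n_iterations < 1 or self.batch_size < 1:
            raise ValueError("n_iterations and batch_size must be positive")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.lr < 0:
            raise ValueError("lr must be non-negative")


@dataclass
class EvalReport:
    """Cross-validation results for one dataset and configuration."""

    per_fold_accuracy: list[float]          # percent, fraction-correct
    confusion: np.ndarray                   # summed over test folds
    loss_curves: list[list[float]]          # per fold, per iteration
    accuracy_curves: list[list[float]]      # held-out accuracy per iteration
    seed: int
    config: dict = field(default_factory=dict)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.per_fold_accuracy))

    @property
    def std_accuracy(self) -> float:
        return float(np.std(self.per_fold_accuracy))

    @property
    def macro_ovr_accuracy(self) -> float:
        """Macro-averaged one-vs-rest (TP+TN)/total accuracy, percent."""
        return 100.0 * macro_ovr_accuracy(self.confusion)

    def summary(self) -> dict:
        return {
            "per_fold_accuracy": [round(a, 4) for a in self.per_fold_accuracy],
            "mean_accuracy": round(self.mean_accuracy, 4),
            "std_accuracy": round(self.std_accuracy, 4),
            "macro_ovr_accuracy": round(self.macro_ovr_accuracy, 4),
            "confusion": self.confusion.tolist(),
            "seed": self.seed,
            "config": self.config,
        }


def accuracy_from_confusion(cm: np.ndarray) -> float:
    """Fraction-correct accuracy from a confusion matrix (rows = truth)."""
    cm = np.asarray(cm)
    return float(np.trace(cm) / cm.sum())


def macro_ovr_accuracy(cm: np.ndarray) -> float:
    """Per-class one-vs-rest (TP+TN)/(TP+TN+FP+FN), macro-averaged."""
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    accs = []
    for k in range(cm.shape[0]):
        tp = cm[k, k]
        fn = cm[k].sum() - tp
        fp = cm[:, k].sum() - tp
        tn = total - tp - fn - fp
        accs.append((tp + tn) / total)
    return float(np.mean(accs))


def kfold_split(labels, k: int = 4, seed: int = 0, groups=None):
    """Stratified k-fold indices; ``groups`` switches to group-aware CV.

    With ``groups`` (e.g. the round index of each trial) the split keeps
    whole groups out of the training set, guarding against the optimism
    of trial-level CV on block-structured sessions.
    """
    labels = np.asarray(labels)
    counts = np.bincount(labels)
    if np.any(counts[np.unique(labels)] < k):
        raise ValueError(f"every class needs at least k={k} trials")
    if groups is None:
        cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return list(cv.split(np.zeros(len(labels)), labels))
    from sklearn.model_selection import StratifiedGroupKFold
    cv = StratifiedGroupKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(cv.split(np.zeros(len(labels)), labels, groups))


def _as_arrays(trials):
    if isinstance(trials, TrialSet):
        return trials.data, trials.labels
    return trials


def train(trials, train_cfg: TrainConfig = TrainConfig(), eval_set=None,
          **model_params) -> MSTCNAMClassifier:
    """Fit one classifier on a TrialSet (or an (X, y) pair)."""
    X, y = _as_arrays(trials)
    clf = MSTCNAMClassifier(
        n_epochs=train_cfg.n_iterations, batch_size=train_cfg.batch_size,
        lr=train_cfg.lr, optimizer=train_cfg.optimizer,
        random_state=train_cfg.seed, **model_params)
    return clf.fit(X, y, eval_set=eval_set)


def evaluate(clf: MSTCNAMClassifier, trials) -> dict:
    """Score a fitted classifier: both accuracy forms plus the confusion.

    Confusion rows are true classes, columns predicted classes.
    """
    X, y = _as_arrays(trials)
    pred = clf.predict(X)
    cm = confusion_matrix(y, pred, labels=clf.classes_)
    return {
        "accuracy": 100.0 * accuracy_from_confusion(cm),
        "macro_ovr_accuracy": 100.0 * macro_ovr_accuracy(cm),
        "confusion": cm,
    }


def crossvalidate(trials, train_cfg: TrainConfig = TrainConfig(),
                  groups=None, record_curves: bool = True,
                  **model_params) -> EvalReport:
    """Stratified k-fold cross-validation of the classifier."""
    X, y = _as_arrays(trials)
    y = np.asarray(y)
    splits = kfold_split(y, k=train_cfg.folds, seed=train_cfg.seed,
                         groups=groups)
    classes = np.unique(y)
    fold_acc, curves_l, curves_a = [], [], []
    confusion = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for tr_idx, te_idx in splits:
        clf = MSTCNAMClassifier(
            n_epochs=train_cfg.n_iterations, batch_size=train_cfg.batch_size,
            lr=train_cfg.lr, optimizer=train_cfg.optimizer,
            random_state=train_cfg.seed, **model_params)
        eval_set = (X[te_idx], y[te_idx]) if record_curves else None
        clf.fit(X[tr_idx], y[tr_idx], eval_set=eval_set)
        res = evaluate(clf, (X[te_idx], y[te_idx]))
        fold_acc.append(res["accuracy"])
        confusion += res["confusion"]
        curves_l.append(list(clf.loss_curve_))
        curves_a.append(list(clf.accuracy_curve_ or []))
    return EvalReport(
        per_fold_accuracy=fold_acc, confusion=confusion,
        loss_curves=curves_l, accuracy_curves=curves_a,
        seed=train_cfg.seed,
        config={"train": vars(train_cfg) | {}, "model": model_params},
    )


def replicate_seeds(trials, train_cfg: TrainConfig, seeds=(0, 1, 2),
                    **kwargs) -> list[EvalReport]:
    """Repeat a cross-validation under several seeds (splits + init).

    Useful for stochastic checks where a single seed's fold noise is of
    the order of the effect under study.
    """
    from dataclasses import replace
    return [crossvalidate(trials, replace(train_cfg, seed=int(s)), **kwargs)
            for s in seeds]


def paired_ttest(acc_a, acc_b) -> tuple[float, float]:
    """Two-sided paired t-test on per-subject accuracies.

    Identical vectors return (0.0, 1.0) by convention; a constant
    nonzero difference has zero variance and raises.
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    d = a - b
    if np.all(d == 0):
        return 0.0, 1.0
    if np.std(d) == 0:
        raise ValueError("zero-variance nonzero differences: t undefined")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def kernel_sweep(trials, kernel_triples,
                 train_cfg: TrainConfig = TrainConfig(),
                 **model_params) -> pd.DataFrame:
    """Cross-validate each temporal-kernel triple with identical splits.

    Triples must be strictly increasing odd widths.  Returns a table
    with columns (s, m, l, mean_accuracy, std_accuracy) sorted by mean
    accuracy, descending.
    """
    rows = []
    for triple in kernel_triples:
        triple = tuple(int(t) for t in triple)
        if len(triple) != 3 or any(t % 2 == 0 for t in triple) or \
                not (triple[0] < triple[1] < triple[2]):
            raise ValueError(
                f"kernel triple {triple} must be strictly increasing odd widths")
        report = crossvalidate(trials, train_cfg, record_curves=False,
                               branch_kernel_widths=triple, **model_params)
        rows.append({"s": triple[0], "m": triple[1], "l": triple[2],
                     "mean_accuracy": report.mean_accuracy,
                     "std_accuracy": report.std_accuracy})
    return (pd.DataFrame(rows)
            .sort_values("mean_accuracy", ascending=False, kind="mergesort")
            .reset_index(drop=True))
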