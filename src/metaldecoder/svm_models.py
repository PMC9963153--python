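"""SVM classification of exposure-concentration classes and metal type.

Covers the discriminative half of the pipeline: stratified train/holdout
splitting, RBF-kernel SVM training at the study's fixed hyperparameters
(C = 1, gamma = "scale"), one-vs-rest sensitivity/specificity/accuracy,
leakage-safe 10-fold cross-validation (SMOTE refit inside every training
fold), and the classification-based limit of detection: the smallest
concentration from which upward every class exchanges less than 2% of its
holdout spectra with the control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .features import FeatureMatrix, smote_oversample

__all__ = [
    "SvmConfig",
    "ConfusionMatrix",
    "ClassMetrics",
    "stratified_split",
    "train_svm",
    "evaluate_classifier",
    "metrics_from_confusion",
    "crossvalidate",
    "determine_lod_classification",
    "NOT_DETECTED",
]

#: Sentinel returned when no concentration satisfies the detection rule.
NOT_DETECTED = None


@dataclass(frozen=True)
class SvmConfig:
    """Fixed SVM hyperparameters of the study."""

    C: float = 1.0
    kernel: str = "rbf"
    gamma: str | float = "scale"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")


@dataclass
class ConfusionMatrix:
    """Square true-by-predicted count table, control class first."""

    classes: np.ndarray  # ordered class indices (ascending; control = 0 first)
    counts: np.ndarray  # (k, k) ints, rows = true

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=int)
        self.counts = np.asarray(self.counts, dtype=int)
        k = self.classes.size
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square and match classes")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass
class ClassMetrics:
    """One-vs-rest sensitivity, specificity and accuracy per class."""

    classes: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    accuracy: np.ndarray

    def as_dict(self) -> dict[int, dict[str, float]]:
        return {
            int(c): {
                "sensitivity": float(se),
                "specificity": float(sp),
                "accuracy": float(ac),
            }
            for c, se, sp, ac in zip(
                self.classes, self.sensitivity, self.specificity, self.accuracy
            )
        }


def stratified_split(
    fm: FeatureMatrix,
    holdout_frac: float = 0.2,
    seed: int = 0,
    min_class_size: int = 5,
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Split rows class-by-class, preserving proportions to within one sample.

    The per-class holdout count is ``round(holdout_frac * n_class)``, so a
    1,200-spectrum class at 20% contributes exactly 240 holdout and 960
    training rows, and the 9,600-spectrum control 1,920 holdout rows.
    """
    if not 0.0 <= holdout_frac < 1.0:
        raise ValueError("holdout_frac must be in [0, 1)")
    rng = np.random.default_rng(seed)
    train_idx, hold_idx = [], []
    for cls, n in sorted(fm.class_counts.items()):
        if holdout_frac > 0 and n < min_class_size:
            raise ValueError(f"class {cls} has only {n} samples (need >= {min_class_size})")
        idx = np.flatnonzero(fm.labels == cls)
        idx = rng.permutation(idx)
        n_hold = int(round(holdout_frac * n))
        hold_idx.append(idx[:n_hold])
        train_idx.append(idx[n_hold:])
    train = fm.subset(np.sort(np.concatenate(train_idx)))
    hold = fm.subset(
        np.sort(np.concatenate(hold_idx)) if hold_idx else np.empty(0, dtype=int)
    )
    return train, hold


def train_svm(train: FeatureMatrix, cfg: SvmConfig = SvmConfig()) -> SVC:
    """Fit the RBF SVM on score rows; deterministic given the config seed."""
    if len(np.unique(train.labels)) < 2:
        raise ValueError("training data must contain at least 2 classes")
    clf = SVC(
        C=cfg.C, kernel=cfg.kernel, gamma=cfg.gamma, random_state=cfg.seed
    )
    clf.fit(train.scores, train.labels)
    return clf


def metrics_from_confusion(cm: ConfusionMatrix) -> ClassMetrics:
    """One-vs-rest metrics: sens = TP/(TP+FN), spec = TN/(TN+FP), acc = (TP+TN)/n."""
    counts = cm.counts.astype(float)
    n = counts.sum()
    tp = np.diag(counts)
    fn = counts.sum(axis=1) - tp
    fp = counts.sum(axis=0) - tp
    tn = n - tp - fn - fp
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = np.where(tp + fn > 0, tp / (tp + fn), np.nan)
        spec = np.where(tn + fp > 0, tn / (tn + fp), np.nan)
    acc = (tp + tn) / n
    return ClassMetrics(cm.classes.copy(), sens, spec, acc)


def evaluate_classifier(
    clf: SVC, holdout: FeatureMatrix
) -> tuple[ConfusionMatrix, ClassMetrics]:
    """Confusion matrix and per-class metrics on a holdout partition."""
    if len(holdout) == 0:
        raise ValueError("holdout set is empty")
    model_classes = np.asarray(clf.classes_, dtype=int)
    unseen = set(np.unique(holdout.labels)) - set(model_classes.tolist())
    if unseen:
        raise ValueError(f"holdout contains classes unseen in training: {sorted(unseen)}")
    pred = clf.predict(holdout.scores)
    k = model_classes.size
    lookup = {c: i for i, c in enumerate(model_classes.tolist())}
    counts = np.zeros((k, k), dtype=int)
    for t, p in zip(holdout.labels, pred):
        counts[lookup[int(t)], lookup[int(p)]] += 1
    cm = ConfusionMatrix(model_classes, counts)
    return cm, metrics_from_confusion(cm)


def crossvalidate(
    fm: FeatureMatrix,
    cfg: SvmConfig = SvmConfig(),
    n_folds: int = 10,
    smote_targets: Mapping[int, int] | None = None,
    smote_k: int = 5,
) -> list[dict]:
    """Stratified k-fold CV with SMOTE applied inside each training fold only.

    Returns one record per fold with the fold confusion matrix, metrics and
    overall accuracy.  Validation folds contain only original rows by
    construction (oversampling happens after the fold split), which is the
    leakage-safe protocol.
    """
    counts = fm.class_counts
    too_small = {c: n for c, n in counts.items() if n < n_folds}
    if too_small:
        raise ValueError(f"classes smaller than n_folds={n_folds}: {too_small}")
    if fm.synthetic.any():
        raise ValueError("cross-validation input must not already contain SMOTE rows")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=cfg.seed)
    records = []
    for fold, (tr, va) in enumerate(skf.split(fm.scores, fm.labels)):
        train, val = fm.subset(tr), fm.subset(va)
        if smote_targets is not None:
            # full-dataset targets scaled to the training-fold share, never
            # below the fold's current count
            scale = (n_folds - 1) / n_folds
            targets = {
                c: max(int(round(t * scale)), train.class_counts.get(c, 0))
                for c, t in smote_targets.items()
            }
            train = smote_oversample(
                train, targets, k=smote_k, rng=cfg.seed * 1000 + fold
            )
        clf = train_svm(train, cfg)
        cm, metrics = evaluate_classifier(clf, val)
        records.append(
            {
                "fold": fold,
                "confusion": cm,
                "metrics": metrics,
                "accuracy": float(np.trace(cm.counts) / cm.counts.sum()),
                "n_synthetic_in_val": int(val.synthetic.sum()),
            }
        )
    return records


def determine_lod_classification(
    cm: ConfusionMatrix,
    concentrations: Sequence[float],
    threshold: float = 0.02,
    rule: str = "symmetric",
) -> tuple[float | None, dict[int, float]]:
    """Classification-based limit of detection.

    A concentration class "separates from control" when fewer than
    ``threshold`` (default 2%, the >98% accuracy criterion) of its holdout
    spectra are predicted as control and — under the default symmetric rule —
    fewer than ``threshold`` of control spectra are predicted as that class.
    The LOD is the smallest concentration for which the criterion holds there
    and at every larger concentration (so detection is monotone).  The
    row-only reading (``rule="row"``) gates only class->control confusion.

    Returns ``(lod, fractions)`` where ``fractions`` maps class index to its
    observed class->control confusion fraction; ``lod`` is ``NOT_DETECTED``
    (``None``) when no class qualifies.
    """
    if rule not in ("symmetric", "row"):
        raise ValueError("rule must be 'symmetric' or 'row'")
    classes = cm.classes.tolist()
    if 0 not in classes:
        raise ValueError("confusion matrix lacks a control class")
    ctrl = classes.index(0)
    nonzero = [i for i in range(len(classes)) if i != ctrl]
    if len(nonzero) != len(concentrations):
        raise ValueError(
            f"{len(concentrations)} concentrations for {len(nonzero)} nonzero classes"
        )
    conc = sorted(concentrations)
    counts = cm.counts.astype(float)
    row_tot = counts.sum(axis=1)
    ctrl_tot = row_tot[ctrl]
    frac_to_ctrl = {}
    ok = []
    for j, i in enumerate(nonzero):
        f_cls = counts[i, ctrl] / row_tot[i] if row_tot[i] else 1.0
        f_ctl = counts[ctrl, i] / ctrl_tot if ctrl_tot else 1.0
        frac_to_ctrl[classes[i]] = float(f_cls)
        good = f_cls < threshold
        if rule == "symmetric":
            good = good and f_ctl < threshold
        ok.append(good)
    lod = NOT_DETECTED
    for j in range(len(ok)):
        if all(ok[j:]):
            lod = conc[j]
            break
    return lod, frac_to_ctrl
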