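"""1-D CNN regression of exposure concentration on PCA scores.

The regressor maps the 22 PCA scores of one spectrum (treated as a length-22
single-channel sequence) to a continuous class-index prediction: 0 for the
control, 1..n for the decade ladder (n = 9 for Cr6+, 13 for As3+).  The
architecture is four convolutional layers — 22, 22, 44, 44 filters of width
7, stride 1, "same" padding, each followed by ReLU, batch normalization and
20% dropout — then flatten, dropout, a 22-unit ReLU dense layer with L2
penalty 0.001, and a linear output unit.  Training uses Adam on mean squared
error with batch size 44 for up to 35 epochs, optionally stopping early
after a run of consecutive validation-loss increases.

Detection limits come from the empirical spread of holdout predictions:
each class gets its central 99% prediction interval; the control's interval
is the limit of blank (LOB); the limit of detection (LOD) is the smallest
concentration whose predictions overlap the LOB in fewer than 0.5% of
spectra (and stay clear at all larger concentrations); the limit of
quantification (LOQ) additionally requires < 0.5% overlap with both
neighbouring classes' intervals.  The dynamic range runs from the LOQ to
the largest calibrated concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from ._nn import (
    Adam,
    BatchNorm1D,
    Conv1D,
    Dense,
    Dropout,
    Flatten,
    Network,
    ReLU,
    mse_loss,
)
from .features import FeatureMatrix, smote_oversample

__all__ = [
    "CnnRegressorSpec",
    "DetectionLimits",
    "build_cnn",
    "train_cnn",
    "predict",
    "evaluate_regression",
    "learning_curve",
    "determine_limits",
    "box_stats",
    "NOT_DETECTED",
]

NOT_DETECTED = None


@dataclass(frozen=True)
class CnnRegressorSpec:
    """Architecture and training hyperparameters of the regressor.

    The layer shapes are fixed by the study design; the Adam step size is
    the one free knob (chosen, as in the original protocol, by monitoring
    convergence of training and validation loss within the 35-epoch budget).
    """

    input_len: int = 22
    conv_layers: tuple[tuple[int, int], ...] = ((22, 7), (22, 7), (44, 7), (44, 7))
    dropout_rate: float = 0.2
    dense_units: int = 22
    l2: float = 0.001
    batch_size: int = 44
    max_epochs: int = 35
    patience: int = 10
    learning_rate: float = 3e-3
    early_stopping: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conv_layers) != 4:
            raise ValueError("the regressor has exactly 4 convolutional layers")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")


@dataclass
class DetectionLimits:
    """Empirical detection limits derived from per-class prediction intervals."""

    lob: tuple[float, float]  # prediction-scale interval of the control
    lod: float | None  # mol/L
    loq: float | None  # mol/L
    dynamic_range: tuple[float, float] | None  # (LOQ, c_max), mol/L
    intervals: dict[int, tuple[float, float]]  # class -> central 99% interval
    lob_overlap: dict[int, float]  # class -> fraction of predictions inside LOB


def build_cnn(spec: CnnRegressorSpec = CnnRegressorSpec()) -> Network:
    """Construct the regressor with seeded He-initialised weights.

    Convolution preserves the spatial length (stride 1, "same" padding), so
    the flattened feature count is ``last_filters * input_len``.
    """
    rng = np.random.default_rng(spec.seed)
    layers = []
    in_ch = 1
    for filters, kernel in spec.conv_layers:
        layers += [
            Conv1D(in_ch, filters, kernel, rng),
            ReLU(),
            BatchNorm1D(filters),
            Dropout(spec.dropout_rate),
        ]
        in_ch = filters
    flat = in_ch * spec.input_len
    layers += [
        Flatten(),
        Dropout(spec.dropout_rate),
        Dense(flat, spec.dense_units, rng, l2=spec.l2),
        ReLU(),
        Dense(spec.dense_units, 1, rng),
    ]
    net = Network(layers, rng)
    net.spec = spec
    return net


def _as_input(scores: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(scores[:, None, :])


def predict(net: Network, scores: np.ndarray) -> np.ndarray:
    """Inference-mode forward pass; returns one real per row."""
    return net.forward(_as_input(np.asarray(scores, float)), training=False).ravel()


def _stratified_val_split(labels, val_frac, rng):
    tr, va = [], []
    for cls in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == cls))
        n_val = int(round(val_frac * idx.size))
        va.append(idx[:n_val])
        tr.append(idx[n_val:])
    return np.concatenate(tr), np.concatenate(va) if va else np.empty(0, int)


def train_cnn(
    net: Network,
    train: FeatureMatrix,
    val_frac: float = 0.1,
    spec: CnnRegressorSpec | None = None,
) -> dict:
    """Train on (scores -> class index) with Adam/MSE; returns loss history.

    A stratified ``val_frac`` share of the training rows is held aside to
    monitor validation loss; with ``early_stopping`` the run stops after
    ``max(1, patience)`` consecutive epochs of rising validation loss
    (patience 0 therefore stops at the first increase).
    """
    if len(train) == 0:
        raise ValueError("training set is empty")
    spec = spec or getattr(net, "spec", CnnRegressorSpec())
    rng = np.random.default_rng(spec.seed + 1)
    y = train.labels.astype(float)
    tr_idx, va_idx = _stratified_val_split(train.labels, val_frac, rng)
    Xtr, ytr = _as_input(train.scores[tr_idx]), y[tr_idx]
    Xva, yva = _as_input(train.scores[va_idx]), y[va_idx]
    opt = Adam(lr=spec.learning_rate)
    history = {"train_loss": [], "val_loss": []}
    worse_streak = 0
    prev_val = np.inf
    for epoch in range(spec.max_epochs):
        order = rng.permutation(len(ytr))
        epoch_loss = 0.0
        for start in range(0, len(order), spec.batch_size):
            batch = order[start : start + spec.batch_size]
            pred = net.forward(Xtr[batch], training=True).ravel()
            loss, grad = mse_loss(pred, ytr[batch])
            net.backward(grad[:, None])
            opt.step(net)
            epoch_loss += loss * batch.size
        history["train_loss"].append(epoch_loss / len(ytr))
        if len(yva):
            val_pred = net.forward(Xva, training=False).ravel()
            val_loss, _ = mse_loss(val_pred, yva)
        else:
            val_loss = history["train_loss"][-1]
        history["val_loss"].append(val_loss)
        if spec.early_stopping:
            worse_streak = worse_streak + 1 if val_loss > prev_val else 0
            if worse_streak >= max(1, spec.patience):
                break
        prev_val = val_loss
    return history


def evaluate_regression(net: Network, holdout: FeatureMatrix) -> tuple[float, float]:
    """MSE and R^2 of predicted vs true class index on a holdout set."""
    if len(holdout) == 0:
        raise ValueError("holdout set is empty")
    y = holdout.labels.astype(float)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined: holdout labels have zero variance")
    pred = predict(net, holdout.scores)
    ss_res = float(((pred - y) ** 2).sum())
    return ss_res / y.size, 1.0 - ss_res / ss_tot


def learning_curve(
    train: FeatureMatrix,
    holdout: FeatureMatrix,
    spec: CnnRegressorSpec = CnnRegressorSpec(),
    sizes: Sequence[int] = (100, 1000, 3000, 7680),
    n_repeats: int = 10,
    max_augment_factor: int = 8,
    smote_k: int = 5,
) -> list[dict]:
    """Holdout MSE/R^2 as a function of per-class training-set size.

    For each size, each repeat draws that many rows per class from the
    training partition (SMOTE-augmenting classes that are smaller than the
    requested size, up to ``max_augment_factor`` times their real count),
    trains a fresh model, and evaluates on the fixed holdout.  Mean and SD
    over repeats are reported per size.
    """
    counts = train.class_counts
    results = []
    for size in sizes:
        limit = max_augment_factor * min(counts.values())
        if size > limit:
            raise ValueError(
                f"size {size} exceeds the augmentable maximum {limit} "
                f"({max_augment_factor}x the smallest class)"
            )
        mses, r2s = [], []
        for rep in range(n_repeats):
            rep_seed = spec.seed + 104729 * size + rep
            rng = np.random.default_rng(rep_seed)
            parts = []
            for cls, n in sorted(counts.items()):
                idx = np.flatnonzero(train.labels == cls)
                take = rng.choice(idx, size=min(size, n), replace=False)
                parts.append(take)
            sub = train.subset(np.concatenate(parts))
            need = {c: size for c, n in sorted(counts.items()) if n < size}
            if need:
                sub = smote_oversample(sub, need, k=smote_k, rng=rng)
            net = build_cnn(replace(spec, seed=rep_seed))
            train_cnn(net, sub, spec=replace(spec, seed=rep_seed))
            mse, r2 = evaluate_regression(net, holdout)
            mses.append(mse)
            r2s.append(r2)
        results.append(
            {
                "size": size,
                "mse_mean": float(np.mean(mses)),
                "mse_sd": float(np.std(mses)),
                "r2_mean": float(np.mean(r2s)),
                "r2_sd": float(np.std(r2s)),
            }
        )
    return results


def _central_interval(preds: np.ndarray, alpha: float) -> tuple[float, float]:
    lo, hi = np.percentile(preds, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


def _fraction_inside(preds: np.ndarray, interval: tuple[float, float]) -> float:
    lo, hi = interval
    return float(np.mean((preds >= lo) & (preds <= hi)))


def determine_limits(
    predictions_by_class: Mapping[int, np.ndarray],
    concentrations: Sequence[float],
    alpha: float = 0.005,
    min_predictions: int = 20,
) -> DetectionLimits:
    """LOB/LOD/LOQ from empirical per-class prediction intervals.

    ``predictions_by_class`` maps class index (0 = control) to holdout
    predictions; ``concentrations`` aligns with classes 1..n ascending.
    Intervals are central ``1 - 2*alpha`` (default 99%) with linearly
    interpolated percentiles.  The LOQ search starts at the LOD so the
    reported LOQ is never below the LOD, and the lower neighbour of class 1
    is the control interval itself.
    """
    classes = sorted(predictions_by_class)
    if 0 not in classes:
        raise ValueError("control predictions (class 0) are required")
    if len(classes) - 1 != len(concentrations):
        raise ValueError("one concentration per nonzero class is required")
    for cls in classes:
        if len(predictions_by_class[cls]) < min_predictions:
            raise ValueError(
                f"class {cls}: need >= {min_predictions} predictions for "
                "stable 99% intervals"
            )
    conc = sorted(concentrations)
    intervals = {
        cls: _central_interval(np.asarray(predictions_by_class[cls], float), alpha)
        for cls in classes
    }
    lob = intervals[0]
    nonzero = classes[1:]
    lob_overlap = {
        cls: _fraction_inside(np.asarray(predictions_by_class[cls], float), lob)
        for cls in nonzero
    }
    detect_ok = [lob_overlap[cls] < alpha for cls in nonzero]
    lod_idx = None
    for j in range(len(nonzero)):
        if all(detect_ok[j:]):
            lod_idx = j
            break
    lod = conc[lod_idx] if lod_idx is not None else NOT_DETECTED

    def quant_ok(j: int) -> bool:
        cls = nonzero[j]
        preds = np.asarray(predictions_by_class[cls], float)
        below = intervals[nonzero[j - 1]] if j > 0 else lob
        if _fraction_inside(preds, below) >= alpha:
            return False
        if j + 1 < len(nonzero):
            if _fraction_inside(preds, intervals[nonzero[j + 1]]) >= alpha:
                return False
        return True

    loq = NOT_DETECTED
    if lod_idx is not None:
        for j in range(lod_idx, len(nonzero)):
            if all(quant_ok(i) for i in range(j, len(nonzero))):
                loq = conc[j]
                break
    dynamic_range = (loq, conc[-1]) if loq is not None else None
    return DetectionLimits(
        lob=lob,
        lod=lod,
        loq=loq,
        dynamic_range=dynamic_range,
        intervals=intervals,
        lob_overlap=lob_overlap,
    )


def box_stats(predictions_by_class: Mapping[int, np.ndarray]) -> dict[int, dict]:
    """Box-plot statistics per class: quartile box plus central-99% whiskers.

    Shares its percentile definition (linear interpolation) with
    :func:`determine_limits` so plotted whiskers and detection intervals
    coincide.
    """
    out = {}
    for cls in sorted(predictions_by_class):
        p = np.asarray(predictions_by_class[cls], float)
        q = np.percentile(p, [0.5, 25, 50, 75, 99.5])
        out[cls] = {
            "whisker_low": float(q[0]),
            "q1": float(q[1]),
            "median": float(q[2]),
            "q3": float(q[3]),
            "whisker_high": float(q[4]),
            "n_outliers": int(np.sum((p < q[0]) | (p > q[4]))),
        }
    return out
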