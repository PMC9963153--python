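"""Transfer learning across water matrices for above/below-limit verdicts.

A binary 1-D CNN (the regressor's convolutional stack with a one-node
sigmoid head) is pretrained on deionised-water data spiked well below and
well above the WHO recommended arsenic limit (10 ug/L = 0.13 uM).  For a
new water matrix — tap water or treated wastewater, whose background
spectra differ systematically — the third and fourth convolutional layers
are frozen and the remaining weights fine-tuned on only 80 spectra per
spiked class.  An unspiked field sample is then judged by majority vote of
per-spectrum probabilities, ties resolving to "above" as the fail-safe
call for water safety.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ._nn import Adam, Dense, Dropout, Flatten, Network, Sigmoid, bce_loss
from .cnn_regression import CnnRegressorSpec, build_cnn
from .features import FeatureMatrix

__all__ = [
    "TransferConfig",
    "pretrain_binary",
    "fine_tune",
    "predict_proba",
    "binary_accuracy",
    "classify_water_sample",
]

#: WHO recommended limit for As3+ in drinking water: 10 ug/L = 0.13 uM.
WHO_LIMIT_AS_MOLAR = 1.3347e-7


@dataclass(frozen=True)
class TransferConfig:
    """Pretraining/fine-tuning protocol for the binary safety classifier."""

    pretrain_below: tuple[float, ...] = (0.05e-9, 0.5e-9, 5e-9)  # mol/L
    pretrain_above: tuple[float, ...] = (5e-6, 50e-6, 500e-6)
    who_limit: float = WHO_LIMIT_AS_MOLAR
    finetune_n_per_class: int = 80
    frozen_conv_layers: tuple[int, ...] = (3, 4)  # 1-based conv indices
    learning_rate: float = 1e-3
    batch_size: int = 44
    max_epochs: int = 35
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c >= self.who_limit for c in self.pretrain_below):
            raise ValueError("all pretrain_below concentrations must be < who_limit")
        if any(c <= self.who_limit for c in self.pretrain_above):
            raise ValueError("all pretrain_above concentrations must be > who_limit")


def build_binary_cnn(cfg: TransferConfig, spec: CnnRegressorSpec | None = None) -> Network:
    """Regressor conv stack with a one-node sigmoid head."""
    spec = spec or CnnRegressorSpec(seed=cfg.seed)
    base = build_cnn(spec)
    rng = base.rng
    conv_stack = base.layers[: 4 * len(spec.conv_layers)]
    flat = spec.conv_layers[-1][0] * spec.input_len
    head = [Flatten(), Dropout(spec.dropout_rate), Dense(flat, 1, rng), Sigmoid()]
    net = Network(conv_stack + head, rng)
    net.spec = spec
    net.transfer_cfg = cfg
    return net


def _conv_layers(net: Network):
    from ._nn import Conv1D

    return [l for l in net.layers if isinstance(l, Conv1D)]


def binary_labels(fm: FeatureMatrix, who_limit: float) -> np.ndarray:
    """1 for above-limit rows, 0 for below (by true spiked concentration)."""
    if fm.concentrations is None:
        raise ValueError("feature matrix carries no concentrations")
    return (fm.concentrations > who_limit).astype(float)


def _train_binary(
    net: Network,
    scores: np.ndarray,
    y: np.ndarray,
    cfg: TransferConfig,
    epochs: int,
    rng: np.random.Generator,
) -> list[float]:
    X = np.ascontiguousarray(scores[:, None, :])
    opt = Adam(lr=cfg.learning_rate)
    history = []
    for _ in range(epochs):
        order = rng.permutation(len(y))
        total = 0.0
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            prob = net.forward(X[batch], training=True).ravel()
            loss, grad = bce_loss(prob, y[batch])
            net.backward(grad[:, None])
            opt.step(net)
            total += loss * batch.size
        history.append(total / len(y))
    return history


def pretrain_binary(
    fm_di: FeatureMatrix, cfg: TransferConfig = TransferConfig(), epochs: int | None = None
) -> Network:
    """Pretrain the binary safety model on DI-water score rows."""
    y = binary_labels(fm_di, cfg.who_limit)
    if len(np.unique(y)) < 2:
        raise ValueError("pretraining data must contain both binary classes")
    net = build_binary_cnn(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    net.history = _train_binary(
        net, fm_di.scores, y, cfg, epochs if epochs is not None else cfg.max_epochs, rng
    )
    return net


def fine_tune(
    net: Network,
    fm_new: FeatureMatrix,
    cfg: TransferConfig = TransferConfig(),
    epochs: int | None = None,
) -> Network:
    """Fine-tune on a new water matrix with conv layers 3-4 frozen.

    Exactly ``finetune_n_per_class`` rows per spiked class are used (a
    seeded subsample when more are supplied; fewer is an error).  Frozen
    layers are restored bit-identically afterwards regardless of gradient
    bookkeeping, making the freeze audit exact.  ``epochs=0`` returns the
    model untouched.
    """
    epochs = cfg.max_epochs if epochs is None else epochs
    if epochs == 0:
        return net
    rng = np.random.default_rng(cfg.seed + 2)
    idx_parts = []
    for cls, n in sorted(fm_new.class_counts.items()):
        if n < cfg.finetune_n_per_class:
            raise ValueError(
                f"class {cls}: {n} spectra < finetune_n_per_class="
                f"{cfg.finetune_n_per_class}"
            )
        idx = np.flatnonzero(fm_new.labels == cls)
        idx_parts.append(rng.choice(idx, cfg.finetune_n_per_class, replace=False))
    sub = fm_new.subset(np.concatenate(idx_parts))
    y = binary_labels(sub, cfg.who_limit)
    convs = _conv_layers(net)
    frozen = [convs[i - 1] for i in cfg.frozen_conv_layers]
    saved = [{k: v.copy() for k, v in layer.params.items()} for layer in frozen]
    for layer in frozen:
        layer.trainable = False
    try:
        net.history_finetune = _train_binary(net, sub.scores, y, cfg, epochs, rng)
    finally:
        for layer, params in zip(frozen, saved):
            for k, v in params.items():
                layer.params[k][...] = v
        for layer in frozen:
            layer.trainable = True
    return net


def predict_proba(net: Network, scores: np.ndarray) -> np.ndarray:
    """Per-spectrum probability that the sample is above the WHO limit."""
    X = np.ascontiguousarray(np.asarray(scores, float)[:, None, :])
    return net.forward(X, training=False).ravel()


def binary_accuracy(net: Network, fm: FeatureMatrix, who_limit: float) -> float:
    """Fraction of rows classified on the correct side of the limit."""
    prob = predict_proba(net, fm.scores)
    return float(np.mean((prob >= 0.5) == binary_labels(fm, who_limit).astype(bool)))


def classify_water_sample(net: Network, scores: np.ndarray) -> dict:
    """Majority-vote verdict for one (unspiked) sample.

    Each spectrum votes "above" when its probability is >= 0.5; the verdict
    is the majority, with exact ties resolved to "above" (the conservative
    call).  Returns the verdict, the fraction voting below, and the count.
    """
    scores = np.atleast_2d(np.asarray(scores, float))
    if scores.shape[0] < 1:
        raise ValueError("need at least one spectrum")
    prob = predict_proba(net, scores)
    below = prob < 0.5
    frac_below = float(below.mean())
    verdict = "below" if frac_below > 0.5 else "above"
    return {
        "verdict": verdict,
        "fraction_below": frac_below,
        "n_spectra": int(scores.shape[0]),
    }
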