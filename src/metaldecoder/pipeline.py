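"""End-to-end experiment orchestration with seeding and provenance.

Reproduces the study's four experiment shapes on synthetic (or user)
data: multiclass SVM concentration classification with a classification
LOD, binary Cr-vs-As metal-type classification, 1-D CNN concentration
regression with LOB/LOD/LOQ, and the transfer-learning above/below-WHO
verdict on a new water matrix.  One top-level seed fans out to per-stage
child seeds through ``numpy.random.SeedSequence``, so each stage is
independently reproducible and two runs of the same config produce
identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .core_io import Metal, SpectralDataset, WaterMatrix
from .cnn_regression import (
    CnnRegressorSpec,
    box_stats,
    build_cnn,
    determine_limits,
    evaluate_regression,
    predict,
    train_cnn,
)
from .features import (
    FeatureMatrix,
    downsample_class,
    fit_pca,
    project,
    smote_oversample,
)
from .preprocess import PreprocessParams, preprocess_dataset
from .svm_models import (
    SvmConfig,
    determine_lod_classification,
    evaluate_classifier,
    stratified_split,
    train_svm,
)
from .syndata import (
    GeneratorConfig,
    as_concentration_ladder,
    cr_concentration_ladder,
    make_matrix_shifted,
    full_layout_config,
    small_layout_config,
)
from .transfer_learning import (
    TransferConfig,
    binary_accuracy,
    classify_water_sample,
    fine_tune,
    pretrain_binary,
)

__all__ = ["RunConfig", "run_experiment", "log_provenance", "stage_seeds"]

EXPERIMENTS = ("svm_concentration", "metal_type", "cnn_regression", "transfer_verdict")


@dataclass(frozen=True)
class RunConfig:
    """Top-level configuration of one experiment run."""

    experiment: str = "svm_concentration"
    metal: Metal = Metal.CR6
    seed: int = 0
    spectra_per_class: int = 100
    n_components: int = 22
    holdout_frac: float = 0.2
    smote_k: int = 5
    cnn_epochs: int = 10
    transfer_matrix: WaterMatrix = WaterMatrix.TAP
    output_dir: str | None = None
    preprocess: PreprocessParams = PreprocessParams()

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.experiment!r}; choose from {EXPERIMENTS}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "metal" in raw:
            raw["metal"] = Metal(raw["metal"])
        if "transfer_matrix" in raw:
            raw["transfer_matrix"] = WaterMatrix(raw["transfer_matrix"])
        if "preprocess" in raw:
            raw["preprocess"] = PreprocessParams(**raw["preprocess"])
        return cls(**raw)


def stage_seeds(seed: int, n: int = 8) -> list[int]:
    """Fan one top-level seed out to independent per-stage child seeds."""
    return [int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(seed).spawn(n)]


def _config_hash(cfg: RunConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return str(o)

    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def log_provenance(cfg: RunConfig) -> dict:
    """Deterministic provenance record embedded in every report."""
    import sklearn

    return {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "sklearn_version": sklearn.__version__,
        "seed": cfg.seed,
        "stage_seeds": stage_seeds(cfg.seed),
        "config_hash": _config_hash(cfg),
        "experiment": cfg.experiment,
    }


def split_dataset(
    ds: SpectralDataset, holdout_frac: float, seed: int
) -> tuple[SpectralDataset, SpectralDataset]:
    """Per-class stratified split at the spectrum level."""
    labels = ds.labels()
    rng = np.random.default_rng(seed)
    train_idx, hold_idx = [], []
    for cls in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == cls))
        n_hold = int(round(holdout_frac * idx.size))
        hold_idx.append(idx[:n_hold])
        train_idx.append(idx[n_hold:])
    tr = np.sort(np.concatenate(train_idx))
    ho = np.sort(np.concatenate(hold_idx))
    prov = dict(ds.provenance)
    return (
        SpectralDataset([ds.spectra[i] for i in tr], provenance=prov),
        SpectralDataset([ds.spectra[i] for i in ho], provenance=prov),
    )


def _generator_for(cfg: RunConfig, seed: int, metal=None, concentrations=None) -> GeneratorConfig:
    metal = metal or cfg.metal
    if cfg.spectra_per_class == 1200:
        gen = full_layout_config(metal, seed=seed)
        if concentrations is not None:
            gen = replace(gen, concentrations=tuple(sorted(concentrations)))
        return gen
    return small_layout_config(
        metal,
        seed=seed,
        spectra_per_class=cfg.spectra_per_class,
        concentrations=concentrations,
    )


def _features_for(
    train_ds: SpectralDataset,
    hold_ds: SpectralDataset,
    n_components: int,
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Fit PCA on the training partition only; project both partitions."""
    basis = fit_pca(train_ds, n_components=n_components)
    return project(train_ds, basis), project(hold_ds, basis)


def _cm_to_lists(cm) -> dict:
    return {"classes": cm.classes.tolist(), "counts": cm.counts.tolist()}


def _run_svm_concentration(cfg: RunConfig, seeds: list[int]) -> dict:
    gen = _generator_for(cfg, seeds[0])
    ds = preprocess_dataset(simulate(gen), cfg.preprocess)
    train_ds, hold_ds = split_dataset(ds, cfg.holdout_frac, seeds[1])
    train, hold = _features_for(train_ds, hold_ds, cfg.n_components)
    target = max(train.class_counts.values())
    train = smote_oversample(
        train, {c: target for c in train.class_counts}, k=cfg.smote_k, rng=seeds[2]
    )
    clf = train_svm(train, SvmConfig(seed=seeds[3]))
    cm, metrics = evaluate_classifier(clf, hold)
    lod, fractions = determine_lod_classification(cm, sorted(gen.concentrations))
    return {
        "confusion": _cm_to_lists(cm),
        "metrics": metrics.as_dict(),
        "holdout_accuracy": float(np.trace(cm.counts) / cm.counts.sum()),
        "lod_molar": lod,
        "control_confusion_fractions": fractions,
    }


def _run_metal_type(cfg: RunConfig, seeds: list[int]) -> dict:
    # pooled binary problem over the sub-decade ranges spanning each LOD
    cr_conc = cr_concentration_ladder()[:7]  # 0.68 pM .. 0.68 uM
    as_conc = as_concentration_ladder()[2:9]  # 0.5 pM .. 0.5 uM
    parts = []
    for metal, conc, seed in (
        (Metal.CR6, cr_conc, seeds[0]),
        (Metal.AS3, as_conc, seeds[1]),
    ):
        gen = _generator_for(cfg, seed, metal=metal, concentrations=conc)
        gen = replace(gen, n_control_surfaces=1)
        ds = preprocess_dataset(simulate(gen), cfg.preprocess)
        # exposure classes only: the task is metal identity, not dose
        keep = [s for s in ds if s.meta.class_index > 0]
        parts.append(split_dataset(SpectralDataset(keep), cfg.holdout_frac, seeds[2]))
    train_ds = SpectralDataset(parts[0][0].spectra + parts[1][0].spectra)
    hold_ds = SpectralDataset(parts[0][1].spectra + parts[1][1].spectra)
    basis = fit_pca(train_ds, n_components=cfg.n_components)
    train, hold = project(train_ds, basis), project(hold_ds, basis)
    train.labels = np.array([0 if s.meta.metal == Metal.CR6 else 1 for s in train_ds])
    hold.labels = np.array([0 if s.meta.metal == Metal.CR6 else 1 for s in hold_ds])
    clf = train_svm(train, SvmConfig(seed=seeds[3]))
    cm, metrics = evaluate_classifier(clf, hold)
    return {
        "confusion": _cm_to_lists(cm),
        "metrics": metrics.as_dict(),
        "holdout_accuracy": float(np.trace(cm.counts) / cm.counts.sum()),
    }


def _run_cnn_regression(cfg: RunConfig, seeds: list[int]) -> dict:
    gen = _generator_for(cfg, seeds[0])
    ds = preprocess_dataset(simulate(gen), cfg.preprocess)
    train_ds, hold_ds = split_dataset(ds, cfg.holdout_frac, seeds[1])
    train, hold = _features_for(train_ds, hold_ds, cfg.n_components)
    target = max(train.class_counts.values())
    train = smote_oversample(
        train, {c: target for c in train.class_counts}, k=cfg.smote_k, rng=seeds[2]
    )
    spec = CnnRegressorSpec(seed=seeds[3], max_epochs=cfg.cnn_epochs)
    net = build_cnn(spec)
    history = train_cnn(net, train, spec=spec)
    mse, r2 = evaluate_regression(net, hold)
    # balance the control for the prediction-interval views
    n_class_hold = min(
        n for c, n in hold.class_counts.items() if c > 0
    )
    hold_bal = hold
    if hold.class_counts.get(0, 0) > n_class_hold:
        hold_bal = downsample_class(hold, 0, n_class_hold, rng=seeds[4])
    preds = predict(net, hold_bal.scores)
    by_class = {
        int(c): preds[hold_bal.labels == c] for c in np.unique(hold_bal.labels)
    }
    limits = determine_limits(
        by_class,
        sorted(gen.concentrations),
        min_predictions=min(20, min(len(v) for v in by_class.values())),
    )
    return {
        "mse": mse,
        "r2": r2,
        "n_holdout": len(hold),
        "loss_history": history,
        "limits": {
            "lob": list(limits.lob),
            "lod_molar": limits.lod,
            "loq_molar": limits.loq,
            "dynamic_range_molar": list(limits.dynamic_range)
            if limits.dynamic_range
            else None,
            "intervals": {str(k): list(v) for k, v in limits.intervals.items()},
        },
        "box_stats": {str(k): v for k, v in box_stats(by_class).items()},
    }


def _run_transfer_verdict(cfg: RunConfig, seeds: list[int]) -> dict:
    # the fine-tuning budget is 80 spectra/class when the layout provides
    # them, otherwise the training partition's per-class size
    n_fine = min(80, int(round(cfg.spectra_per_class * (1 - cfg.holdout_frac))))
    tcfg = TransferConfig(seed=seeds[0], finetune_n_per_class=n_fine)
    pretrain_conc = list(tcfg.pretrain_below) + list(tcfg.pretrain_above)
    finetune_conc = [1.3e-9, 13e-9, 1.3e-6]  # tap-water spiking scheme
    base = _generator_for(cfg, seeds[1], metal=Metal.AS3, concentrations=pretrain_conc)
    base = replace(base, n_control_surfaces=1)
    di = preprocess_dataset(simulate(base), cfg.preprocess)
    di_train_ds, di_hold_ds = split_dataset(di, cfg.holdout_frac, seeds[2])
    basis = fit_pca(di_train_ds, n_components=cfg.n_components)
    di_train = project(di_train_ds, basis)
    spiked = di_train.subset(np.flatnonzero(di_train.labels > 0))
    net = pretrain_binary(spiked, tcfg, epochs=cfg.cnn_epochs)

    shifted_gen = _generator_for(
        cfg, seeds[3], metal=Metal.AS3, concentrations=finetune_conc
    )
    shifted_gen = replace(shifted_gen, n_control_surfaces=1)
    shifted_gen = make_matrix_shifted(shifted_gen, cfg.transfer_matrix)
    new = preprocess_dataset(simulate(shifted_gen), cfg.preprocess)
    new_train_ds, new_hold_ds = split_dataset(new, cfg.holdout_frac, seeds[4])
    new_train = project(new_train_ds, basis)
    new_hold = project(new_hold_ds, basis)
    spiked_hold = new_hold.subset(np.flatnonzero(new_hold.labels > 0))
    frozen_acc = binary_accuracy(net, spiked_hold, tcfg.who_limit)
    fine_tune(
        net,
        new_train.subset(np.flatnonzero(new_train.labels > 0)),
        tcfg,
        epochs=cfg.cnn_epochs,
    )
    tuned_acc = binary_accuracy(net, spiked_hold, tcfg.who_limit)
    unspiked = new_hold.subset(np.flatnonzero(new_hold.labels == 0))
    verdict = classify_water_sample(net, unspiked.scores)
    return {
        "pretrained_accuracy_on_shifted": frozen_acc,
        "finetuned_accuracy_on_shifted": tuned_acc,
        "n_shifted_holdout": len(spiked_hold),
        "unspiked_verdict": verdict,
        "who_limit_molar": tcfg.who_limit,
        "matrix": cfg.transfer_matrix.value,
    }


def simulate(gen: GeneratorConfig) -> SpectralDataset:
    from .syndata import simulate_dataset

    return simulate_dataset(gen)


_RUNNERS = {
    "svm_concentration": _run_svm_concentration,
    "metal_type": _run_metal_type,
    "cnn_regression": _run_cnn_regression,
    "transfer_verdict": _run_transfer_verdict,
}


def run_experiment(cfg: RunConfig) -> dict:
    """Execute one experiment; returns (and optionally writes) the report."""
    seeds = stage_seeds(cfg.seed)
    try:
        report = _RUNNERS[cfg.experiment](cfg, seeds)
    except Exception as exc:
        raise RuntimeError(f"experiment {cfg.experiment!r} failed: {exc}") from exc
    report["provenance"] = log_provenance(cfg)
    if cfg.output_dir:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        if "confusion" in report:
            cmr = report["confusion"]
            lines = [",".join(map(str, ["true\\pred"] + cmr["classes"]))]
            for cls, row in zip(cmr["classes"], cmr["counts"]):
                lines.append(",".join(map(str, [cls] + row)))
            (out / "confusion.csv").write_text("\n".join(lines) + "\n")
    return report
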