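"""Published full-data performance figures, kept as replication targets.

These numbers were measured on the deposited experimental campaign
(Zenodo, doi:10.5281/zenodo.7109184) of roughly 20,000 lysate spectra per
metal.  They depend on the real instrument noise, surface chemistry and
biology, so they are *not* expected from synthetic data and nothing in
this package's test suite asserts them; they are recorded so that a user
who downloads the archive can check the pipeline against them.
"""

from __future__ import annotations

FULL_DATA_TARGETS: dict[str, object] = {
    # SVM concentration classification, above the LOD (fractional metrics)
    "svm_min_sensitivity_specificity_accuracy": 0.97,
    # binary Cr vs As SVM accuracy
    "metal_type_accuracy": 0.988,
    # CNN regression on the SMOTE-balanced (7,680/class) training set
    "cnn_mse": {"As3": 0.09, "Cr6": 0.11},
    "cnn_r2": {"As3": 0.99, "Cr6": 0.99},
    # detection/quantification limits, mol/L
    "lod_molar": {"Cr6": 6.8e-12, "As3": 5e-13},
    "loq_molar": {"Cr6": 6.8e-11, "As3": 5e-12},
    "dynamic_range_molar": {"Cr6": (6.8e-11, 68e-6), "As3": (5e-12, 5e-3)},
    # transfer-learning verdicts on unseen matrices
    "tap_water_accuracy": 0.99,
    "wastewater_unspiked_below_fraction": 0.92,
}
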