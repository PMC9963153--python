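"""Spectral preprocessing: AsLS baseline, Savitzky-Golay smoothing, Si normalization.

The chain is applied in the fixed order baseline -> smooth -> normalize, so
the silicon internal-standard maximum is exactly 1 in the output.  Baseline
estimation uses asymmetric least squares (AsLS): the baseline ``z`` minimises

    sum_i w_i (y_i - z_i)^2 + lambda * sum_i (Delta^2 z_i)^2

with asymmetric weights ``w_i = p`` where ``y_i > z_i`` (points above the
baseline, i.e. peaks, barely pull it up) and ``w_i = 1 - p`` elsewhere,
re-iterated a fixed number of times.  The quadratic subproblem is a
symmetric pentadiagonal system solved with a banded Cholesky factorisation.

Raman spectra have no universal (lambda, p) — the defaults here are the
standard chemometric choices and every knob is exposed in
:class:`PreprocessParams`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import solveh_banded
from scipy.signal import savgol_filter

from .core_io import Spectrum, SpectralDataset

__all__ = [
    "PreprocessParams",
    "NormalizationError",
    "baseline_asls",
    "smooth_savgol",
    "normalize_silicon",
    "preprocess_spectrum",
    "preprocess_dataset",
]


class NormalizationError(ValueError):
    """Raised when the silicon internal-standard window carries no signal."""


@dataclass(frozen=True)
class PreprocessParams:
    """Knobs of the preprocessing chain.

    asls_lambda
        Baseline smoothness weight (larger -> stiffer baseline).
    asls_p
        Asymmetry in (0, 1); small values let peaks float above the baseline.
    asls_iters
        Number of weight re-estimation passes.
    savgol_window, savgol_order
        Smoothing window (odd, in grid points) and local polynomial order.
    si_center, si_halfwidth
        Internal-standard search window in cm^-1; the window *maximum* is the
        normalization reference, tolerating small calibration shifts.
    """

    asls_lambda: float = 1e5
    asls_p: float = 0.01
    asls_iters: int = 10
    savgol_window: int = 11
    savgol_order: int = 3
    si_center: float = 520.0
    si_halfwidth: float = 15.0

    def __post_init__(self) -> None:
        if self.asls_lambda <= 0:
            raise ValueError("asls_lambda must be positive")
        if not 0.0 < self.asls_p < 1.0:
            raise ValueError("asls_p must lie in (0, 1)")
        if self.asls_iters < 1:
            raise ValueError("asls_iters must be >= 1")
        if self.savgol_window < 3 or self.savgol_window % 2 == 0:
            raise ValueError("savgol_window must be an odd integer >= 3")
        if self.savgol_order >= self.savgol_window:
            raise ValueError("savgol_order must be smaller than savgol_window")


def _second_difference_banded(n: int, lam: float) -> np.ndarray:
    """Upper banded form (bandwidth 2) of lambda * D2^T D2 for n points."""
    ab = np.zeros((3, n))
    # interior stencil of D2^T D2 is [1, -4, 6, -4, 1]; edges truncate
    d0 = np.full(n, 6.0)
    d0[[0, -1]] = 1.0
    d0[[1, -2]] = 5.0
    d1 = np.full(n - 1, -4.0)
    d1[[0, -1]] = -2.0
    d2 = np.full(n - 2, 1.0)
    if n < 5:  # tiny systems: build densely and read the bands off
        import numpy.linalg  # noqa: F401
        D = np.diff(np.eye(n), 2, axis=0)
        M = D.T @ D
        d0 = np.diag(M).astype(float)
        d1 = np.diag(M, 1).astype(float)
        d2 = np.diag(M, 2).astype(float) if n >= 3 else np.zeros(0)
    ab[0, 2:] = lam * d2
    ab[1, 1:] = lam * d1
    ab[2, :] = lam * d0
    return ab


def baseline_asls(
    s: Spectrum, params: PreprocessParams = PreprocessParams()
) -> tuple[Spectrum, Spectrum]:
    """Estimate and subtract an AsLS baseline; returns (corrected, baseline)."""
    y = s.intensities
    if y.size < 3:
        raise ValueError("AsLS needs at least 3 points")
    if not np.all(np.isfinite(y)):
        raise ValueError("intensities must be finite")
    penalty = _second_difference_banded(y.size, params.asls_lambda)
    w = np.ones_like(y)
    z = y
    for _ in range(params.asls_iters):
        ab = penalty.copy()
        ab[2, :] += w
        z = solveh_banded(ab, w * y, lower=False)
        w = np.where(y > z, params.asls_p, 1.0 - params.asls_p)
    return s.with_intensities(y - z), s.with_intensities(z)


def smooth_savgol(s: Spectrum, params: PreprocessParams = PreprocessParams()) -> Spectrum:
    """Savitzky-Golay smoothing; endpoints by polynomial edge-fit extrapolation."""
    if params.savgol_window > len(s):
        raise ValueError(
            f"savgol_window {params.savgol_window} exceeds spectrum length {len(s)}"
        )
    smoothed = savgol_filter(
        s.intensities, params.savgol_window, params.savgol_order, mode="interp"
    )
    return s.with_intensities(smoothed)


def normalize_silicon(
    s: Spectrum, params: PreprocessParams = PreprocessParams()
) -> Spectrum:
    """Divide by the maximum intensity in the Si internal-standard window."""
    window = np.abs(s.wavenumbers - params.si_center) <= params.si_halfwidth
    if not window.any():
        raise NormalizationError(
            f"Si window {params.si_center}±{params.si_halfwidth} cm^-1 "
            "does not intersect the grid"
        )
    ref = s.intensities[window].max()
    if ref <= 0:
        raise NormalizationError("Si window maximum is nonpositive")
    return s.with_intensities(s.intensities / ref)


def preprocess_spectrum(s: Spectrum, params: PreprocessParams = PreprocessParams()) -> Spectrum:
    """Baseline-correct, smooth, then normalize one spectrum."""
    corrected, _ = baseline_asls(s, params)
    return normalize_silicon(smooth_savgol(corrected, params), params)


def preprocess_dataset(
    ds: SpectralDataset, params: PreprocessParams = PreprocessParams()
) -> SpectralDataset:
    """Apply the full chain to every spectrum; parameters go into provenance.

    The chain is not idempotent (a second baseline pass removes real signal);
    re-application is allowed but warned about via the provenance record.
    """
    if ds.provenance.get("preprocess") is not None:
        warnings.warn(
            "dataset was already preprocessed; applying the chain again "
            "is not idempotent",
            stacklevel=2,
        )
    out = []
    for i, s in enumerate(ds):
        try:
            out.append(preprocess_spectrum(s, params))
        except (ValueError, NormalizationError) as exc:
            raise type(exc)(f"spectrum {i} ({s.meta.surface_id}/{s.meta.map_id}): {exc}")
    provenance = dict(ds.provenance)
    provenance["preprocess"] = {
        "asls_lambda": params.asls_lambda,
        "asls_p": params.asls_p,
        "asls_iters": params.asls_iters,
        "savgol_window": params.savgol_window,
        "savgol_order": params.savgol_order,
        "si_center": params.si_center,
        "si_halfwidth": params.si_halfwidth,
    }
    return SpectralDataset(out, provenance=provenance)
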