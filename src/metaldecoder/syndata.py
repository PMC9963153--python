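"""Synthetic lysate-SERS dataset generator.

Emulates the acquisition layout of the chromium/arsenic exposure study this
package analyses: per concentration class, Raman maps of fixed size are
acquired on a SERS surface; the unexposed control is pooled from several
surfaces measured in biological duplicate, making it several times larger
than any exposure class.  Spectra are sums of Lorentzian metabolite bands on
a smooth baseline plus a silicon internal-standard line at 520 cm^-1,
scaled by multiplicative log-normal surface and replicate gains and
degraded with additive Gaussian noise.

Metabolite band amplitudes follow a Hill dose-response in the exposure
concentration, so class structure is monotone and learnable — the property
every downstream model stage assumes of real lysate data.  Surface gains
are exactly what silicon normalization must cancel, so the generator also
exercises the preprocessing chain rather than handing it clean data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core_io import Metal, Salt, SampleMeta, Spectrum, SpectralDataset, WaterMatrix

__all__ = [
    "PeakSpec",
    "GeneratorConfig",
    "dose_response",
    "lorentzian",
    "simulate_spectrum",
    "simulate_dataset",
    "make_matrix_shifted",
    "cr_concentration_ladder",
    "as_concentration_ladder",
    "default_peak_library",
    "full_layout_config",
    "small_layout_config",
]

#: Canonical synthetic grid: 300-1800 cm^-1 at 1 cm^-1 spacing, covering the
#: Si 520 cm^-1 internal standard and the dominant 700-750 cm^-1 band.
DEFAULT_GRID = (300.0, 1800.0, 1.0)


def cr_concentration_ladder() -> list[float]:
    """Nine Cr6+ decades, 0.68 pM to 68 uM."""
    return [0.68e-12 * 10**i for i in range(9)]


def as_concentration_ladder() -> list[float]:
    """Thirteen As3+ decades, 5 fM to 5 mM."""
    return [5e-15 * 10**i for i in range(13)]


@dataclass(frozen=True)
class PeakSpec:
    """One Lorentzian band with a Hill dose-response of its amplitude.

    Parameters
    ----------
    center, width
        Band position and FWHM in cm^-1.
    base_amplitude
        Peak height (a.u.) at zero exposure.
    response_direction
        +1 for bands that grow with exposure, -1 for bands that are depleted.
    hill_K, hill_h
        Half-effect concentration (mol/L) and Hill slope of the response.
    max_fold_change
        Saturating fractional amplitude change; 0 makes the band inert.
    """

    center: float
    width: float
    base_amplitude: float
    response_direction: int = 1
    hill_K: float = 1.0
    hill_h: float = 1.0
    max_fold_change: float = 0.0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("width must be positive")
        if self.hill_K <= 0 or self.hill_h <= 0:
            raise ValueError("hill_K and hill_h must be positive")
        if self.max_fold_change < 0:
            raise ValueError("max_fold_change must be nonnegative")
        if self.response_direction not in (-1, 1):
            raise ValueError("response_direction must be +1 or -1")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full description of one synthetic acquisition campaign."""

    metal: Metal
    concentrations: tuple[float, ...]
    n_maps_per_class: int = 3
    map_shape: tuple[int, int] = (20, 20)
    n_control_surfaces: int = 8
    peak_library: tuple[PeakSpec, ...] = ()
    si_line: PeakSpec = PeakSpec(center=520.0, width=8.0, base_amplitude=5.0)
    baseline_offset: float = 0.3
    baseline_slope: float = -0.1
    baseline_gauss_amplitude: float = 0.5
    baseline_gauss_center: float = 1100.0
    baseline_gauss_width: float = 500.0
    noise_sd: float = 0.05
    surface_gain_sd: float = 0.15
    replicate_gain_sd: float = 0.05
    matrix: WaterMatrix = WaterMatrix.DI
    matrix_background: tuple[PeakSpec, ...] = ()
    grid: tuple[float, float, float] = DEFAULT_GRID
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_maps_per_class < 1:
            raise ValueError("n_maps_per_class must be >= 1")
        if min(self.map_shape) < 1:
            raise ValueError("map_shape entries must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("exposure concentrations must be positive")

    def wavenumbers(self) -> np.ndarray:
        lo, hi, step = self.grid
        return np.arange(lo, hi + step / 2, step)

    @property
    def spectra_per_class(self) -> int:
        return self.n_maps_per_class * self.map_shape[0] * self.map_shape[1]


def dose_response(c: float, pk: PeakSpec) -> float:
    """Band amplitude at exposure concentration ``c`` (mol/L).

    ``base * (1 + direction * max_fold_change * c^h / (K^h + c^h))``,
    clipped at zero.  Monotone in ``c``; equals ``base`` at ``c = 0`` and
    saturates at ``base * (1 ± max_fold_change)``.
    """
    if c < 0:
        raise ValueError("concentration must be nonnegative")
    if c == 0.0:
        return pk.base_amplitude
    # work in log space to avoid overflow across the fM..mM ladder
    logt = pk.hill_h * (math.log(c) - math.log(pk.hill_K))
    occ = 1.0 / (1.0 + math.exp(-logt))
    amp = pk.base_amplitude * (1.0 + pk.response_direction * pk.max_fold_change * occ)
    return max(amp, 0.0)


def lorentzian(wavenumbers: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    """Unit-height Lorentzian profile."""
    hwhm = fwhm / 2.0
    return 1.0 / (1.0 + ((wavenumbers - center) / hwhm) ** 2)


def _baseline(cfg: GeneratorConfig, wn: np.ndarray) -> np.ndarray:
    lo, hi, _ = cfg.grid
    t = (wn - lo) / (hi - lo)
    gauss = cfg.baseline_gauss_amplitude * np.exp(
        -0.5 * ((wn - cfg.baseline_gauss_center) / cfg.baseline_gauss_width) ** 2
    )
    return cfg.baseline_offset + cfg.baseline_slope * t + gauss


def noiseless_signal(cfg: GeneratorConfig, c: float) -> np.ndarray:
    """Deterministic part of a unit-gain spectrum at concentration ``c``."""
    wn = cfg.wavenumbers()
    signal = _baseline(cfg, wn)
    for pk in cfg.peak_library:
        signal = signal + dose_response(c, pk) * lorentzian(wn, pk.center, pk.width)
    for pk in cfg.matrix_background:
        signal = signal + pk.base_amplitude * lorentzian(wn, pk.center, pk.width)
    signal = signal + cfg.si_line.base_amplitude * lorentzian(
        wn, cfg.si_line.center, cfg.si_line.width
    )
    return signal


def simulate_spectrum(
    cfg: GeneratorConfig,
    c: float,
    surface_gain: float = 1.0,
    replicate_gain: float = 1.0,
    rng: np.random.Generator | None = None,
    meta: SampleMeta | None = None,
) -> Spectrum:
    """One spectrum: gain * (baseline + bands + Si line) + Gaussian noise."""
    rng = rng or np.random.default_rng(cfg.seed)
    signal = surface_gain * replicate_gain * noiseless_signal(cfg, c)
    if cfg.noise_sd > 0:
        signal = signal + rng.normal(0.0, cfg.noise_sd, signal.size)
    np.clip(signal, 0.0, None, out=signal)
    return Spectrum(cfg.wavenumbers(), signal, meta or SampleMeta())


def _salt_for(metal: Metal) -> Salt:
    return {Metal.CR6: Salt.K2CR2O7, Metal.AS3: Salt.NAASO2, Metal.NONE: Salt.NONE}[metal]


def simulate_dataset(cfg: GeneratorConfig) -> SpectralDataset:
    """Generate the full campaign: control plus one class per concentration.

    Each nonzero class contributes ``n_maps_per_class * rows * cols`` spectra
    acquired on one surface (surfaces cycle through the control-surface pool,
    mirroring shared-surface acquisition).  The control pools
    ``n_control_surfaces`` surfaces, maps alternating between two biological
    replicates, each (surface, replicate) pair with its own log-normal gain.
    Fully deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    rows, cols = cfg.map_shape
    n_pts = rows * cols
    surfaces = [f"S{i + 1}" for i in range(cfg.n_control_surfaces)]
    surface_gain = {
        s: float(np.exp(rng.normal(0.0, cfg.surface_gain_sd))) for s in surfaces
    }
    replicate_gain = {
        (s, r): float(np.exp(rng.normal(0.0, cfg.replicate_gain_sd)))
        for s in surfaces
        for r in ("R1", "R2")
    }
    salt = _salt_for(cfg.metal)
    spectra: list[Spectrum] = []
    wn = cfg.wavenumbers()  # one shared grid array for the whole campaign
    signal_cache: dict[float, np.ndarray] = {}

    def acquire(c: float, class_index: int, surface: str, replicate: str, map_id: str):
        meta = SampleMeta(
            metal=cfg.metal if class_index else Metal.NONE,
            salt=salt if class_index else Salt.NONE,
            concentration_molar=c,
            class_index=class_index,
            surface_id=surface,
            replicate_id=replicate,
            map_id=map_id,
            matrix=cfg.matrix,
        )
        if c not in signal_cache:
            signal_cache[c] = noiseless_signal(cfg, c)
        gain = surface_gain[surface] * replicate_gain[(surface, replicate)]
        block = gain * signal_cache[c]
        if cfg.noise_sd > 0:
            block = block + rng.normal(0.0, cfg.noise_sd, (n_pts, wn.size))
        else:
            block = np.broadcast_to(block, (n_pts, wn.size)).copy()
        np.clip(block, 0.0, None, out=block)
        for row in block:
            spectra.append(Spectrum(wn, row, meta))

    # control: every surface, maps alternating between biological duplicates
    for surface in surfaces:
        for m in range(cfg.n_maps_per_class):
            acquire(0.0, 0, surface, f"R{1 + m % 2}", f"M{m + 1}")
    # exposure classes: one surface each, cycling through the pool
    for ci, c in enumerate(sorted(cfg.concentrations), start=1):
        surface = surfaces[(ci - 1) % len(surfaces)]
        for m in range(cfg.n_maps_per_class):
            acquire(c, ci, surface, "R1", f"M{m + 1}")
    return SpectralDataset(spectra, provenance={"generator_seed": cfg.seed})


#: Additive background bands per water matrix (inert: max_fold_change = 0).
_MATRIX_BACKGROUNDS = {
    WaterMatrix.TAP: (
        PeakSpec(center=980.0, width=12.0, base_amplitude=0.35),
        PeakSpec(center=1048.0, width=10.0, base_amplitude=0.25),
    ),
    WaterMatrix.WASTEWATER: (
        PeakSpec(center=980.0, width=14.0, base_amplitude=0.55),
        PeakSpec(center=1048.0, width=10.0, base_amplitude=0.45),
        PeakSpec(center=1350.0, width=60.0, base_amplitude=0.40),
        PeakSpec(center=1590.0, width=50.0, base_amplitude=0.35),
    ),
}

_MATRIX_BASELINE_OFFSET = {WaterMatrix.TAP: 0.15, WaterMatrix.WASTEWATER: 0.35}


def make_matrix_shifted(cfg: GeneratorConfig, matrix: WaterMatrix) -> GeneratorConfig:
    """Config for the same campaign in a different water matrix.

    Adds inert background bands and a baseline offset; the dose-responsive
    metabolite bands and the Si internal standard are untouched.
    """
    matrix = WaterMatrix(matrix)
    if matrix == WaterMatrix.DI:
        return cfg
    if matrix not in _MATRIX_BACKGROUNDS:
        raise ValueError(f"unknown water matrix {matrix!r}")
    return replace(
        cfg,
        matrix=matrix,
        matrix_background=_MATRIX_BACKGROUNDS[matrix],
        baseline_offset=cfg.baseline_offset + _MATRIX_BASELINE_OFFSET[matrix],
    )


def default_peak_library(metal: Metal, concentrations: Sequence[float]) -> tuple[PeakSpec, ...]:
    """Metabolite band library with half-effect points spread over the ladder.

    The dominant responsive band sits in the 700-750 cm^-1 region (consistent
    with the largest PC1 loading of the real lysate data); the remaining
    centers are generic nucleotide/protein-region placeholders.  Spreading
    ``hill_K`` across the decade ladder makes every neighbouring pair of
    classes separable by at least one band, which is how a metabolic stress
    response graded over eight-plus orders of magnitude must behave for
    decade classification to work at all.
    """
    c = sorted(concentrations)

    def K(i: int) -> float:  # clamp to ladder
        return c[min(max(i, 0), len(c) - 1)]

    if Metal(metal) == Metal.AS3:
        # arsenite signature: efflux/ATP-coupled response pattern — partially
        # inverted directions and shifted half-effect points relative to Cr
        return (
            PeakSpec(732.0, 14.0, 2.0, +1, K(2), 0.35, 1.8),
            PeakSpec(660.0, 12.0, 0.8, +1, K(1), 0.40, 0.7),
            PeakSpec(960.0, 12.0, 1.2, -1, K(4), 0.30, 0.5),
            PeakSpec(1003.0, 10.0, 0.9, +1, K(3), 0.35, 0.9),
            PeakSpec(1095.0, 14.0, 1.0, +1, K(5), 0.40, 1.1),
            PeakSpec(1240.0, 16.0, 0.9, +1, K(6), 0.30, 0.6),
            PeakSpec(1320.0, 14.0, 1.1, -1, K(5), 0.35, 0.4),
            PeakSpec(1450.0, 16.0, 0.7, +1, K(8), 0.40, 0.8),
            PeakSpec(1575.0, 14.0, 0.9, +1, K(4), 0.30, 0.5),
        )
    return (
        PeakSpec(725.0, 14.0, 2.0, +1, K(2), 0.35, 2.5),
        PeakSpec(660.0, 12.0, 0.8, -1, K(1), 0.40, 0.6),
        PeakSpec(780.0, 12.0, 0.7, +1, K(3), 0.35, 0.8),
        PeakSpec(960.0, 12.0, 1.2, +1, K(4), 0.30, 1.2),
        PeakSpec(1095.0, 14.0, 1.0, +1, K(6), 0.40, 0.9),
        PeakSpec(1240.0, 16.0, 0.9, -1, K(3), 0.30, 0.5),
        PeakSpec(1320.0, 14.0, 1.1, +1, K(5), 0.35, 0.8),
        PeakSpec(1450.0, 16.0, 0.7, +1, K(7), 0.40, 0.6),
        PeakSpec(1575.0, 14.0, 0.9, -1, K(4), 0.30, 0.4),
    )


def full_layout_config(metal: Metal, seed: int = 0) -> GeneratorConfig:
    """Full acquisition layout: 3 maps of 20x20 per class, 8 control surfaces.

    Yields 1,200 spectra per exposure class and 9,600 control spectra —
    the class structure of the real Cr6+/As3+ campaigns.
    """
    metal = Metal(metal)
    conc = {
        Metal.CR6: cr_concentration_ladder(),
        Metal.AS3: as_concentration_ladder(),
    }[metal]
    return GeneratorConfig(
        metal=metal,
        concentrations=tuple(conc),
        peak_library=default_peak_library(metal, conc),
        seed=seed,
    )


def small_layout_config(
    metal: Metal,
    seed: int = 0,
    spectra_per_class: int = 100,
    concentrations: Sequence[float] | None = None,
    n_control_surfaces: int = 1,
) -> GeneratorConfig:
    """Scaled-down layout for quick studies: same structure, fewer spectra.

    ``spectra_per_class`` must factor as maps x rows x cols; the default 100
    uses 4 maps of 5x5.
    """
    metal = Metal(metal)
    if concentrations is None:
        concentrations = {
            Metal.CR6: cr_concentration_ladder(),
            Metal.AS3: as_concentration_ladder(),
        }[metal]
    if spectra_per_class % 4 == 0:
        side = int(round(math.sqrt(spectra_per_class / 4)))
        if 4 * side * side != spectra_per_class:
            raise ValueError("spectra_per_class must be 4*k^2")
        maps, shape = 4, (side, side)
    else:
        maps, shape = spectra_per_class, (1, 1)
    return GeneratorConfig(
        metal=metal,
        concentrations=tuple(concentrations),
        n_maps_per_class=maps,
        map_shape=shape,
        n_control_surfaces=n_control_surfaces,
        peak_library=default_peak_library(metal, concentrations),
        seed=seed,
    )
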