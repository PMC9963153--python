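"""Data model and file I/O for lysate SERS spectra.

A :class:`Spectrum` is one wavenumber-indexed intensity trace with its
acquisition metadata; a :class:`SpectralDataset` is a labelled collection of
spectra sharing a common grid.  Readers accept the two plain-text layouts in
which instrument exports of this kind circulate: two-column ASCII tables
(wavenumber, intensity) and CSV matrices with a wavenumber header row.
Datasets round-trip through a directory layout of per-spectrum tables plus a
TSV manifest carrying all sample metadata.
"""

from __future__ import annotations

import enum
import io
import os
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Metal",
    "Salt",
    "WaterMatrix",
    "SampleMeta",
    "Spectrum",
    "SpectralDataset",
    "SpectrumFormatError",
    "read_spectrum_table",
    "write_dataset",
    "read_dataset",
    "summarize",
]

#: Relative tolerance for declaring the wavenumber grid uniformly spaced.
GRID_SPACING_RTOL = 1e-6

MANIFEST_NAME = "manifest.tsv"
MANIFEST_COLUMNS = [
    "path",
    "metal",
    "salt",
    "concentration_molar",
    "class_index",
    "surface_id",
    "replicate_id",
    "map_id",
    "matrix",
]


class Metal(str, enum.Enum):
    """Heavy-metal ion the culture was exposed to (``NONE`` for controls)."""

    CR6 = "Cr6"
    AS3 = "As3"
    NONE = "none"


class Salt(str, enum.Enum):
    """Salt used to dose the exposure medium."""

    K2CR2O7 = "K2Cr2O7"
    NAASO2 = "NaAsO2"
    NONE = "none"


class WaterMatrix(str, enum.Enum):
    """Water source the sample was prepared in."""

    DI = "DI"
    TAP = "tap"
    WASTEWATER = "wastewater"


class SpectrumFormatError(ValueError):
    """Raised for malformed spectral tables or inconsistent grids."""


@dataclass(frozen=True)
class SampleMeta:
    """Provenance of a single lysate spectrum.

    ``class_index`` encodes the concentration decade: 0 for the unexposed
    control and ``1 + log10(c / c_min)`` for exposure at concentration ``c``
    when the lowest nonzero concentration of the experiment is ``c_min``.
    """

    metal: Metal = Metal.NONE
    salt: Salt = Salt.NONE
    concentration_molar: float = 0.0
    class_index: int = 0
    surface_id: str = "S1"
    replicate_id: str = "R1"
    map_id: str = "M1"
    matrix: WaterMatrix = WaterMatrix.DI

    def __post_init__(self) -> None:
        if self.concentration_molar < 0:
            raise ValueError("concentration_molar must be nonnegative")
        if self.class_index < 0:
            raise ValueError("class_index must be nonnegative")
        if (self.class_index == 0) != (self.concentration_molar == 0.0):
            raise ValueError(
                "class_index must be 0 exactly for the zero-concentration control "
                f"(got class_index={self.class_index}, "
                f"concentration={self.concentration_molar!r})"
            )


@dataclass
class Spectrum:
    """One SERS intensity trace on a strictly increasing uniform grid."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    meta: SampleMeta = field(default_factory=SampleMeta)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise SpectrumFormatError("wavenumbers and intensities must be 1-D")
        if self.wavenumbers.size != self.intensities.size:
            raise SpectrumFormatError(
                f"length mismatch: {self.wavenumbers.size} wavenumbers vs "
                f"{self.intensities.size} intensities"
            )
        if self.wavenumbers.size >= 2:
            steps = np.diff(self.wavenumbers)
            if np.any(steps <= 0):
                raise SpectrumFormatError("wavenumber grid must be strictly increasing")
            mean_step = steps.mean()
            if np.any(np.abs(steps - mean_step) > GRID_SPACING_RTOL * abs(mean_step)):
                raise SpectrumFormatError("wavenumber grid spacing is not uniform")

    def __len__(self) -> int:
        return self.wavenumbers.size

    def with_intensities(self, intensities: np.ndarray) -> "Spectrum":
        """Copy of this spectrum with replaced intensities (same grid/meta)."""
        return Spectrum(self.wavenumbers.copy(), np.asarray(intensities, float), self.meta)


@dataclass
class SpectralDataset:
    """Spectra sharing one wavenumber grid, with per-class bookkeeping."""

    spectra: list[Spectrum]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.spectra:
            grid = self.spectra[0].wavenumbers
            for i, s in enumerate(self.spectra):
                if s.wavenumbers.shape != grid.shape or not np.array_equal(
                    s.wavenumbers, grid
                ):
                    raise SpectrumFormatError(
                        f"spectrum {i} is not on the shared wavenumber grid"
                    )

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    @property
    def grid(self) -> np.ndarray:
        if not self.spectra:
            return np.empty(0)
        return self.spectra[0].wavenumbers

    @property
    def class_counts(self) -> dict[int, int]:
        return dict(sorted(Counter(s.meta.class_index for s in self.spectra).items()))

    def intensity_matrix(self) -> np.ndarray:
        """Stack intensities into an (n_spectra, n_points) array."""
        if not self.spectra:
            return np.empty((0, 0))
        return np.stack([s.intensities for s in self.spectra])

    def labels(self) -> np.ndarray:
        return np.array([s.meta.class_index for s in self.spectra], dtype=int)

    def concentrations(self) -> np.ndarray:
        return np.array([s.meta.concentration_molar for s in self.spectra])


def _parse_two_column(text: str, origin: str) -> tuple[np.ndarray, np.ndarray]:
    wn: list[float] = []
    inten: list[float] = []
    width = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if width is None:
            width = len(parts)
        if len(parts) != width or len(parts) < 2:
            raise SpectrumFormatError(
                f"{origin}: line {lineno}: expected {width or 2} columns, "
                f"got {len(parts)}"
            )
        try:
            values = [float(p) for p in parts[:2]]
        except ValueError as exc:
            raise SpectrumFormatError(
                f"{origin}: line {lineno}: non-numeric value in {line!r}"
            ) from exc
        wn.append(values[0])
        inten.append(values[1])
    if not wn:
        raise SpectrumFormatError(f"{origin}: no numeric rows found")
    return np.array(wn), np.array(inten)


def _orient_grid(wn: np.ndarray, rows: np.ndarray, origin: str) -> tuple[np.ndarray, np.ndarray]:
    """Force the grid ascending, reversing a monotone-decreasing export."""
    steps = np.diff(wn)
    if wn.size >= 2 and np.all(steps < 0):
        return wn[::-1].copy(), rows[..., ::-1].copy()
    if np.any(steps <= 0):
        raise SpectrumFormatError(f"{origin}: wavenumber grid is not monotone")
    return wn, rows


def read_spectrum_table(
    path: str | os.PathLike,
    dialect: str = "two_column_ascii",
    meta: SampleMeta | None = None,
) -> Spectrum | SpectralDataset:
    """Read a spectral table.

    ``two_column_ascii`` (the deposit format: wavenumber, intensity per row)
    yields a single :class:`Spectrum`; ``csv_matrix`` (header row of
    wavenumbers, one spectrum per data row) yields a
    :class:`SpectralDataset`.  Monotone-decreasing grids — a common
    instrument-export convention — are silently reversed.
    """
    path = Path(path)
    if dialect == "two_column_ascii":
        wn, inten = _parse_two_column(path.read_text(), str(path))
        wn, inten = _orient_grid(wn, inten, str(path))
        return Spectrum(wn, inten, meta or SampleMeta())
    if dialect == "csv_matrix":
        frame = pd.read_csv(path)
        try:
            wn = np.array([float(c) for c in frame.columns])
        except ValueError as exc:
            raise SpectrumFormatError(
                f"{path}: csv_matrix header must be numeric wavenumbers"
            ) from exc
        values = frame.to_numpy(dtype=float)
        wn, values = _orient_grid(wn, values, str(path))
        base = meta or SampleMeta()
        return SpectralDataset([Spectrum(wn, row, base) for row in values])
    raise ValueError(f"unknown dialect {dialect!r}")


def _sort_key(item: tuple[int, Spectrum]):
    pos, s = item
    m = s.meta
    return (m.class_index, m.surface_id, m.replicate_id, m.map_id, pos)


def write_dataset(ds: SpectralDataset, directory: str | os.PathLike) -> Path:
    """Write per-spectrum two-column tables plus a TSV manifest.

    Ordering is deterministic (class, surface, replicate, map, original
    row-major position), so two writes of the same dataset are byte-identical.
    Returns the manifest path.
    """
    if not len(ds):
        raise ValueError("refusing to write an empty dataset")
    directory = Path(directory)
    spectra_dir = directory / "spectra"
    spectra_dir.mkdir(parents=True, exist_ok=True)
    ordered = sorted(enumerate(ds.spectra), key=_sort_key)
    rows = []
    for i, (_, s) in enumerate(ordered):
        rel = f"spectra/spec_{i:06d}.txt"
        buf = io.StringIO()
        for w, y in zip(s.wavenumbers, s.intensities):
            buf.write(f"{w:.10g}\t{y:.12g}\n")
        (directory / rel).write_text(buf.getvalue())
        m = s.meta
        rows.append(
            {
                "path": rel,
                "metal": m.metal.value,
                "salt": m.salt.value,
                "concentration_molar": f"{m.concentration_molar:.12e}",
                "class_index": m.class_index,
                "surface_id": m.surface_id,
                "replicate_id": m.replicate_id,
                "map_id": m.map_id,
                "matrix": m.matrix.value,
            }
        )
    manifest = directory / MANIFEST_NAME
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_dataset(directory: str | os.PathLike) -> SpectralDataset:
    """Read a dataset directory written by :func:`write_dataset`."""
    directory = Path(directory)
    manifest = pd.read_csv(directory / MANIFEST_NAME, sep="\t", dtype=str)
    spectra = []
    for _, row in manifest.iterrows():
        meta = SampleMeta(
            metal=Metal(row["metal"]),
            salt=Salt(row["salt"]),
            concentration_molar=float(row["concentration_molar"]),
            class_index=int(row["class_index"]),
            surface_id=row["surface_id"],
            replicate_id=row["replicate_id"],
            map_id=row["map_id"],
            matrix=WaterMatrix(row["matrix"]),
        )
        spec = read_spectrum_table(directory / row["path"], meta=meta)
        spectra.append(spec)
    return SpectralDataset(spectra)


def summarize(ds: SpectralDataset) -> dict:
    """Per-class and per-surface spectrum counts (totals equal ``len(ds)``)."""
    per_class = Counter()
    per_surface = Counter()
    for s in ds:
        per_class[s.meta.class_index] += 1
        per_surface[s.meta.surface_id] += 1
    return {
        "n_spectra": len(ds),
        "per_class": dict(sorted(per_class.items())),
        "per_surface": dict(sorted(per_surface.items())),
    }
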