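"""Datasets, regions of interest, and standard-format I/O.

The in-memory model is deliberately small: an :class:`IMSDataset` is a
pixel grid of centroided :class:`Spectrum` objects plus spatial metadata.
Disk format is imzML (+ .ibd) via ``pyimzml``; regions of interest and
result tables travel as plain CSV.

Conventions
-----------
* Pixel coordinates are 0-based ``(col, row)`` with the origin at the
  top-left; imzML's 1-based indices are converted on read and write.
* Pixel iteration order is row-major (row by row, column within row) and
  is preserved by a write/read round trip.
* Intensities are float64 in memory and float32 on disk.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from pyimzml.ImzMLParser import ImzMLParser
from pyimzml.ImzMLWriter import ImzMLWriter

__all__ = [
    "Spectrum",
    "IMSDataset",
    "CircleROI",
    "MaskROI",
    "ROISet",
    "read_imzml",
    "write_imzml",
    "read_roi",
    "write_roi",
    "write_table",
]


@dataclass
class Spectrum:
    """One centroided spectrum at one pixel.

    ``mz`` must be strictly increasing; intensities are non-negative and
    the same length as ``mz``.
    """

    mz: np.ndarray
    intensity: np.ndarray
    pixel: tuple[int, int]  # (col, row), 0-based

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("m/z values must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be >= 0")
        col, row = self.pixel
        self.pixel = (int(col), int(row))


@dataclass
class IMSDataset:
    """A grid of centroided spectra with spatial metadata.

    ``grid_shape`` is ``(n_cols, n_rows)``; ``pixel_size`` is in μm
    (100 μm is the typical laser pitch for whole-section work at this
    scale). Not every grid pixel need carry a spectrum (sparse
    acquisition); occupied pixels must lie inside the grid.
    """

    grid_shape: tuple[int, int]
    pixel_size: float
    spectra: list[Spectrum]
    mass_range: tuple[float, float]
    polarity: str = "positive"
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_cols, n_rows = self.grid_shape
        if n_cols < 1 or n_rows < 1:
            raise ValueError("grid_shape must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        lo, hi = self.mass_range
        if not lo < hi:
            raise ValueError("mass_range must satisfy lo < hi")
        if self.polarity not in ("positive", "negative"):
            raise ValueError("polarity must be 'positive' or 'negative'")
        for s in self.spectra:
            col, row = s.pixel
            if not (0 <= col < n_cols and 0 <= row < n_rows):
                raise ValueError(f"pixel {s.pixel} outside grid {self.grid_shape}")
            if s.mz.size and (s.mz[0] < lo or s.mz[-1] > hi):
                raise ValueError(
                    f"spectrum at {s.pixel} outside mass range {self.mass_range}"
                )
        # row-major order: all spectra of row 0 left to right, then row 1 ...
        self.spectra.sort(key=lambda s: (s.pixel[1], s.pixel[0]))

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    def pixel_index(self) -> dict[tuple[int, int], Spectrum]:
        return {s.pixel: s for s in self.spectra}


def read_imzml(path: str | Path) -> IMSDataset:
    """Read an imzML file (continuous or processed mode) into a dataset.

    The binary ``.ibd`` companion must sit next to the XML file. The
    imzML mode is recorded under ``metadata["imzml_mode"]``.
    """
    path = Path(path)
    try:
        parser = ImzMLParser(str(path))
    except IndexError:
        # pyimzml cannot index an empty coordinate list; a file with a
        # zero-spectrum run is still valid imzML
        return _read_empty_imzml(path)
    try:
        n_cols = int(parser.imzmldict.get("max count of pixels x", 0))
        n_rows = int(parser.imzmldict.get("max count of pixels y", 0))
        pixel_size = float(parser.imzmldict.get("pixel size x", 100.0) or 100.0)
        spectra = []
        for i, (x, y, *_z) in enumerate(parser.coordinates):
            mzs, ints = parser.getspectrum(i)
            mzs = np.asarray(mzs, dtype=np.float64)
            ints = np.asarray(ints, dtype=np.float64)
            order = np.argsort(mzs, kind="stable")
            spectra.append(Spectrum(mzs[order], ints[order], (int(x) - 1, int(y) - 1)))
        n_cols = max(n_cols, max((s.pixel[0] for s in spectra), default=0) + 1, 1)
        n_rows = max(n_rows, max((s.pixel[1] for s in spectra), default=0) + 1, 1)
        if spectra:
            lo = min(s.mz[0] for s in spectra if s.mz.size)
            hi = max(s.mz[-1] for s in spectra if s.mz.size)
        else:
            lo, hi = 0.0, 1.0
        metadata = {"imzml_mode": "continuous" if parser.metadata is not None
                    and "continuous" in str(parser.metadata.file_description) else "processed",
                    "source": str(path)}
        return IMSDataset(
            grid_shape=(n_cols, n_rows),
            pixel_size=pixel_size,
            spectra=spectra,
            mass_range=(float(lo), float(hi) if hi > lo else float(lo) + 1.0),
            metadata=metadata,
        )
    finally:
        if hasattr(parser, "m") and parser.m is not None:
            parser.m.close()


def _read_empty_imzml(path: Path) -> IMSDataset:
    import re

    text = path.read_text()
    if '<spectrumList count="0"' not in text:
        raise ValueError(f"{path}: could not parse imzML")

    def _extent(name: str) -> int:
        m = re.search(rf'name="max count of pixels {name}" value="(\d+)"', text)
        return int(m.group(1)) if m else 1

    return IMSDataset(grid_shape=(_extent("x"), _extent("y")),
                      pixel_size=100.0, spectra=[], mass_range=(0.0, 1.0),
                      metadata={"imzml_mode": "processed", "source": str(path)})


def write_imzml(dataset: IMSDataset, path: str | Path) -> Path:
    """Write a dataset to processed-mode imzML (+ .ibd).

    Round trip: ``read_imzml(write_imzml(d, p))`` reproduces every
    spectrum to float32 precision, in the same row-major pixel order.
    A dataset with zero spectra yields a valid file with an empty
    spectrum list (only the grid extent survives its round trip).
    """
    import re

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with ImzMLWriter(str(path), mode="processed",
                     mz_dtype=np.float64, intensity_dtype=np.float32) as writer:
        if dataset.spectra:
            for s in dataset.spectra:
                col, row = s.pixel
                writer.addSpectrum(s.mz, s.intensity, (col + 1, row + 1))
        else:
            # placeholder carrying the grid extent; stripped below so the
            # file records an empty run (pyimzml cannot write zero spectra)
            writer.addSpectrum(np.array([1.0]), np.array([0.0]),
                               dataset.grid_shape)
    if not dataset.spectra:
        text = path.read_text()
        text = re.sub(r"<spectrum .*?</spectrum>\s*", "", text, flags=re.S)
        text = text.replace('<spectrumList count="1"',
                            '<spectrumList count="0"')
        path.write_text(text)
    return path


@dataclass(frozen=True)
class CircleROI:
    """Circular region: pixels with centre distance <= radius (in px)."""

    center: tuple[float, float]  # (col, row)
    radius: float

    def mask(self, grid_shape: tuple[int, int]) -> np.ndarray:
        n_cols, n_rows = grid_shape
        cols, rows = np.meshgrid(np.arange(n_cols), np.arange(n_rows))
        cx, cy = self.center
        return ((cols - cx) ** 2 + (rows - cy) ** 2) <= self.radius**2


@dataclass(frozen=True)
class MaskROI:
    """Explicit pixel-list region."""

    pixels: frozenset[tuple[int, int]]

    def mask(self, grid_shape: tuple[int, int]) -> np.ndarray:
        n_cols, n_rows = grid_shape
        out = np.zeros((n_rows, n_cols), dtype=bool)
        for col, row in self.pixels:
            out[row, col] = True
        return out


@dataclass
class ROISet:
    """Labelled regions, optionally with known spotted amounts (pmol)."""

    regions: dict[str, CircleROI | MaskROI] = field(default_factory=dict)
    known_amount: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, amount in self.known_amount.items():
            if label not in self.regions:
                raise ValueError(f"known_amount for unknown label {label!r}")
            if amount < 0:
                raise ValueError(f"negative amount for {label!r}")

    def add(self, label: str, region: CircleROI | MaskROI,
            amount: float | None = None) -> None:
        if label in self.regions:
            raise ValueError(f"duplicate ROI label {label!r}")
        self.regions[label] = region
        if amount is not None:
            if amount < 0:
                raise ValueError(f"negative amount for {label!r}")
            self.known_amount[label] = float(amount)

    def __len__(self) -> int:
        return len(self.regions)

    def validate_grid(self, grid_shape: tuple[int, int]) -> None:
        n_cols, n_rows = grid_shape
        for label, region in self.regions.items():
            if isinstance(region, CircleROI):
                cx, cy = region.center
                r = region.radius
                inside = (cx - r >= -0.5 and cy - r >= -0.5
                          and cx + r <= n_cols - 0.5 and cy + r <= n_rows - 0.5)
            else:
                inside = all(0 <= c < n_cols and 0 <= r_ < n_rows
                             for c, r_ in region.pixels)
            if not inside:
                raise ValueError(f"ROI {label!r} extends outside grid {grid_shape}")


def read_roi(path: str | Path,
             grid_shape: tuple[int, int] | None = None) -> ROISet:
    """Read a ROI CSV.

    Schema (one region per line, header optional)::

        label,shape,params...,amount

        spot_100pmol,circle,10,10,4,100      # centre (10,10), radius 4, 100 pmol
        airway,mask,3 4;3 5;4 4              # explicit "col row" pixel list

    The trailing amount field is optional. Duplicate labels are an error;
    with ``grid_shape`` given, regions outside the grid are an error.
    """
    roi = ROISet()
    with open(path, newline="") as fh:
        for line_no, rowvals in enumerate(csv.reader(fh), start=1):
            rowvals = [v.strip() for v in rowvals if v.strip() != ""]
            if not rowvals:
                continue
            if line_no == 1 and rowvals[0].lower() == "label":
                continue  # header
            label, shape, *rest = rowvals
            if shape == "circle":
                if len(rest) not in (3, 4):
                    raise ValueError(f"line {line_no}: circle needs cx,cy,r[,amount]")
                cx, cy, r = (float(v) for v in rest[:3])
                amount = float(rest[3]) if len(rest) == 4 else None
                roi.add(label, CircleROI((cx, cy), r), amount)
            elif shape == "mask":
                if len(rest) not in (1, 2):
                    raise ValueError(f"line {line_no}: mask needs pixel list[,amount]")
                pixels = frozenset(
                    tuple(int(v) for v in px.split())
                    for px in rest[0].split(";") if px.strip()
                )
                amount = float(rest[1]) if len(rest) == 2 else None
                roi.add(label, MaskROI(pixels), amount)
            else:
                raise ValueError(f"line {line_no}: unknown shape {shape!r}")
    if grid_shape is not None:
        roi.validate_grid(grid_shape)
    return roi


def write_roi(roi: ROISet, path: str | Path) -> Path:
    """Write a ROI set to CSV in the :func:`read_roi` schema."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "shape", "params", "", "", "amount"])
        for label, region in roi.regions.items():
            amount = roi.known_amount.get(label)
            tail = [f"{amount:g}"] if amount is not None else []
            if isinstance(region, CircleROI):
                cx, cy = region.center
                writer.writerow([label, "circle", f"{cx:g}", f"{cy:g}",
                                 f"{region.radius:g}", *tail])
            else:
                pixel_list = ";".join(
                    f"{c} {r}" for c, r in sorted(region.pixels)
                )
                writer.writerow([label, "mask", pixel_list, *tail])
    return path


def write_table(rows: Iterable[Mapping[str, object]] | "pd.DataFrame",
                path: str | Path,
                columns: Sequence[str] | None = None) -> Path:
    """Write rows (mappings or a DataFrame) to CSV with a header row."""
    import pandas as pd

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    if columns is not None:
        df = df[list(columns)]
    df.to_csv(path, index=False)
    return path
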