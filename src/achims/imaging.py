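"""From centroided spectra to calibrated, normalized ion images.

The targeted-MSI workflow is: (1) lock-mass recalibrate each spectrum so
a known matrix ion lands exactly on its theoretical m/z, (2) extract a
per-pixel ion image by aggregating centroid intensities inside a narrow
absolute mass window around the analyte, (3) divide by the image of an
internal-standard ion extracted the same way, cancelling the shared
matrix-deposition/ionisation-efficiency field, and (4) summarize regions
of interest or whole tissue sections by the mean of the defined pixels.

Missing values: pixels where the internal-standard reference is at or
below the floor are NaN in a normalized image and excluded from every
downstream mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .io import CircleROI, IMSDataset, MaskROI, Spectrum

__all__ = [
    "MassWindow",
    "IonImage",
    "AmbiguousCalibrantError",
    "lock_mass_recalibrate",
    "recalibrate_dataset",
    "extract_ion_image",
    "normalize_to_internal_standard",
    "roi_mean",
    "section_mean",
    "render_heatmap",
    "HEATMAP_STOPS",
]


@dataclass(frozen=True)
class MassWindow:
    """Absolute mass-selection window: ``center ± half_width`` Da.

    Absolute Da (not ppm) because targeted filters for small molecules
    are conventionally quoted that way (e.g. 146.117 ± 0.02).
    """

    center: float
    half_width: float

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ValueError("half_width must be > 0")

    @property
    def lo(self) -> float:
        return self.center - self.half_width

    @property
    def hi(self) -> float:
        return self.center + self.half_width


@dataclass
class IonImage:
    """Per-pixel intensity map for one mass window.

    ``values`` has shape (n_rows, n_cols); NaN marks missing pixels
    (undefined ratios). ``normalized_by`` records the reference window
    of a normalized image.
    """

    values: np.ndarray
    window: MassWindow
    normalized_by: MassWindow | None = None
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (n_rows, n_cols)")
        if self.normalized_by is None and np.nanmin(
                self.values, initial=0.0) < 0:
            raise ValueError("raw ion-image values must be >= 0")

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values)


class AmbiguousCalibrantError(ValueError):
    """Two or more peaks inside the lock-mass tolerance window."""


def lock_mass_recalibrate(spectrum: Spectrum, reference: float,
                          tolerance: float) -> tuple[Spectrum, bool]:
    """Rescale a spectrum's m/z axis so the calibrant sits on ``reference``.

    The correction is multiplicative (all m/z scaled by
    ``reference / observed``), the right model for analysers whose mass
    error grows proportionally with m/z; a uniform ppm distortion is
    removed exactly. Intensities are never touched.

    Returns ``(spectrum, found)``; when no peak lies within
    ``±tolerance`` of the reference the spectrum is returned unchanged
    and ``found`` is False so callers can count misses.

    Raises
    ------
    AmbiguousCalibrantError
        If two or more peaks fall inside the tolerance window; the
        message names the candidate m/z values.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    in_tol = np.nonzero(np.abs(spectrum.mz - reference) <= tolerance)[0]
    if in_tol.size == 0:
        return spectrum, False
    if in_tol.size > 1:
        cands = ", ".join(f"{m:.5f}" for m in spectrum.mz[in_tol])
        raise AmbiguousCalibrantError(
            f"ambiguous calibrant near {reference}: peaks at {cands}"
        )
    observed = spectrum.mz[in_tol[0]]
    factor = reference / observed
    return Spectrum(spectrum.mz * factor, spectrum.intensity.copy(),
                    spectrum.pixel), True


def recalibrate_dataset(dataset: IMSDataset, reference: float,
                        tolerance: float) -> tuple[IMSDataset, int]:
    """Lock-mass recalibrate every spectrum; returns (dataset, n_missed)."""
    misses = 0
    spectra = []
    lo, hi = dataset.mass_range
    for s in dataset:
        out, found = lock_mass_recalibrate(s, reference, tolerance)
        misses += not found
        spectra.append(out)
        if out.mz.size:
            lo, hi = min(lo, out.mz[0]), max(hi, out.mz[-1])
    out_ds = IMSDataset(
        grid_shape=dataset.grid_shape, pixel_size=dataset.pixel_size,
        spectra=spectra, mass_range=(lo, hi),
        polarity=dataset.polarity,
        metadata={**dataset.metadata,
                  "lock_mass": f"{reference:g}",
                  "lock_mass_misses": str(misses)},
    )
    return out_ds, misses


def extract_ion_image(dataset: IMSDataset, window: MassWindow,
                      aggregator: Literal["sum", "max"] = "sum") -> IonImage:
    """Per-pixel aggregate of centroid intensities inside a mass window.

    ``sum`` (default) adds every in-window centroid; ``max`` takes the
    tallest. Pixels with no in-window peak get 0; grid pixels with no
    spectrum at all get 0 too (sparse acquisitions).
    """
    lo_ds, hi_ds = dataset.mass_range
    if window.lo < lo_ds or window.hi > hi_ds:
        raise ValueError(
            f"window [{window.lo:g}, {window.hi:g}] outside dataset "
            f"mass range [{lo_ds:g}, {hi_ds:g}]"
        )
    if aggregator not in ("sum", "max"):
        raise ValueError(f"aggregator must be 'sum' or 'max', got {aggregator!r}")
    n_cols, n_rows = dataset.grid_shape
    values = np.zeros((n_rows, n_cols))
    for s in dataset:
        i0 = np.searchsorted(s.mz, window.lo, side="left")
        i1 = np.searchsorted(s.mz, window.hi, side="right")
        if i1 > i0:
            col, row = s.pixel
            chunk = s.intensity[i0:i1]
            values[row, col] = chunk.sum() if aggregator == "sum" else chunk.max()
    return IonImage(values=values, window=window)


def normalize_to_internal_standard(target: IonImage, reference: IonImage,
                                   min_reference: float = 0.0) -> IonImage:
    """Per-pixel ratio target/reference, the internal-standard correction.

    Any per-pixel factor common to both channels (matrix deposition,
    ionisation efficiency) cancels in the ratio. Pixels whose reference
    intensity is zero or below ``min_reference`` become NaN (missing)
    rather than infinite, and are excluded from all downstream means;
    their count is reported on the result.
    """
    if target.values.shape != reference.values.shape:
        raise ValueError(
            f"grid mismatch: {target.values.shape} vs {reference.values.shape}"
        )
    ref = reference.values
    bad = (ref <= 0) | (ref < min_reference) | np.isnan(ref) | target.missing
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(bad, np.nan, target.values / np.where(bad, 1.0, ref))
    return IonImage(values=ratio, window=target.window,
                    normalized_by=reference.window,
                    n_excluded=int(bad.sum()))


def _roi_mask(roi, shape_rc: tuple[int, int]) -> np.ndarray:
    n_rows, n_cols = shape_rc
    if isinstance(roi, (CircleROI, MaskROI)):
        return roi.mask((n_cols, n_rows))
    mask = np.asarray(roi, dtype=bool)
    if mask.shape != (n_rows, n_cols):
        raise ValueError(f"mask shape {mask.shape} != image {shape_rc}")
    return mask


def roi_mean(image: IonImage, roi) -> tuple[float, int]:
    """Mean over non-missing ROI pixels and the count included.

    ``roi`` is a :class:`CircleROI`, :class:`MaskROI` or boolean mask.
    A ROI whose pixels are all missing has no defined mean and raises.
    """
    mask = _roi_mask(roi, image.values.shape)
    vals = image.values[mask]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("ROI contains no non-missing pixels; mean undefined")
    return float(vals.mean()), int(vals.size)


def section_mean(image: IonImage, tissue_mask: np.ndarray) -> float:
    """Mean over non-missing tissue pixels (whole-section summary)."""
    mean, _ = roi_mean(image, tissue_mask)
    return mean


#: Intensity colour ramp: not-detected through low, medium, high,
#: ultra-high to extremely high.
HEATMAP_STOPS = (
    (0.0, (0.0, 0.0, 0.0)),     # black
    (0.25, (0.0, 0.0, 1.0)),    # blue
    (0.5, (0.6, 0.8, 0.2)),     # yellow-green
    (0.7, (1.0, 1.0, 0.0)),     # yellow
    (0.88, (1.0, 0.0, 0.0)),    # red
    (1.0, (1.0, 1.0, 1.0)),     # white
)
_MISSING_GREY = (128, 128, 128)


def render_heatmap(image: IonImage,
                   scale: tuple[float, float] | None = None,
                   percentiles: tuple[float, float] = (1.0, 99.0)
                   ) -> tuple[np.ndarray, tuple[float, float]]:
    """Render an ion image as an RGB uint8 raster.

    Piecewise-linear colormap black → blue → yellow-green → yellow →
    red → white. Values ≤ lo map to black, ≥ hi to white; missing pixels
    render grey. ``scale=None`` auto-scales to the given percentiles of
    the non-missing pixels; the scale actually used is returned so it
    can be embedded in output metadata.
    """
    from matplotlib.colors import LinearSegmentedColormap

    vals = image.values
    finite = vals[~np.isnan(vals)]
    if scale is None:
        if finite.size == 0:
            raise ValueError("cannot auto-scale an all-missing image")
        lo, hi = (float(np.percentile(finite, percentiles[0])),
                  float(np.percentile(finite, percentiles[1])))
        if hi <= lo:  # flat image: degenerate percentile scale
            hi = lo + max(abs(lo), 1.0) * 1e-6
    else:
        lo, hi = scale
        if not hi > lo:
            raise ValueError(f"degenerate scale: lo={lo} hi={hi}")
    cmap = LinearSegmentedColormap.from_list(
        "msi_intensity", [(pos, rgb) for pos, rgb in HEATMAP_STOPS]
    )
    norm = np.clip((vals - lo) / (hi - lo), 0.0, 1.0)
    rgba = cmap(np.nan_to_num(norm, nan=0.0))
    rgb = (rgba[..., :3] * 255).round().astype(np.uint8)
    rgb[np.isnan(vals)] = _MISSING_GREY
    return rgb, (lo, hi)


def save_png(rgb: np.ndarray, path) -> None:
    """Write an RGB raster to PNG."""
    from PIL import Image

    Image.fromarray(rgb, mode="RGB").save(path)
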