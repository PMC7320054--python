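"""On-tissue calibration: level statistics, standard curve, RSD%, LOD.

A dilution series of standard spots on tissue, measured with technical
replicates, yields per-level summary statistics (mean, SD, SEM, RSD%),
an ordinary-least-squares standard curve fitted on the *level means*
(the convention under which published correlation coefficients for such
curves are quoted), and an empirical limit of detection.

The data such curves come from are semi-quantitative: matrix effects
make the absolute response instrument- and section-specific, so
:func:`back_calculate` is for *relative* comparisons within one
calibrated analysis and every result carries its fit range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .imaging import MassWindow, extract_ion_image, roi_mean
from .io import IMSDataset, ROISet

__all__ = [
    "CalibrationLevel",
    "CalibrationCurve",
    "BackCalcResult",
    "level_stats",
    "rsd_from_mean_sem",
    "fit_calibration",
    "back_calculate",
    "lod_from_detection",
    "detect_lod",
]


@dataclass(frozen=True)
class CalibrationLevel:
    """One amount level of the dilution series with replicate statistics.

    ``rsd_percent`` is ``100 * sd / mean`` (sample SD, n-1); it is None
    (flagged undefined) when the mean is zero.
    """

    amount: float
    replicate_values: tuple[float, ...]
    mean: float
    sd: float
    sem: float
    rsd_percent: float | None

    @property
    def n(self) -> int:
        return len(self.replicate_values)


def level_stats(amount: float, replicates: Sequence[float]) -> CalibrationLevel:
    """Summarize one calibration level from its replicate intensities."""
    if amount <= 0:
        raise ValueError("amount must be > 0")
    values = tuple(float(v) for v in replicates)
    n = len(values)
    if n < 2:
        raise ValueError("need >= 2 replicates per level")
    arr = np.asarray(values)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    sem = sd / math.sqrt(n)
    rsd = 100.0 * sd / mean if mean != 0 else None
    return CalibrationLevel(amount=float(amount), replicate_values=values,
                            mean=mean, sd=sd, sem=sem, rsd_percent=rsd)


def rsd_from_mean_sem(mean: float, sem: float, n: int) -> float:
    """Reconstruct RSD% from summary statistics: ``100 * (sem*sqrt(n)) / mean``.

    Lets published mean ± SEM tables be converted back to the
    reproducibility metric without the raw replicates.
    """
    if mean <= 0:
        raise ValueError("mean must be > 0")
    if sem < 0:
        raise ValueError("sem must be >= 0")
    if n < 2:
        raise ValueError("n must be >= 2")
    return 100.0 * (sem * math.sqrt(n)) / mean


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear standard curve fitted on level means.

    ``fit_range`` records the (min, max) amounts actually used;
    ``lod`` is a separately determined detection limit (pmol) or None
    when undetermined.
    """

    levels: tuple[CalibrationLevel, ...]
    slope: float
    intercept: float
    r_squared: float
    fit_range: tuple[float, float]
    lod: float | None = None

    def with_lod(self, lod: float | None) -> "CalibrationCurve":
        return CalibrationCurve(self.levels, self.slope, self.intercept,
                                self.r_squared, self.fit_range, lod)


def fit_calibration(levels: Sequence[CalibrationLevel],
                    fit_range: tuple[float, float] | None = None,
                    on: str = "means") -> CalibrationCurve:
    """Unweighted OLS of intensity on amount over levels in ``fit_range``.

    ``on="means"`` (default) regresses the per-level mean intensities —
    the convention that reproduces published standard-curve R² values
    from mean ± SEM tables; ``on="pooled"`` regresses every replicate
    individually. R² is the squared Pearson correlation of the fitted
    (amount, intensity) pairs. No 1/x weighting is applied.
    """
    if on not in ("means", "pooled"):
        raise ValueError(f"on must be 'means' or 'pooled', got {on!r}")
    lv = sorted(levels, key=lambda l: l.amount)
    if fit_range is not None:
        lo, hi = fit_range
        lv = [l for l in lv if lo <= l.amount <= hi]
    if len(lv) < 3:
        raise ValueError("need >= 3 levels inside the fit range")
    if on == "means":
        x = np.array([l.amount for l in lv])
        y = np.array([l.mean for l in lv])
    else:
        x = np.concatenate([[l.amount] * l.n for l in lv])
        y = np.concatenate([l.replicate_values for l in lv])
    if np.all(x == x[0]):
        raise ValueError("all amounts identical; no fit possible")
    res = sps.linregress(x, y)
    return CalibrationCurve(
        levels=tuple(lv),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        fit_range=(float(min(l.amount for l in lv)),
                   float(max(l.amount for l in lv))),
    )


@dataclass(frozen=True)
class BackCalcResult:
    """Amount read off the standard curve, with honesty flags."""

    amount: float
    extrapolated: bool
    clipped: bool


def back_calculate(intensity: float, curve: CalibrationCurve) -> BackCalcResult:
    """Invert the standard curve: ``(intensity - intercept) / slope``.

    Negative amounts are clipped to 0 and flagged; intensities outside
    the calibrated response range are flagged as extrapolated (the curve
    is for relative quantification within its fit range).
    """
    if curve.slope <= 0:
        raise ValueError(f"slope must be > 0 for back-calculation, "
                         f"got {curve.slope}")
    amount = (intensity - curve.intercept) / curve.slope
    lo, hi = curve.fit_range
    resp_lo = curve.intercept + curve.slope * lo
    resp_hi = curve.intercept + curve.slope * hi
    extrapolated = not (resp_lo <= intensity <= resp_hi)
    clipped = amount < 0
    return BackCalcResult(amount=max(amount, 0.0),
                          extrapolated=extrapolated, clipped=clipped)


def lod_from_detection(detection: Mapping[float, Sequence[bool]],
                       min_fraction: float = 0.5) -> float | None:
    """Smallest amount detected in at least ``min_fraction`` of replicates.

    ``detection`` maps amount -> per-replicate detected flags. Returns
    None (undetermined) when no level qualifies.
    """
    qualifying = [
        amount for amount, flags in detection.items()
        if len(flags) > 0 and sum(flags) / len(flags) >= min_fraction
    ]
    return min(qualifying) if qualifying else None


def detect_lod(dataset: IMSDataset, rois: ROISet, window: MassWindow,
               background_windows: Sequence[MassWindow],
               snr_min: float = 3.0,
               min_fraction: float = 0.5,
               ) -> tuple[float | None, Mapping[float, list[bool]]]:
    """Empirical LOD of a spot dilution series by a local S/N criterion.

    A replicate spot counts as *detected* when its ROI-mean in-window
    intensity is at least ``snr_min`` times the ROI-mean intensity in
    the flanking background windows (the local chemical background). The
    LOD is the smallest amount detected in ≥ ``min_fraction`` of its
    replicates; None when no level qualifies. This S/N ≥ 3,
    ≥ half-of-replicates rule is this package's operationalization of an
    empirical "smallest amount with clear peaks" limit.

    Returns ``(lod, detection_table)``.
    """
    if not background_windows:
        raise ValueError("need at least one background window")
    signal = extract_ion_image(dataset, window)
    bg_images = [extract_ion_image(dataset, w) for w in background_windows]
    detection: dict[float, list[bool]] = {}
    for label, region in rois.regions.items():
        amount = rois.known_amount.get(label)
        if amount is None:
            continue
        s, _ = roi_mean(signal, region)
        noise = float(np.mean([roi_mean(img, region)[0] for img in bg_images]))
        detected = s >= snr_min * noise if noise > 0 else s > 0
        detection.setdefault(amount, []).append(detected)
    return lod_from_detection(detection, min_fraction), detection
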