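"""Synthetic MSI generator with known ground truth.

No public MSI dataset accompanies the acetylcholine lung work this
package operationalizes, so every downstream stage is exercised on
simulated data whose statistical structure mirrors the experimental
design:

* a 10-level on-tissue dilution series of standard spots
  (100 … 0.20 pmol per 0.2 μL spot), 8 replicate spots per level;
* whole-section images for three treatment groups (saline, HDM,
  HDM/Alum) with true abundance ratios 1 : 2 : 3;
* a smooth matrix-deposition/ionisation-efficiency field *shared* by the
  analyte channel and the DHB internal-standard channel — the structural
  assumption that makes per-pixel internal-standard normalization work;
* a tissue-derived isobaric interference at m/z 146.163, resolvable from
  the analyte only because the mass window is narrow (±0.02 Da);
* an optional bright rim on the section boundary emulating analyte
  accumulation at cut edges.

Noise model
-----------
Replicate-to-replicate scatter is multiplicative lognormal
(``rep_sigma``) plus an additive intensity floor (``floor_sigma``),
giving a replicate RSD that tracks
``sqrt(rep_sigma^2 + (floor_sigma/signal)^2)``: with the defaults the
realized RSD falls from ≈ 45% at the lowest spot amount to
≈ rep_sigma ≈ 15% at the highest — the reproducibility profile such
dilution series show in practice. Per-pixel texture is an
independent lognormal (``pixel_sigma``) that largely averages out over a
spot. All randomness flows from a single seed: identical config + seed
reproduces the dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import ndimage

from .io import CircleROI, IMSDataset, ROISet, Spectrum
from . import mass

__all__ = ["SimulationConfig", "GroundTruth", "simulate_spot_series",
           "simulate_lung_section", "GROUP_FOLDS"]

#: m/z of the analyte cation as observed (electron-corrected theory).
ACH_MZ = mass.ion_mz(mass.MoleculeSpec("C7H16NO2", charge=1, adduct="none",
                                       electron_correction=True))
#: m/z of the protonated DHB internal-standard / lock-mass ion.
DHB_MZ = mass.ion_mz(mass.DHB_PROTONATED)
#: Tissue-derived isobaric interference next to the analyte.
INTERFERENCE_MZ = 146.163
#: Chemical-background peaks flanking the analyte, used for local S/N.
BACKGROUND_MZS = (146.080, 146.210)
#: Cosmetic matrix-derived peaks (DHB fragment/adducts).
MATRIX_MZS = (137.0233, 177.0546, 273.0394)

#: True abundance multiplier per treatment group (1 : 2 : 3 design).
GROUP_FOLDS: Mapping[str, float] = {"saline": 1.0, "HDM": 2.0, "HDM_Alum": 3.0}


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters; defaults are the emulated study conditions."""

    seed: int = 0
    layout: str = "spot_series"  # or "lung_section"
    #: Spotted amounts in pmol per 0.2 μL spot, high to low.
    amounts: tuple[float, ...] = (100.0, 50.0, 25.0, 12.5, 6.25,
                                  3.13, 1.56, 0.78, 0.39, 0.20)
    replicates: int = 8
    grid_shape: tuple[int, int] = (120, 120)
    pixel_size: float = 100.0  # μm laser pitch
    spot_radius: float = 4.0  # px
    #: Analyte response, a.u. of raw peak intensity per pmol.
    response_per_pmol: float = 25.0
    #: Matrix-deposition efficiency field: 1 + amplitude * smooth(+-1).
    efficiency_amplitude: float = 0.25
    efficiency_length: float = 30.0  # correlation length, px
    #: Replicate-level multiplicative lognormal sigma (spots/sections).
    rep_sigma: float = 0.15
    #: Replicate-level additive intensity floor sigma, a.u. The default
    #: is calibrated so the *realized* replicate RSD at the lowest spot
    #: amount is ~45% (sample-SD bias, chemical background and
    #: truncation at zero all deflate the naive sqrt-formula value).
    floor_sigma: float = 2.5
    #: Per-pixel multiplicative lognormal sigma.
    pixel_sigma: float = 0.20
    #: Per-pixel additive chemical noise sigma on the analyte channel, a.u.
    chem_sigma: float = 0.4
    #: Tissue-derived isobaric peak at m/z 146.163.
    interference: bool = True
    interference_mean: float = 50.0
    #: Mean DHB internal-standard intensity, a.u.
    internal_standard_base: float = 200.0
    background_mean: float = 1.2
    #: Section-edge accumulation artifact (lung layout only).
    edge_artifact: bool = False
    edge_magnitude: float = 2.0
    #: Baseline tissue analyte amount for lung sections, pmol-equivalent.
    section_base_amount: float = 2.0
    #: Uniform relative mass-axis distortion applied to every m/z (ppm);
    #: lock-mass recalibration should remove it exactly.
    mass_error_ppm: float = 0.0
    mass_range: tuple[float, float] = (50.0, 350.0)

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.amounts):
            raise ValueError("amounts must be > 0")
        if min(self.rep_sigma, self.floor_sigma, self.pixel_sigma,
               self.chem_sigma) < 0:
            raise ValueError("noise sigmas must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


@dataclass
class GroundTruth:
    """What the generator actually put down, for recovery checks."""

    #: Per-pixel true analyte amount, shape (n_rows, n_cols), pmol(-equiv).
    amount_map: np.ndarray
    #: ROI label -> true spotted amount (spot series only).
    roi_amounts: dict[str, float] = field(default_factory=dict)
    #: True group abundance multiplier (lung sections only).
    fold: float | None = None


def _efficiency_field(rng: np.random.Generator,
                      config: SimulationConfig) -> np.ndarray:
    """Smooth multiplicative field in [1-A, 1+A], shared by all channels.

    A low-order cosine mixture: cheap, seedable, and with a tunable
    correlation length — a stand-in for inhomogeneous matrix coating and
    crystal heterogeneity, which scale every ion at a pixel alike.
    """
    n_cols, n_rows = config.grid_shape
    cols, rows = np.meshgrid(np.arange(n_cols), np.arange(n_rows))
    n_comp = 4
    f = np.zeros((n_rows, n_cols))
    for _ in range(n_comp):
        theta = rng.uniform(0, 2 * np.pi)
        freq = 1.0 / max(config.efficiency_length, 1.0)
        u, v = freq * np.cos(theta), freq * np.sin(theta)
        phase = rng.uniform(0, 2 * np.pi)
        f += np.cos(2 * np.pi * (u * cols + v * rows) + phase)
    f /= n_comp  # in [-1, 1]
    return 1.0 + config.efficiency_amplitude * f


def _lognormal(rng: np.random.Generator, sigma: float, size=None) -> np.ndarray:
    """Mean-one multiplicative noise; exactly 1 when sigma == 0."""
    if sigma == 0:
        return np.ones(size) if size is not None else 1.0
    return np.exp(rng.normal(0.0, sigma, size=size) - 0.5 * sigma**2)


def _assemble_spectra(config: SimulationConfig, rng: np.random.Generator,
                      present: np.ndarray,
                      ach: np.ndarray,
                      interference: np.ndarray,
                      dhb: np.ndarray,
                      background: np.ndarray) -> list[Spectrum]:
    """Build one centroided spectrum per present pixel.

    Intensity maps are (n_rows, n_cols); peaks with non-positive
    intensity are dropped, mimicking centroided acquisition where absent
    ions simply yield no peak.
    """
    n_cols, n_rows = config.grid_shape
    scale = 1.0 + config.mass_error_ppm * 1e-6
    matrix_int = {m: config.internal_standard_base * fr
                  for m, fr in zip(MATRIX_MZS, (0.35, 0.20, 0.10))}
    peak_mzs = np.array(
        [BACKGROUND_MZS[0], ACH_MZ, INTERFERENCE_MZ, BACKGROUND_MZS[1],
         DHB_MZ, *MATRIX_MZS]
    )
    order = np.argsort(peak_mzs)
    matrix_maps = [
        matrix_int[m] * _lognormal(rng, config.pixel_sigma, (n_rows, n_cols))
        for m in MATRIX_MZS
    ]
    spectra: list[Spectrum] = []
    rows_idx, cols_idx = np.nonzero(present)
    stacked = np.stack(
        [background[0], ach, interference, background[1],
         dhb, *matrix_maps]
    )[:, rows_idx, cols_idx]
    sorted_mzs = peak_mzs[order] * scale
    stacked = stacked[order]
    for j in range(rows_idx.size):
        ints = stacked[:, j]
        keep = ints > 0
        spectra.append(Spectrum(sorted_mzs[keep], ints[keep],
                                (int(cols_idx[j]), int(rows_idx[j]))))
    return spectra


def _channel_maps(config: SimulationConfig, rng: np.random.Generator,
                  amount_map: np.ndarray, tissue: np.ndarray,
                  eff: np.ndarray,
                  rep_scale: np.ndarray | float = 1.0,
                  rep_floor: np.ndarray | float = 0.0):
    """Raw intensity maps for every channel given a true amount map.

    ``rep_scale`` / ``rep_floor`` carry replicate-level noise, already
    broadcast to pixel shape (e.g. constant per spot or per section).
    """
    n_cols, n_rows = config.grid_shape
    shape = (n_rows, n_cols)
    k = config.response_per_pmol

    # replicate-level response: multiplicative lognormal + additive floor,
    # applied before per-pixel texture so the configured RSD profile
    # sqrt(rep_sigma^2 + (floor_sigma / (k*amount))^2) is realized
    response = k * amount_map * rep_scale + np.asarray(rep_floor) * (amount_map > 0)
    response = np.clip(response, 0.0, None)
    ach = response * eff * _lognormal(rng, config.pixel_sigma, shape)
    if config.chem_sigma > 0:
        ach = ach + np.abs(rng.normal(0.0, config.chem_sigma, shape)) * tissue
    ach = np.clip(ach, 0.0, None) * tissue

    dhb = (config.internal_standard_base * eff
           * _lognormal(rng, config.pixel_sigma, shape))

    if config.interference:
        interference = (config.interference_mean * eff
                        * _lognormal(rng, config.pixel_sigma, shape)) * tissue
    else:
        interference = np.zeros(shape)

    background = [
        config.background_mean * _lognormal(rng, config.pixel_sigma * 2, shape)
        * tissue
        for _ in BACKGROUND_MZS
    ]
    return ach, interference, dhb, background


def simulate_spot_series(config: SimulationConfig
                         ) -> tuple[IMSDataset, ROISet, GroundTruth]:
    """Dilution-series layout: levels in columns, replicate spots in rows.

    Returns the dataset, one circular ROI per (level, replicate) with its
    known amount, and the ground truth. In the noise-free limit the
    internal-standard-normalized ROI means are exactly proportional to
    amount even though the raw means are not (the efficiency field warps
    them) — the identifiability property normalization relies on.
    """
    if config.layout != "spot_series":
        raise ValueError(f"layout must be 'spot_series', got {config.layout!r}")
    n_cols, n_rows = config.grid_shape
    n_levels, n_reps = len(config.amounts), config.replicates
    dx, dy = n_cols / n_levels, n_rows / n_reps
    if min(dx, dy) < 2 * config.spot_radius + 1:
        raise ValueError(
            f"grid {config.grid_shape} too small for {n_levels}x{n_reps} "
            f"spots of radius {config.spot_radius}"
        )
    rng = np.random.default_rng(config.seed)
    eff = _efficiency_field(rng, config)

    rois = ROISet()
    amount_map = np.zeros((n_rows, n_cols))
    rep_scale = np.ones((n_rows, n_cols))
    rep_floor = np.zeros((n_rows, n_cols))
    truth = GroundTruth(amount_map=amount_map)
    cols_g, rows_g = np.meshgrid(np.arange(n_cols), np.arange(n_rows))
    for i, amount in enumerate(config.amounts):
        for j in range(n_reps):
            cx, cy = dx * (i + 0.5), dy * (j + 0.5)
            label = f"spot_{amount:g}pmol_rep{j + 1}"
            rois.add(label, CircleROI((cx, cy), config.spot_radius), amount)
            in_spot = ((cols_g - cx) ** 2 + (rows_g - cy) ** 2
                       <= config.spot_radius**2)
            amount_map[in_spot] = amount
            rep_scale[in_spot] = _lognormal(rng, config.rep_sigma)
            rep_floor[in_spot] = (rng.normal(0.0, config.floor_sigma)
                                  if config.floor_sigma > 0 else 0.0)
            truth.roi_amounts[label] = amount

    tissue = np.ones((n_rows, n_cols), dtype=bool)  # spots sit on a section
    ach, interference, dhb, background = _channel_maps(
        config, rng, amount_map, tissue, eff, rep_scale, rep_floor
    )
    spectra = _assemble_spectra(config, rng, tissue, ach, interference,
                                dhb, background)
    dataset = IMSDataset(
        grid_shape=config.grid_shape, pixel_size=config.pixel_size,
        spectra=spectra, mass_range=config.mass_range,
        metadata={"layout": "spot_series", "seed": str(config.seed)},
    )
    return dataset, rois, truth


def _tissue_mask(rng: np.random.Generator,
                 config: SimulationConfig) -> np.ndarray:
    """Irregular lobe-like mask with airway-like holes."""
    n_cols, n_rows = config.grid_shape
    cols, rows = np.meshgrid(np.arange(n_cols), np.arange(n_rows))
    cx, cy = (n_cols - 1) / 2, (n_rows - 1) / 2
    dxn, dyn = (cols - cx) / (0.40 * n_cols), (rows - cy) / (0.44 * n_rows)
    theta = np.arctan2(dyn, dxn)
    wobble = (1.0 + 0.12 * np.cos(3 * theta + rng.uniform(0, 2 * np.pi))
              + 0.08 * np.cos(5 * theta + rng.uniform(0, 2 * np.pi)))
    mask = dxn**2 + dyn**2 <= wobble**2
    # airway-like holes
    n_holes = 3
    for _ in range(n_holes):
        hx = cx + rng.uniform(-0.2, 0.2) * n_cols
        hy = cy + rng.uniform(-0.2, 0.2) * n_rows
        hr = rng.uniform(0.02, 0.04) * min(n_cols, n_rows)
        mask &= (cols - hx) ** 2 + (rows - hy) ** 2 > hr**2
    return mask


def simulate_lung_section(config: SimulationConfig,
                          group: str | float = "saline",
                          section_seed: int | None = None
                          ) -> tuple[IMSDataset, np.ndarray, GroundTruth]:
    """One whole-section image for a treatment group (or explicit fold).

    The tissue structure, efficiency field and noise draws depend only on
    the seed, never on the fold, so two sections simulated with the same
    seed but different folds differ *exactly* by the fold — the basis of
    the noise-free fold-recovery checks. Off-tissue pixels carry matrix
    peaks only.
    """
    fold = GROUP_FOLDS[group] if isinstance(group, str) else float(group)
    if fold <= 0:
        raise ValueError(f"fold must be > 0, got {fold}")
    seed = config.seed if section_seed is None else section_seed
    rng = np.random.default_rng(seed)
    n_cols, n_rows = config.grid_shape

    eff = _efficiency_field(rng, config)
    tissue = _tissue_mask(rng, config)
    # smooth within-section abundance pattern, fold-independent
    pattern = 1.0 + 0.25 * (_efficiency_field(rng, config) - 1.0) / max(
        config.efficiency_amplitude, 1e-12
    )
    amount_map = config.section_base_amount * pattern * tissue
    if config.edge_artifact:
        rim = tissue & ~ndimage.binary_erosion(tissue, iterations=2)
        amount_map[rim] += config.edge_magnitude * config.section_base_amount
    amount_map = amount_map * fold

    rep_scale = _lognormal(rng, config.rep_sigma)  # one draw per section
    rep_floor = (rng.normal(0.0, config.floor_sigma)
                 if config.floor_sigma > 0 else 0.0)
    ach, interference, dhb, background = _channel_maps(
        config, rng, amount_map, tissue, eff, rep_scale, rep_floor
    )
    present = np.ones((n_rows, n_cols), dtype=bool)
    spectra = _assemble_spectra(config, rng, present, ach, interference,
                                dhb, background)
    dataset = IMSDataset(
        grid_shape=config.grid_shape, pixel_size=config.pixel_size,
        spectra=spectra, mass_range=config.mass_range,
        metadata={"layout": "lung_section", "seed": str(seed),
                  "fold": f"{fold:g}"},
    )
    return dataset, tissue, GroundTruth(amount_map=amount_map, fold=fold)
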