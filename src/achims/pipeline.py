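"""End-to-end orchestration: simulate → calibrate → image → compare.

One :func:`run_pipeline` call reproduces the whole analysis on synthetic
data: a spot dilution series is simulated, lock-mass recalibrated,
extracted, internal-standard normalized and fitted into a standard
curve with RSD% and LOD; whole-section images are simulated for the
three treatment groups, summarized per mouse (technical replicates
averaged first) and compared pairwise by Student's t. Every run is
deterministic given its seed and writes a JSON manifest listing each
output file with a content hash.

imzML files embed a fresh UUID on every write, so their manifest entries
hash the *spectral content* (pixel coordinates, m/z and intensity
arrays) rather than file bytes; all other outputs are hashed as bytes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .calibration import detect_lod, fit_calibration, level_stats
from .groupstats import (collapse_technical, pairwise_comparisons,
                         summarize_group)
from .imaging import (MassWindow, extract_ion_image,
                      normalize_to_internal_standard, recalibrate_dataset,
                      render_heatmap, roi_mean, save_png, section_mean)
from .io import write_imzml, write_roi, write_table
from .mass import MoleculeSpec, ion_mz
from .simulate import (BACKGROUND_MZS, GROUP_FOLDS, SimulationConfig,
                       simulate_lung_section, simulate_spot_series)

__all__ = ["RunConfig", "PipelineStageError", "run_pipeline"]

log = logging.getLogger("achims.pipeline")


class PipelineStageError(RuntimeError):
    """A stage failed; names the stage and cleans partial outputs."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    """Configuration for a full synthetic analysis run."""

    outdir: str | Path = "results/run"
    seed: int = 0
    #: Target ion: acetylcholine's intrinsic cation.
    target: MoleculeSpec = field(default_factory=lambda: MoleculeSpec(
        "C7H16NO2", charge=1, adduct="none", electron_correction=True))
    #: Internal standard and lock mass: protonated DHB.
    internal_standard: MoleculeSpec = field(default_factory=lambda: MoleculeSpec(
        "C7H6O4", charge=1, adduct="protonated", electron_correction=True))
    window_half_width: float = 0.02  # Da
    lock_mass_tolerance: float = 0.01  # Da
    min_reference: float = 0.0
    #: Per-pixel normalization (primary); "section" divides the section
    #: mean of the target by that of the reference instead.
    normalization: str = "pixel"
    n_mice: int = 6
    technical_replicates: int = 2
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    #: Section grid kept smaller than the spot grid: 36 sections per run.
    section_grid: tuple[int, int] = (64, 64)
    write_datasets: bool = False  # imzML output is opt-in (it is bulky)

    def __post_init__(self) -> None:
        if self.window_half_width <= 0 or self.lock_mass_tolerance <= 0:
            raise ValueError("windows and tolerances must be positive")
        if self.normalization not in ("pixel", "section"):
            raise ValueError("normalization must be 'pixel' or 'section'")


def _config_dict(config: RunConfig) -> dict:
    """JSON-serializable view of the run config for the manifest."""
    from .mass import formula_to_hill

    out = {}
    for f in dataclasses.fields(config):
        value = getattr(config, f.name)
        if isinstance(value, MoleculeSpec):
            value = {"formula": formula_to_hill(value.composition),
                     "charge": value.charge, "adduct": value.adduct,
                     "electron_correction": value.electron_correction}
        elif isinstance(value, SimulationConfig):
            value = dataclasses.asdict(value)
        elif isinstance(value, Path):
            value = str(value)
        out[f.name] = value
    return out


def _section_seed(seed: int, group_idx: int, mouse: int, rep: int) -> int:
    ss = np.random.SeedSequence([seed, group_idx, mouse, rep])
    return int(ss.generate_state(1)[0] % (2**31))


def _dataset_content_hash(dataset) -> str:
    h = hashlib.sha256()
    for s in dataset:
        h.update(np.asarray(s.pixel, dtype=np.int64).tobytes())
        h.update(s.mz.tobytes())
        h.update(s.intensity.astype(np.float32).tobytes())
    return h.hexdigest()


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _normalized_images(dataset, config: RunConfig):
    target_window = MassWindow(ion_mz(config.target), config.window_half_width)
    ref_window = MassWindow(ion_mz(config.internal_standard),
                            config.window_half_width)
    recal, misses = recalibrate_dataset(
        dataset, ion_mz(config.internal_standard), config.lock_mass_tolerance
    )
    target_img = extract_ion_image(recal, target_window)
    ref_img = extract_ion_image(recal, ref_window)
    norm = normalize_to_internal_standard(target_img, ref_img,
                                          config.min_reference)
    return target_img, ref_img, norm, misses


def run_pipeline(config: RunConfig) -> dict:
    """Run the full synthetic analysis; returns the manifest dict.

    Stages: ``simulate_spots`` → ``calibrate`` → ``image_sections`` →
    ``compare`` → ``manifest``. Any stage error aborts with the stage
    name after removing the files written so far in this run.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[tuple[Path, str]] = []  # (path, hash-kind)
    stage = "setup"
    t0 = time.time()
    try:
        # ---- simulate + calibrate the spot dilution series -------------
        stage = "simulate_spots"
        sim = config.simulation.with_(seed=config.seed, layout="spot_series")
        spots, rois, truth = simulate_spot_series(sim)
        log.info("simulated spot series: %d spectra, %d ROIs (%.1fs)",
                 len(spots), len(rois), time.time() - t0)
        roi_path = write_roi(rois, outdir / "spots_roi.csv")
        written.append((roi_path, "file-bytes"))
        spot_hash = _dataset_content_hash(spots)
        if config.write_datasets:
            ds_path = write_imzml(spots, outdir / "spots.imzML")
            written.append((ds_path, "spectra-content"))
            written.append((ds_path.with_suffix(".ibd"), "spectra-content"))

        stage = "calibrate"
        if len(rois) == 0:
            raise ValueError("no calibration ROIs available")
        _, _, norm, _ = _normalized_images(spots, config)
        by_amount: dict[float, list[float]] = {}
        for label, region in rois.regions.items():
            amount = rois.known_amount[label]
            mean, _n = roi_mean(norm, region)
            by_amount.setdefault(amount, []).append(mean)
        levels = [level_stats(a, reps) for a, reps in sorted(by_amount.items())]
        curve = fit_calibration(levels)
        target_window = MassWindow(ion_mz(config.target),
                                   config.window_half_width)
        lod, _detection = detect_lod(
            spots, rois, target_window,
            [MassWindow(m, config.window_half_width) for m in BACKGROUND_MZS],
        )
        curve = curve.with_lod(lod)
        log.info("calibration: slope=%.4g intercept=%.4g R2=%.4f LOD=%s",
                 curve.slope, curve.intercept, curve.r_squared, curve.lod)
        lv_path = write_table(
            [{"amount_pmol": l.amount, "n": l.n, "mean": l.mean, "sd": l.sd,
              "sem": l.sem, "rsd_percent": l.rsd_percent} for l in levels],
            outdir / "calibration_levels.csv",
        )
        fit_path = write_table(
            [{"slope": curve.slope, "intercept": curve.intercept,
              "r_squared": curve.r_squared,
              "fit_min_pmol": curve.fit_range[0],
              "fit_max_pmol": curve.fit_range[1],
              "lod_pmol": curve.lod}],
            outdir / "calibration_fit.csv",
        )
        written += [(lv_path, "file-bytes"), (fit_path, "file-bytes")]

        # ---- simulate + image the three-group section study ------------
        stage = "image_sections"
        sec_cfg = config.simulation.with_(
            seed=config.seed, layout="lung_section",
            grid_shape=config.section_grid,
        )
        section_rows = []
        group_values: dict[str, dict[str, list[float]]] = {}
        for gi, (group, fold) in enumerate(GROUP_FOLDS.items()):
            for mouse in range(1, config.n_mice + 1):
                for rep in range(1, config.technical_replicates + 1):
                    seed = _section_seed(config.seed, gi, mouse, rep)
                    ds, mask, _gt = simulate_lung_section(sec_cfg, group,
                                                          section_seed=seed)
                    _, ref_img, norm_img, _ = _normalized_images(ds, config)
                    if config.normalization == "pixel":
                        value = section_mean(norm_img, mask)
                    else:
                        tgt_img = extract_ion_image(
                            ds, MassWindow(ion_mz(config.target),
                                           config.window_half_width))
                        value = (section_mean(tgt_img, mask)
                                 / section_mean(ref_img, mask))
                    section_rows.append(
                        {"group": group, "mouse_id": f"{group}_m{mouse}",
                         "technical_rep": rep, "section_value": value})
                    group_values.setdefault(group, {}).setdefault(
                        f"{group}_m{mouse}", []).append(value)
                    if mouse == 1 and rep == 1:
                        rgb, scale = render_heatmap(norm_img)
                        png = outdir / f"section_{group}.png"
                        save_png(rgb, png)
                        written.append((png, "file-bytes"))
                        log.info("%s heatmap scale: %.3g..%.3g",
                                 group, *scale)
        sec_path = write_table(section_rows, outdir / "section_means.csv")
        written.append((sec_path, "file-bytes"))

        # ---- group statistics ------------------------------------------
        stage = "compare"
        summaries = []
        for group in GROUP_FOLDS:
            per_mouse = collapse_technical(group_values[group])
            summaries.append(summarize_group(group, list(per_mouse.values())))
        comparisons = pairwise_comparisons(summaries)
        sum_path = write_table(
            [{"group": s.label, "n": s.n, "mean": s.mean, "sem": s.sem}
             for s in summaries],
            outdir / "group_summary.csv",
        )
        cmp_path = write_table(
            [{"reference": c.pair[0], "test": c.pair[1],
              "t": c.t_statistic, "df": c.degrees_of_freedom,
              "p_value": c.p_value, "stars": c.stars,
              "fold_change": c.fold_change} for c in comparisons],
            outdir / "comparisons.csv",
        )
        written += [(sum_path, "file-bytes"), (cmp_path, "file-bytes")]
        for c in comparisons:
            log.info("%s vs %s: t=%.3f df=%d p=%.4g %s fold=%.3f",
                     *c.pair, c.t_statistic, c.degrees_of_freedom,
                     c.p_value, c.stars, c.fold_change)

        # ---- manifest ---------------------------------------------------
        stage = "manifest"
        manifest = {
            "package": "achims",
            "version": __version__,
            "seed": config.seed,
            "config": _config_dict(config),
            "spot_dataset_sha256": spot_hash,
            "elapsed_s": round(time.time() - t0, 2),
            "files": sorted(
                ({"path": p.name, "sha256": (_file_hash(p)
                                             if kind == "file-bytes"
                                             else spot_hash),
                  "hash_of": kind} for p, kind in written),
                key=lambda e: e["path"],
            ),
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        log.info("run complete in %.1fs; %d files", time.time() - t0,
                 len(manifest["files"]))
        return manifest
    except PipelineStageError:
        raise
    except Exception as exc:
        for p, _ in written:
            p.unlink(missing_ok=True)
        raise PipelineStageError(stage, exc) from exc
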