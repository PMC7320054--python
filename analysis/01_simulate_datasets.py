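#!/usr/bin/env python
"""Simulate the two study layouts and write them to standard formats.

Produces, under results/data/:
* a 10-level x 8-replicate on-tissue spot dilution series
  (100 ... 0.20 pmol per spot) as imzML + ROI CSV + ground truth, and
* one whole-section image per treatment group (saline, HDM, HDM/Alum;
  true abundance ratios 1:2:3) with its tissue mask.

Everything downstream (02-04) regenerates data in memory from seeds;
these files exist so the datasets can be inspected with standard MSI
tools.
"""

import sys
from pathlib import Path

import numpy as np

from achims import io
from achims.simulate import (GROUP_FOLDS, SimulationConfig,
                             simulate_lung_section, simulate_spot_series)

OUT = Path("results/data")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    cfg = SimulationConfig(seed=SEED)
    spots, rois, truth = simulate_spot_series(cfg)
    io.write_imzml(spots, OUT / "spot_series.imzML")
    io.write_roi(rois, OUT / "spot_series_rois.csv")
    io.write_table(
        [{"label": k, "amount_pmol": v} for k, v in truth.roi_amounts.items()],
        OUT / "spot_series_truth.csv",
    )
    print(f"spot series: {len(spots)} spectra, {len(rois)} ROIs, "
          f"amounts {min(cfg.amounts)}-{max(cfg.amounts)} pmol")

    sec_cfg = cfg.with_(layout="lung_section", grid_shape=(64, 64))
    for group in GROUP_FOLDS:
        ds, mask, gt = simulate_lung_section(sec_cfg, group,
                                             section_seed=SEED)
        io.write_imzml(ds, OUT / f"section_{group}.imzML")
        np.savetxt(OUT / f"section_{group}_mask.csv", mask.astype(int),
                   fmt="%d", delimiter=",")
        print(f"section {group}: fold {gt.fold:g}, "
              f"{int(mask.sum())} tissue pixels, "
              f"mean true amount {gt.amount_map[mask].mean():.2f}")


if __name__ == "__main__":
    main()
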