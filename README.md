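# achims

Label-free quantitative MALDI imaging mass spectrometry (MSI) of
acetylcholine (ACh) in lung tissue, as a tested, reusable Python
pipeline: exact-mass ion targeting, narrow mass-window ion-image
extraction, lock-mass (online) calibration, internal-standard
normalization against a matrix ion, on-tissue calibration curves with
RSD%/LOD, and group-level relative quantification with Student's *t*
tests.

## The problem

ACh is the principal bronchoconstrictor neurotransmitter, and its
abundance in lung tissue rises with allergic-asthma severity. Imaging
it is hard: ACh is a low-mass intrinsic cation (C₇H₁₆NO₂⁺, detected at
*m/z* 146.117 without protonation) surrounded by near-isobaric tissue
and matrix peaks (the nearest tissue-derived interference sits at
*m/z* 146.163), so targeted extraction needs ultra-high mass resolution
and a narrow absolute window (*m/z* 146.117 ± 0.02). Because MALDI
matrix deposition and ionisation efficiency vary across a section, raw
intensities are not comparable between pixels or sections; dividing the
ACh image pixel-wise by the image of a protonated DHB matrix ion
(*m/z* 155.03389, also the lock mass) cancels that shared efficiency
field and makes relative quantification possible.

The statistical machinery: each dilution level of an on-tissue standard
series (100 … 0.20 pmol per 0.2 μL spot, *n* = 8 technical replicates)
is summarized as mean ± SEM with RSD% = 100·SD/mean; the standard curve
is unweighted OLS of level-mean intensity on amount, with
R² = r²(amount, mean); group designs (*N* = 6 mice, ≥ 2 technical
replicates averaged per mouse) are compared by unpaired two-tailed
pooled-variance Student's *t* (df = n_A + n_B − 2).

No public dataset accompanies this kind of experiment, so the package
ships a first-class synthetic-data generator ([`achims.simulate`](src/achims/simulate.py))
whose defaults encode the study design — spot series, three treatment
groups at true abundance ratios 1:2:3, a deposition-efficiency field
shared between analyte and internal-standard channels, the 146.163
interference, and a replicate noise model whose RSD falls from ~45 % at
0.20 pmol to ~15 % at 100 pmol — giving every downstream stage a known
ground truth.

## Worked example

```sh
$ achims mz C7H16NO2 --no-electron-correction
146.11810
$ achims mz C7H6O4 --adduct protonated
155.03389
```

The first is the ACh cation's monoisotopic mass by the neutral-formula
convention (the value conventionally quoted as the "theoretical exact
mass", 146.1181); the second is the electron-corrected protonated-DHB
lock mass.

The analysis itself is laid out as numbered drivers under `analysis/`
(each regenerates its inputs from a seed):

```sh
$ python analysis/02_calibration_curve.py 1
reference table:
  R2 (0.20-100 pmol) = 0.9865
  R2 (0.20-1.56 pmol) = 0.9966
  RSD% reconstructed at 25/50/100 pmol: [25.65, 14.14, 14.67]
simulated series (seed 1):
  lock-mass misses: 0
  slope 0.1299 (true 0.1250 ratio-units/pmol), intercept 0.0048, R2 0.9998, LOD 0.2 pmol
```

Part A reconstructs, from the shipped reference summary table
(`achims.datasets`), the published standard-curve R² over the full and
low ranges and the RSD% row from mean ± SEM alone. Part B runs the full
machinery on a simulated series: the fitted slope recovers the
generator's true response within a few percent, and the S/N ≥ 3
detection rule finds the 0.20 pmol limit of the simulated series.

```sh
$ python analysis/04_group_comparison.py 1
reference section-mean summaries (n = 6 mice/group):
  HDM vs saline: fold 1.90, t = 3.23, df = 10, p = 0.0089 **
  HDM_Alum vs HDM: fold 1.90, t = 3.97, df = 10, p = 0.0027 **
  HDM_Alum vs saline: fold 3.60, t = 7.04, df = 10, p = 0.0000 ***

simulated pipeline (seed 1, 6 mice x 2 reps/group):
  HDM vs saline: fold 2.03, t = 10.66, p = 8.82e-07 ***
  HDM_Alum vs saline: fold 3.04, t = 21.13, p = 1.25e-09 ***
  HDM_Alum vs HDM: fold 1.50, t = 8.73, p = 5.46e-06 ***
```

The synthetic three-group run recovers the designed 1:2:3 abundance
ratios (folds 2.03 and 3.04 against saline) and flags every pairwise
difference; outputs (calibration tables, section means, comparisons,
heatmap PNGs, hash manifest) land in `results/pipeline_run/`.

`achims --help` lists the remaining subcommands (`simulate`, `image`,
`calibrate`, `compare`, `run`) for working from imzML/CSV files
directly.

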