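# Methods

## Target ions and mass conventions

Target ions are defined by elemental formula, charge and adduct
(`achims.mass.MoleculeSpec`). Masses are most-abundant-isotope sums
from an embedded constants table (IUPAC/CODATA values to ≥ 6 decimals;
no runtime database lookups). Two m/z conventions coexist for singly
charged cations and both are supported explicitly:

* **neutral-formula** ("theoretical exact mass"): the plain
  monoisotopic mass of the formula. ACh's intrinsic cation C₇H₁₆NO₂⁺ is
  conventionally quoted this way, 146.1181 Da;
* **electron-corrected**: subtract one electron mass (0.00054858 Da)
  per positive charge. The protonated DHB matrix ion
  (C₇H₆O₄ + H)⁺ is quoted this way, 155.03389 Da.

The electron correction defaults on for observed/calibrant m/z (it is
what the instrument sees) and the neutral-formula value remains
available; nothing is hidden in an unswitchable default. The observed
ACh peak is usually quoted at 146.117 (3 d.p.); the package always
reports full precision and never truncates. The parser accepts
Hill-notation formulas only; isotope labels (deuterated standards) are
a documented extension point, not implemented.

## Ion images

* **Mass windows are absolute** (centre ± half-width in Da, default
  ± 0.02), matching how targeted small-molecule filters are quoted, not
  ppm.
* **Extraction** aggregates in-window centroid intensities per pixel;
  the default aggregator is *sum* (vendor software rules are
  undocumented; *max* is available, and synthetic spectra carry one
  in-window peak so results here are aggregator-independent). Pixels
  with no in-window peak read 0.
* **Lock-mass recalibration is multiplicative**: all m/z in a spectrum
  are scaled so the calibrant lands exactly on its theoretical value.
  The multiplicative model is chosen because FT-ICR mass error grows
  proportionally with m/z; a uniform ppm distortion is removed exactly.
  A spectrum with no calibrant peak inside the tolerance (default
  ± 0.01 Da) is passed through unchanged and counted; two candidate
  peaks raise an error naming both. Intensities are never modified.
* **Internal-standard normalization** is per-pixel division of the
  analyte image by the reference-ion image. Pixels with reference
  intensity ≤ `min_reference` (default 0, i.e. only exact zeros, since
  no principled DHB floor is established) become missing (NaN), are
  excluded from every downstream mean, and are counted. Whether such
  normalization should be per pixel or per section is genuinely open;
  per-pixel is the primary implementation and a per-section-ratio
  alternative is exposed in the pipeline config (`normalization:
  "section"`) for comparison.
* **Heatmaps** use a piecewise-linear ramp
  black → blue → yellow-green → yellow → red → white (not detected →
  low → medium → high → ultra-high → extremely high); values ≤ lo map
  to black, ≥ hi to white, missing pixels render grey. Auto-scale is
  the 1st–99th percentile of non-missing pixels and the scale actually
  used is always returned/embedded, since no universal convention
  exists.

## Calibration and detection limit

Per level: mean, sample SD (n−1), SEM = SD/√n, RSD% = 100·SD/mean
(flagged undefined at zero mean). RSD% is also reconstructible from
summary statistics as 100·(SEM·√n)/mean, so published mean ± SEM tables
can be audited without raw replicates.

The standard curve is **unweighted OLS of level-mean intensity on
amount**; R² is the squared Pearson correlation of (amount, mean).
Fitting on level means (rather than pooled replicates) is the
convention under which published correlation coefficients for such
mean ± SEM curves are quoted, and the shipped reference table
reproduces its published R² = 0.9865 exactly under it; pooled-replicate
fitting is available as an option. Nothing suggests 1/x weighting and
none is applied.

`back_calculate` inverts the curve, clipping negative amounts to zero
with a flag and flagging intensities outside the calibrated response
range as extrapolated. On-tissue MALDI response is matrix- and
section-specific, so back-calculated amounts are documented as
*relative/semi-quantitative* and every curve carries its fit range.

**LOD** is operationalized — this package's own rule, since empirical
"smallest clearly detected amount" statements come without a formula —
as the smallest amount whose ROI-mean in-window signal reaches
S/N ≥ 3 against the local chemical background (flanking windows at
146.080 and 146.210, chosen to exclude both the analyte and the 146.163
interference) in at least half of the replicate spots. No LOQ threshold
is imposed; RSD% is reported per level and levels with RSD > 20 % can
be flagged by the caller.

## Group statistics

Technical replicates are averaged per mouse *before* any group
statistic; the biological n is the number of mice (default design:
6 mice × 2 technical replicates × 3 groups). Groups are summarized as
mean ± SEM and compared by unpaired two-tailed **pooled-variance
Student's t** (not Welch — the equal-variance test is the named
convention for this design), df = n_A + n_B − 2, with stars at
0.05/0.01/0.001 and no multiple-testing correction (raw p-values are
printed, as is conventional for these pairwise panels). Zero pooled
variance degenerates explicitly: equal means → t = 0, p = 1; unequal
means → flagged degenerate with p reported as < 1e−300 rather than 0.
Fold change is mean_B/mean_A.

## The synthetic-data generator

`achims.simulate` emulates the study's two layouts with full ground
truth; its defaults are the study conditions, not tuning knobs.

**Spot series**: 10 amounts (100, 50, 25, 12.5, 6.25, 3.13, 1.56, 0.78,
0.39, 0.20 pmol per 0.2 μL spot) × 8 replicate circular spots on a
tissue background, on a 120 × 120 px grid at 100 μm pitch (desk-scale
mirror of the stated spatial resolution). **Lung sections**: an
irregular lobe-like tissue mask with airway-like holes; per-group true
abundance multipliers 1.0 (saline), 2.0 (HDM), 3.0 (HDM/Alum); an
optional bright rim on the mask boundary emulating analyte accumulation
at cut edges (off by default). Tissue structure and every noise draw
depend only on the seed, never on the fold, so same-seed sections at
different folds differ exactly by the fold.

**Channels** per pixel: the analyte at its electron-corrected m/z
(146.11756), the interference at 146.163 (tissue-derived, mean
50 a.u.), the DHB internal standard at 155.03389 (mean 200 a.u.,
everywhere — it is the matrix), two chemical-background peaks flanking
the analyte (mean 1.2 a.u., the S/N reference), and cosmetic matrix
peaks. A smooth multiplicative efficiency field (low-order cosine
mixture, correlation length 30 px, amplitude 0.25) is **shared by all
channels at a pixel** — the structural assumption behind
internal-standard normalization, reflecting inhomogeneous matrix
coating and crystal heterogeneity which scale co-located ions alike.

**Noise model** (the simplest family reproducing the observed
reproducibility pattern): replicate-level multiplicative lognormal
(σ = 0.15) plus a replicate-level additive intensity floor
(σ = 2.5 a.u.), applied to the response before per-pixel lognormal
texture (σ = 0.20) and a small additive chemical term (half-normal,
σ = 0.4 a.u.). With the default response of 25 a.u./pmol this yields a
replicate RSD falling from ≈ 45 % at 0.20 pmol to ≈ 15 % at 100 pmol.
The floor default is calibrated against the *realized* RSD, because
the naive √(σ_rep² + (floor/signal)²) value is deflated by small-sample
SD bias, the chemical-background mean and truncation at zero. Absolute
intensity units are instrument-specific; the generator matches relative
structure (RSD profile, folds, linearity), never absolute published
means.

What the generator does **not** emulate: physical MALDI plume/
ionisation, isotope patterns, profile-mode peaks, chromatographic or
3-D structure, histology co-registration, section-to-section tissue
shape variability beyond the seeded mask, and real tissue-specific
interferences beyond the single 146.163 peak. Passing tests therefore
demonstrate correctness of the *analysis machinery* under the stated
statistical structure, not performance on real instrument data.

## I/O conventions

imzML (+ .ibd) via pyimzml; both continuous and processed modes are
read, the simulator writes processed mode (natural for sparse
centroided data). Pixel coordinates are 0-based (col, row), origin
top-left, row-major iteration; imzML's 1-based indices are converted at
the boundary. Intensities are float64 in memory, float32 on disk. A
zero-spectrum dataset still writes a valid file with an empty spectrum
list (only its grid extent survives the round trip). ROI sets (circles
or explicit pixel masks, optional known amount in pmol) and all tables
travel as headered CSV; images as PNG. Vendor raw formats and project
files are out of scope.

## Pipeline and reproducibility

`run_pipeline` composes the stages exactly as the individual functions
do (asserted by test) and is deterministic given its seed: per-section
seeds are spawned from (seed, group, mouse, replicate) via
`SeedSequence`. Every run writes a JSON manifest with the config,
package version, seed and a content hash per output file; imzML files
embed a random UUID on every write, so their manifest entries hash the
spectral content (coordinates + m/z + intensity arrays) rather than
file bytes. A stage failure aborts with the stage name after removing
the files written so far.

Problem sizes are chosen at desk scale: the default pipeline run uses
the full 120 × 120 spot grid but 64 × 64 sections
(3 groups × 6 mice × 2 replicates = 36 sections), completing in a few
seconds; Monte-Carlo properties in the test suite use 40–60 px grids
and 8–20 seeds, sizes at which the sampling error of each checked
statistic is comfortably inside its asserted tolerance.

## Known limitations

* Only most-abundant-isotope masses: no isotope-pattern or averagine
  modelling, no MS/MS prediction.
* The LOD rule is a declared operationalization; other reasonable rules
  (calibration-based 3.3·σ/slope, etc.) would give different values on
  noisy data.
* Back-calculation assumes the linear fit holds at the queried
  intensity; it flags but does not prevent extrapolation.
* The per-section normalization alternative is provided but untested
  against real data, where the per-pixel/per-section distinction can
  matter near tissue edges and cracks.
* The edge-accumulation artifact is modelled as a simple additive rim;
  real thaw-mounting artifacts are more structured. Whether edge pixels
  should be excluded from section means is left to the caller (the
  tissue mask can be eroded before `section_mean`).
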