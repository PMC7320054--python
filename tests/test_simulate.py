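"""Generator properties: determinism, ground-truth consistency, noise
structure, and the identifiability rationale for internal-standard
normalization."""

import numpy as np
import pytest

from achims.calibration import level_stats
from achims.imaging import (extract_ion_image, normalize_to_internal_standard,
                            roi_mean, section_mean)
from achims.simulate import (GROUP_FOLDS, SimulationConfig,
                             simulate_lung_section, simulate_spot_series)
from conftest import ACH_WINDOW, DHB_WINDOW


def _normalized_roi_means(dataset, rois):
    tgt = extract_ion_image(dataset, ACH_WINDOW)
    ref = extract_ion_image(dataset, DHB_WINDOW)
    norm = normalize_to_internal_standard(tgt, ref)
    by_amount = {}
    for label, region in rois.regions.items():
        amount = rois.known_amount[label]
        by_amount.setdefault(amount, []).append(roi_mean(norm, region)[0])
    return by_amount, tgt


def test_identical_seed_reproduces_dataset_bitwise(spot_cfg_small):
    a, _, _ = simulate_spot_series(spot_cfg_small)
    b, _, _ = simulate_spot_series(spot_cfg_small)
    for sa, sb in zip(a, b):
        assert sa.pixel == sb.pixel
        np.testing.assert_array_equal(sa.mz, sb.mz)
        np.testing.assert_array_equal(sa.intensity, sb.intensity)


def test_spot_series_layout_and_ground_truth():
    ds, rois, truth = simulate_spot_series(SimulationConfig(seed=1))
    assert len(rois) == 80  # 10 levels x 8 technical replicates
    assert set(truth.roi_amounts.values()) == set(
        SimulationConfig().amounts)
    for label, amount in truth.roi_amounts.items():
        assert rois.known_amount[label] == amount


def test_spot_grid_too_small_rejected():
    with pytest.raises(ValueError, match="too small"):
        simulate_spot_series(SimulationConfig(grid_shape=(40, 40)))


def test_noise_free_normalized_means_exactly_proportional(
        spot_cfg_noise_free):
    """Zero noise: normalized ROI mean is k/base * amount at every level,
    even though matrix heterogeneity warps the raw means."""
    ds, rois, _ = simulate_spot_series(spot_cfg_noise_free)
    by_amount, raw = _normalized_roi_means(ds, rois)
    cfg = spot_cfg_noise_free
    expected = cfg.response_per_pmol / cfg.internal_standard_base
    ratios = []
    for amount, means in by_amount.items():
        for m in means:
            assert m / amount == pytest.approx(expected, rel=1e-9)
    # raw means are NOT proportional (deposition heterogeneity survives)
    raw_by = {}
    for label, region in rois.regions.items():
        raw_by.setdefault(rois.known_amount[label], []).append(
            roi_mean(raw, region)[0])
    raw_ratios = np.array([np.mean(v) / a for a, v in raw_by.items()])
    assert np.ptp(raw_ratios) / raw_ratios.mean() > 0.01


def test_replicate_rsd_profile_decreases_with_amount():
    """Averaged over seeds, the replicate RSD% falls from ~45% at the
    lowest amount to ~15% at the highest, tracking the configured
    replicate-sigma + intensity-floor noise model."""
    cfg = SimulationConfig()
    rsds = {a: [] for a in cfg.amounts}
    for seed in range(8):
        ds, rois, _ = simulate_spot_series(cfg.with_(seed=seed))
        by_amount, _ = _normalized_roi_means(ds, rois)
        for a, vals in by_amount.items():
            rsds[a].append(level_stats(a, vals).rsd_percent)
    mean_rsd = {a: float(np.mean(v)) for a, v in rsds.items()}
    lowest, highest = min(mean_rsd), max(mean_rsd)
    assert mean_rsd[lowest] == pytest.approx(45.0, abs=8.0)
    assert mean_rsd[highest] == pytest.approx(15.0, abs=4.0)
    # monotone trend within sampling error: every low-amount level
    # (< 1 pmol) noisier than every high-amount level (> 10 pmol)
    low = [mean_rsd[a] for a in cfg.amounts if a < 1]
    high = [mean_rsd[a] for a in cfg.amounts if a > 10]
    assert min(low) > max(high)


def test_generator_rsd_converges_to_configured_value():
    """Pooling replicate spots across seeds into one large sample (no
    chemical background), the realized replicate CV at a high amount
    approaches sqrt(rep^2 + (floor/(k*a))^2) ~ rep_sigma."""
    from scipy.special import gammaln

    cfg = SimulationConfig(chem_sigma=0.0)
    rsds = []
    for seed in range(20):
        ds, rois, _ = simulate_spot_series(cfg.with_(seed=seed))
        by_amount, _ = _normalized_roi_means(ds, rois)
        rsds.append(level_stats(100.0, by_amount[100.0]).rsd_percent)
    n = cfg.replicates
    # c4 unbiasing factor for the sample SD at small n
    c4 = np.sqrt(2 / (n - 1)) * np.exp(gammaln(n / 2) - gammaln((n - 1) / 2))
    realized = np.mean(rsds) / c4
    configured = 100.0 * np.sqrt(
        cfg.rep_sigma**2
        + (cfg.floor_sigma / (cfg.response_per_pmol * 100.0)) ** 2)
    assert realized == pytest.approx(configured, rel=0.15)


def test_noise_free_fold_ratio_exact(lung_cfg_noise_free):
    means = {}
    for fold in (1.0, 3.0):
        ds, mask, _ = simulate_lung_section(lung_cfg_noise_free, fold)
        tgt = extract_ion_image(ds, ACH_WINDOW)
        ref = extract_ion_image(ds, DHB_WINDOW)
        norm = normalize_to_internal_standard(tgt, ref)
        means[fold] = section_mean(norm, mask)
    assert means[3.0] / means[1.0] == pytest.approx(3.0, rel=1e-12)


def test_seeded_fold_two_recovery_within_15_percent(lung_cfg_small):
    """Six sections per group at default noise recover the true 2x
    abundance ratio; averaged over seeds the estimate sits within 15%."""
    estimates = []
    for seed in range(10):
        vals = {1.0: [], 2.0: []}
        for fold in vals:
            for sec in range(6):
                ds, mask, _ = simulate_lung_section(
                    lung_cfg_small, fold,
                    section_seed=10_000 * seed + 100 * int(fold) + sec)
                tgt = extract_ion_image(ds, ACH_WINDOW)
                ref = extract_ion_image(ds, DHB_WINDOW)
                norm = normalize_to_internal_standard(tgt, ref)
                vals[fold].append(section_mean(norm, mask))
        estimates.append(np.mean(vals[2.0]) / np.mean(vals[1.0]))
    assert np.mean(estimates) == pytest.approx(2.0, rel=0.15)


def test_edge_artifact_brightens_boundary(lung_cfg_small):
    from scipy import ndimage

    ds, mask, _ = simulate_lung_section(
        lung_cfg_small.with_(edge_artifact=True), "saline")
    img = extract_ion_image(ds, ACH_WINDOW)
    rim = mask & ~ndimage.binary_erosion(mask, iterations=2)
    interior = ndimage.binary_erosion(mask, iterations=2)
    assert img.values[rim].mean() > img.values[interior].mean()


def test_group_names_map_to_design_folds():
    assert GROUP_FOLDS == {"saline": 1.0, "HDM": 2.0, "HDM_Alum": 3.0}
    with pytest.raises(ValueError):
        simulate_lung_section(SimulationConfig(layout="lung_section"), -1.0)


def test_off_tissue_pixels_carry_no_analyte(lung_cfg_small):
    ds, mask, _ = simulate_lung_section(lung_cfg_small, "saline")
    img = extract_ion_image(ds, ACH_WINDOW)
    assert img.values[~mask].max() == 0.0
    ref = extract_ion_image(ds, DHB_WINDOW)
    assert ref.values[~mask].min() > 0.0  # matrix everywhere
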