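"""Lock-mass recalibration, window extraction, normalization, ROI means
and heatmap rendering."""

import numpy as np
import pytest

from achims.imaging import (AmbiguousCalibrantError, HEATMAP_STOPS, IonImage,
                            MassWindow, extract_ion_image,
                            lock_mass_recalibrate,
                            normalize_to_internal_standard,
                            recalibrate_dataset, render_heatmap, roi_mean,
                            section_mean)
from achims.io import CircleROI, IMSDataset, Spectrum
from achims.simulate import (ACH_MZ, DHB_MZ, SimulationConfig,
                             simulate_lung_section, simulate_spot_series)
from conftest import ACH_WINDOW, DHB_WINDOW


def _ds(peaks_by_pixel, grid=(2, 2), mass_range=(50.0, 350.0)):
    spectra = [
        Spectrum(np.array([m for m, _ in sorted(peaks)]),
                 np.array([i for _, i in sorted(peaks)]), pixel)
        for pixel, peaks in peaks_by_pixel.items()
    ]
    return IMSDataset(grid, 100.0, spectra, mass_range)


# ---- lock-mass recalibration -------------------------------------------

def test_lock_mass_lands_calibrant_on_reference():
    s = Spectrum(np.array([100.0, 155.0350]), np.array([5.0, 50.0]), (0, 0))
    out, found = lock_mass_recalibrate(s, 155.03389, 0.01)
    assert found
    assert out.mz[1] == pytest.approx(155.03389, abs=1e-12)
    # multiplicative: the other peak scales by the same factor
    assert out.mz[0] == pytest.approx(100.0 * 155.03389 / 155.0350, abs=1e-9)
    np.testing.assert_array_equal(out.intensity, s.intensity)


def test_lock_mass_miss_returns_unchanged():
    s = Spectrum(np.array([100.0]), np.array([5.0]), (0, 0))
    out, found = lock_mass_recalibrate(s, 155.03389, 0.01)
    assert not found and out is s


def test_lock_mass_ambiguous_calibrant_names_both_peaks():
    s = Spectrum(np.array([155.030, 155.037]), np.array([5.0, 5.0]), (0, 0))
    with pytest.raises(AmbiguousCalibrantError, match="155.03000.*155.03700"):
        lock_mass_recalibrate(s, 155.03389, 0.01)


def test_uniform_ppm_distortion_removed_in_every_pixel():
    """A +30 ppm mass-axis error is corrected to < 1 ppm at the analyte."""
    cfg = SimulationConfig(seed=9, layout="lung_section", grid_shape=(32, 32),
                           mass_error_ppm=30.0)
    ds, mask, _ = simulate_lung_section(cfg, "saline")
    recal, misses = recalibrate_dataset(ds, DHB_MZ, 0.01)
    assert misses == 0
    for s in recal:
        near = np.abs(s.mz - ACH_MZ) < 0.01
        if near.any():
            err_ppm = np.abs(s.mz[near] - ACH_MZ) / ACH_MZ * 1e6
            assert err_ppm.max() < 1.0


# ---- ion-image extraction ----------------------------------------------

def test_window_excludes_isobaric_interference():
    ds = _ds({(0, 0): [(146.117, 100.0), (146.163, 50.0)]}, grid=(1, 1))
    img = extract_ion_image(ds, MassWindow(146.117, 0.02))
    assert img.values[0, 0] == 100.0


def test_empty_spectrum_gives_zero():
    ds = _ds({(0, 0): [], (1, 1): [(146.117, 3.0)]})
    img = extract_ion_image(ds, MassWindow(146.117, 0.02))
    assert img.values[0, 0] == 0.0
    assert img.values[1, 1] == 3.0


def test_sum_aggregator_adds_in_window_centroids():
    ds = _ds({(0, 0): [(146.110, 40.0), (146.120, 60.0)]}, grid=(1, 1))
    w = MassWindow(146.117, 0.02)
    assert extract_ion_image(ds, w).values[0, 0] == 100.0
    assert extract_ion_image(ds, w, aggregator="max").values[0, 0] == 60.0


def test_extraction_additive_over_disjoint_windows():
    ds = _ds({(0, 0): [(146.100, 10.0), (146.117, 100.0), (146.163, 50.0)]},
             grid=(1, 1))
    whole = extract_ion_image(ds, MassWindow(146.13, 0.04)).values[0, 0]
    left = extract_ion_image(ds, MassWindow(146.105, 0.015)).values[0, 0]
    right = extract_ion_image(ds, MassWindow(146.145, 0.025)).values[0, 0]
    assert whole == left + right


def test_window_outside_mass_range_rejected():
    ds = _ds({(0, 0): [(146.117, 1.0)]}, grid=(1, 1), mass_range=(50.0, 350.0))
    with pytest.raises(ValueError, match="outside dataset"):
        extract_ion_image(ds, MassWindow(400.0, 0.02))


# ---- internal-standard normalization -----------------------------------

def test_normalization_elementwise_ratio_and_missing():
    tgt = IonImage(np.array([[10.0, 4.0], [6.0, 1.0]]),
                   MassWindow(146.117, 0.02))
    ref = IonImage(np.array([[5.0, 2.0], [0.0, 2.0]]), DHB_WINDOW)
    out = normalize_to_internal_standard(tgt, ref)
    assert out.values[0, 0] == 2.0
    assert out.values[0, 1] == 2.0
    assert np.isnan(out.values[1, 0])  # zero reference -> missing
    assert out.n_excluded == 1
    assert out.normalized_by == DHB_WINDOW


def test_normalization_constant_reference_scales_target():
    rng = np.random.default_rng(0)
    vals = rng.uniform(1, 10, size=(4, 4))
    tgt = IonImage(vals, ACH_WINDOW)
    ref = IonImage(np.full((4, 4), 4.0), DHB_WINDOW)
    out = normalize_to_internal_standard(tgt, ref)
    np.testing.assert_allclose(out.values, vals / 4.0, rtol=1e-12)


def test_normalization_scale_equivariance():
    rng = np.random.default_rng(1)
    tgt = IonImage(rng.uniform(1, 10, (5, 5)), ACH_WINDOW)
    ref = IonImage(rng.uniform(1, 10, (5, 5)), DHB_WINDOW)
    base = normalize_to_internal_standard(tgt, ref).values
    scaled = normalize_to_internal_standard(
        IonImage(3.0 * tgt.values, ACH_WINDOW), ref).values
    np.testing.assert_allclose(scaled, 3.0 * base, rtol=1e-12)
    # a shared per-pixel field cancels entirely
    field = rng.uniform(0.5, 2.0, (5, 5))
    both = normalize_to_internal_standard(
        IonImage(tgt.values * field, ACH_WINDOW),
        IonImage(ref.values * field, DHB_WINDOW)).values
    np.testing.assert_allclose(both, base, rtol=1e-12)


def test_normalization_grid_mismatch_rejected():
    with pytest.raises(ValueError, match="grid mismatch"):
        normalize_to_internal_standard(
            IonImage(np.ones((2, 2)), ACH_WINDOW),
            IonImage(np.ones((3, 3)), DHB_WINDOW))


# ---- ROI and section means ---------------------------------------------

def test_roi_mean_basic_and_missing_exclusion():
    img = IonImage(np.array([[4.0, 6.0]]), ACH_WINDOW)
    roi = np.array([[True, True]])
    assert roi_mean(img, roi) == (5.0, 2)
    img2 = IonImage(np.array([[4.0, np.nan]]), ACH_WINDOW,
                    normalized_by=DHB_WINDOW)
    assert roi_mean(img2, roi) == (4.0, 1)


def test_roi_entirely_missing_is_an_error():
    img = IonImage(np.array([[np.nan, np.nan]]), ACH_WINDOW,
                   normalized_by=DHB_WINDOW)
    with pytest.raises(ValueError, match="no non-missing"):
        roi_mean(img, np.array([[True, True]]))


def test_roi_mean_of_noise_free_spot_matches_ground_truth(
        spot_cfg_noise_free):
    ds, rois, truth = simulate_spot_series(spot_cfg_noise_free)
    tgt = extract_ion_image(ds, ACH_WINDOW)
    ref = extract_ion_image(ds, DHB_WINDOW)
    norm = normalize_to_internal_standard(tgt, ref)
    k = (spot_cfg_noise_free.response_per_pmol
         / spot_cfg_noise_free.internal_standard_base)
    for label, region in rois.regions.items():
        mean, n = roi_mean(norm, region)
        assert n > 0
        assert mean == pytest.approx(k * truth.roi_amounts[label], rel=1e-9)


def test_section_mean_fold_invariant(lung_cfg_noise_free):
    vals = {}
    for fold in (1.0, 2.0):
        ds, mask, _ = simulate_lung_section(lung_cfg_noise_free, fold)
        norm = normalize_to_internal_standard(
            extract_ion_image(ds, ACH_WINDOW),
            extract_ion_image(ds, DHB_WINDOW))
        vals[fold] = section_mean(norm, mask)
    assert vals[2.0] / vals[1.0] == pytest.approx(2.0, rel=1e-12)


# ---- heatmap rendering --------------------------------------------------

def test_heatmap_endpoints_and_missing_colour():
    img = IonImage(np.array([[0.0, 5.0, 10.0, np.nan]]), ACH_WINDOW,
                   normalized_by=DHB_WINDOW)
    rgb, scale = render_heatmap(img, scale=(0.0, 10.0))
    assert scale == (0.0, 10.0)
    np.testing.assert_array_equal(rgb[0, 0], [0, 0, 0])       # lo -> black
    np.testing.assert_array_equal(rgb[0, 2], [255, 255, 255])  # hi -> white
    np.testing.assert_array_equal(rgb[0, 3], [128, 128, 128])  # missing
    # below/above the scale clamp to the endpoints
    rgb2, _ = render_heatmap(IonImage(np.array([[-1.0e3, 1.0e6]]),
                                      ACH_WINDOW, normalized_by=DHB_WINDOW),
                             scale=(0.0, 10.0))
    np.testing.assert_array_equal(rgb2[0, 0], [0, 0, 0])
    np.testing.assert_array_equal(rgb2[0, 1], [255, 255, 255])


def test_heatmap_monotone_ramp_follows_colormap_index():
    """A monotone intensity ramp maps to monotone colormap positions."""
    from matplotlib.colors import LinearSegmentedColormap

    ramp = np.linspace(0.0, 1.0, 64)[None, :]
    rgb, _ = render_heatmap(IonImage(ramp, ACH_WINDOW), scale=(0.0, 1.0))
    cmap = LinearSegmentedColormap.from_list(
        "oracle", [(p, c) for p, c in HEATMAP_STOPS])
    expected = (cmap(np.linspace(0, 1, 64))[:, :3] * 255).round()
    np.testing.assert_array_equal(rgb[0], expected.astype(np.uint8))


def test_heatmap_degenerate_scale_rejected():
    img = IonImage(np.ones((2, 2)), ACH_WINDOW)
    with pytest.raises(ValueError, match="degenerate"):
        render_heatmap(img, scale=(1.0, 1.0))


def test_heatmap_autoscale_reported():
    rng = np.random.default_rng(2)
    img = IonImage(rng.uniform(0, 100, (20, 20)), ACH_WINDOW)
    _, (lo, hi) = render_heatmap(img)
    assert lo == pytest.approx(np.percentile(img.values, 1))
    assert hi == pytest.approx(np.percentile(img.values, 99))
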