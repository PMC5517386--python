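"""Gated-CT volumetry: resampling, histogram fit, segmentation, EF."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

import cardiophantom as cp
from cardiophantom.ct import (HistogramFitError, SegmentationError,
                              analyze_phase, clean_mask, compute_ef,
                              fit_double_gaussian, histogram_for_fit,
                              mask_volume_ml, resample_long_axis, segment_lv,
                              segmentation_threshold, SegMask, HistogramFit)
from cardiophantom.grids import ImageVolume, VolumeCurve
from cardiophantom.phantom import cavity_volume_at_phase

CT_FOV, CT_MATRIX = 115.2, 128  # 0.9 mm isotropic


# ---------------------------------------------------------------- resampling

def test_identity_resample_returns_input():
    cfg = cp.PhantomConfig(ef_nominal=65, ct_noise_sd=0)
    vol = cp.rasterize_ct(cfg, 0.0, fov_mm=CT_FOV, matrix=64)
    out = resample_long_axis(vol, vol.spacing_mm[0])
    np.testing.assert_allclose(out.grid, vol.grid, atol=1e-6)


def test_rotated_volume_realigned_with_mass_preserved():
    cfg = cp.PhantomConfig(ef_nominal=65, ct_noise_sd=0,
                           long_axis=(1.0, 0.0, 0.0))  # 90 deg off
    vol = cp.rasterize_ct(cfg, 0.0, fov_mm=CT_FOV, matrix=96)
    iso = vol.spacing_mm[0]
    out = resample_long_axis(vol, iso)
    assert np.allclose(out.long_axis, (0, 0, 1))
    mass_in = vol.grid.sum() * vol.voxel_volume_ml
    mass_out = out.grid.sum() * out.voxel_volume_ml
    assert mass_out == pytest.approx(mass_in, rel=0.01)
    # the realigned object is longest along the third grid axis
    shell = out.grid > 400
    spans = [np.ptp(np.nonzero(shell)[i]) for i in range(3)]
    assert np.argmax(spans) == 2


def test_constant_volume_stays_constant():
    vol = ImageVolume(np.full((24, 24, 24), 7.0), (1.0, 1.5, 1.0),
                      "HU", (0.0, 1.0, 0.0))
    out = resample_long_axis(vol, 1.0)
    np.testing.assert_allclose(out.grid, 7.0, atol=1e-6)


# ------------------------------------------------------------- histogram fit

def _mixture_histogram(seed=0, n=200_000, w=0.7, mus=(0.0, 800.0),
                       sigmas=(20.0, 50.0)):
    rng = np.random.default_rng(seed)
    n1 = int(w * n)
    samples = np.concatenate([rng.normal(mus[0], sigmas[0], n1),
                              rng.normal(mus[1], sigmas[1], n - n1)])
    return histogram_for_fit(samples)


def test_double_gaussian_recovers_generator_means():
    fit = fit_double_gaussian(_mixture_histogram(seed=1))
    assert abs(fit.mu1 - 0.0) < 5.0
    assert abs(fit.mu2 - 800.0) < 5.0
    assert fit.mu1 < fit.mu2
    assert fit.sigma1 > 0 and fit.sigma2 > 0 and fit.residual >= 0


def test_unimodal_histogram_rejected():
    rng = np.random.default_rng(2)
    hist = histogram_for_fit(rng.normal(100.0, 30.0, 100_000))
    with pytest.raises(HistogramFitError):
        fit_double_gaussian(hist)


def test_peak_ordering_enforced():
    # mirrored mixture: dominant peak on the high side
    fit = fit_double_gaussian(_mixture_histogram(seed=3, w=0.3))
    assert fit.mu1 < fit.mu2


@pytest.mark.parametrize("mu1, mu2, expected", [
    (0.0, 800.0, 400.0), (-10.0, 790.0, 390.0), (120.0, 120.0, 120.0),
])
def test_threshold_is_peak_midpoint(mu1, mu2, expected):
    fit = HistogramFit(mu1, mu2, 10.0, 10.0, 1.0, 1.0, 0.0)
    assert segmentation_threshold(fit) == pytest.approx(expected)
    assert segmentation_threshold(fit, "half_upper") == pytest.approx(mu2 / 2)


@given(shift=st.floats(-300, 300))
def test_threshold_equivariant_under_intensity_shift(shift):
    centers, counts = _mixture_histogram(seed=4)
    base = segmentation_threshold(fit_double_gaussian((centers, counts)))
    moved = segmentation_threshold(fit_double_gaussian((centers + shift, counts)))
    assert moved - base == pytest.approx(shift, abs=1.0)


# -------------------------------------------------------------- segmentation

def test_segment_recovers_phantom_volume_within_2pct():
    cfg = cp.PhantomConfig(ef_nominal=65, ct_noise_sd=0)
    for phase in (0.0, cfg.systolic_duty):
        vol = cp.rasterize_ct(cfg, phase, fov_mm=CT_FOV, matrix=CT_MATRIX)
        v, mask, _ = analyze_phase(vol)
        assert v == pytest.approx(cavity_volume_at_phase(cfg, phase), rel=0.02)


def test_all_background_volume_fails():
    vol = ImageVolume(np.zeros((16, 16, 16)), (1.0, 1.0, 1.0))
    with pytest.raises(SegmentationError):
        segment_lv(vol, 400.0)


def test_cleanup_is_idempotent():
    cfg = cp.PhantomConfig(ef_nominal=65, seed=5)
    vol = cp.rasterize_ct(cfg, 0.3, fov_mm=CT_FOV, matrix=96)
    mask = segment_lv(vol, 400.0)
    again = clean_mask(mask.grid)
    np.testing.assert_array_equal(mask.grid, again)


def test_mask_volume_arithmetic():
    grid = np.zeros((20, 20, 20), dtype=bool)
    grid.flat[:1000] = True
    assert mask_volume_ml(SegMask(grid, (0.6, 0.6, 0.6), 400.0)) == \
        pytest.approx(0.216)
    assert mask_volume_ml(SegMask(np.zeros((5, 5, 5)), (1, 1, 1), 0.0)) == 0.0
    other = np.zeros((20, 20, 20), dtype=bool)
    other.flat[2000:2500] = True
    union = mask_volume_ml(SegMask(grid | other, (0.6, 0.6, 0.6), 400.0))
    assert union == pytest.approx(
        mask_volume_ml(SegMask(grid, (0.6,) * 3, 0)) +
        mask_volume_ml(SegMask(other, (0.6,) * 3, 0)))


# ------------------------------------------------------------------- EF math

@pytest.mark.parametrize("edv, esv, expected_1dp", [
    (93.6, 32.6, 65.2),
    (110.4, 32.5, 70.6),
    (95.2, 33.3, 65.0),
])
def test_ef_matches_reported_phantom_validation_rows(edv, esv, expected_1dp):
    curve = VolumeCurve([0.0, 0.35], [edv, esv])
    res = compute_ef(curve)
    assert cp.round_half_away(res.ef_percent, 1) == pytest.approx(expected_1dp)
    assert res.edv_ml == edv and res.esv_ml == esv


def test_ef_degenerate_and_domain():
    assert compute_ef(VolumeCurve([0, 0.5], [40.0, 40.0])).ef_percent == 0.0
    with pytest.raises(ValueError):
        compute_ef(VolumeCurve([0, 0.5], [40.0, -1.0]))


@given(scale=st.floats(0.01, 100))
def test_ef_scale_invariant(scale):
    v = np.array([60.0, 45.0, 33.0, 50.0])
    base = compute_ef(VolumeCurve(np.linspace(0, 0.75, 4), v))
    scaled = compute_ef(VolumeCurve(np.linspace(0, 0.75, 4), v * scale))
    assert scaled.ef_percent == pytest.approx(base.ef_percent, abs=1e-9)


# ------------------------------------------------------------------ pipeline

def test_pipeline_two_phase_equals_full_curve_ef():
    cfg = cp.PhantomConfig(ef_nominal=65, seed=2)
    series2, _ = cp.simulate_gated_ct(cfg, n_phases=2, fov_mm=CT_FOV,
                                      matrix=CT_MATRIX)
    series5, _ = cp.simulate_gated_ct(cfg, n_phases=5, fov_mm=CT_FOV,
                                      matrix=CT_MATRIX)
    _, ef2 = cp.ct_pipeline(series2)
    _, ef5 = cp.ct_pipeline(series5)
    assert ef2.ef_percent == pytest.approx(ef5.ef_percent, abs=0.1)


def test_noise_free_pipeline_curve_tracks_truth():
    cfg = cp.PhantomConfig(ef_nominal=55, ct_noise_sd=0)
    series, truth = cp.simulate_gated_ct(cfg, n_phases=5, fov_mm=CT_FOV,
                                         matrix=CT_MATRIX)
    curve, ef, qc = cp.ct_pipeline(series, qc=True)
    np.testing.assert_allclose(curve.volumes_ml, truth.volumes_ml, rtol=0.02)
    assert not qc["outlier"].any()
    # sinusoidal-like: one max and one min over the cycle
    assert ef.edv_phase_index != ef.esv_phase_index


def test_parameter_recovery_over_random_configs():
    """Median EF error < 0.5 points over 50 random settings at 15 HU noise."""
    rng = np.random.default_rng(12345)
    errors = []
    for _ in range(50):
        cfg = cp.PhantomConfig(
            ef_nominal=float(rng.uniform(40, 72)),
            esv_ml=float(rng.uniform(28, 38)),
            seed=int(rng.integers(0, 2**31 - 1)))
        series, _ = cp.simulate_gated_ct(cfg, n_phases=2, fov_mm=CT_FOV,
                                         matrix=CT_MATRIX)
        _, ef = cp.ct_pipeline(series)
        errors.append(abs(ef.ef_percent - cfg.ef_nominal))
    assert np.median(errors) < 0.5
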