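"""Acquisition simulator: protocols, PSF, projector physics, gating, noise."""
import numpy as np
import pytest

import cardiophantom as cp
from cardiophantom.grids import ImageVolume
from cardiophantom.spect import (AcquisitionProtocol, PSFModel, ProjectionSet,
                                 SystemModel, default_psf, forward_project,
                                 gate_phase_samples, make_protocol,
                                 psf_sigma_at_depth, simulate_gated_acquisition)

SMALL = AcquisitionProtocol("LEHR", 180.0, 16, 11.25, 25.0, 250.0, 32, 4.8, 8)


def test_iqspect_protocol_geometry():
    p = make_protocol("IQSPECT")
    assert p.arc_deg == 204.0
    assert p.n_projections == 34
    assert p.step_deg == pytest.approx(6.12)
    assert p.time_per_view_s == 30.0
    assert p.orbit_radius_mm == 280.0
    assert p.n_gates == 8
    assert p.angles_deg.max() < 204.0 + p.step_deg


def test_lehr_protocol_geometry():
    p = make_protocol("LEHR")
    assert (p.arc_deg, p.n_projections, p.step_deg, p.time_per_view_s) == \
        (180.0, 128, 1.4, 25.0)
    assert p.matrix == 128 and p.pixel_mm == 4.8
    assert p.angles_deg.min() == 0.0 and p.angles_deg.max() < 180.0


def test_protocol_consistency_invariant():
    for name in ("LEHR", "IQSPECT"):
        p = make_protocol(name)
        assert abs(p.n_projections * p.step_deg - p.arc_deg) <= p.step_deg
    with pytest.raises(ValueError):
        make_protocol("FANBEAM")
    with pytest.raises(ValueError):
        AcquisitionProtocol("X", 180.0, 10, 1.0, 1.0, 250.0, 64, 4.8, 8)


@pytest.mark.parametrize("sigma0, slope, depth, expected", [
    (1.5, 0.02, 0.0, 1.5), (1.5, 0.02, 100.0, 3.5), (2.0, 0.0, 500.0, 2.0),
])
def test_psf_sigma_linear_in_depth(sigma0, slope, depth, expected):
    assert psf_sigma_at_depth(PSFModel(sigma0, slope), depth) == \
        pytest.approx(expected)


def test_psf_rejects_negative_depth():
    with pytest.raises(ValueError):
        psf_sigma_at_depth(PSFModel(), -1.0)


def test_zero_activity_projects_to_zero():
    act = ImageVolume(np.zeros((33, 33, 9)), (4.8,) * 3, "activity")
    ps = forward_project(act, SMALL, PSFModel(1.5, 0.0, 1.0))
    assert not np.any(ps.counts)


def test_point_source_spreads_with_collimator_sigma():
    """Each view of a centred point shows a Gaussian of the PSF sigma."""
    act = np.zeros((33, 33, 23))
    act[16, 16, 11] = 1000.0  # exactly at the rotation centre (odd grid)
    model = SystemModel((33, 33, 23), 4.8, SMALL, PSFModel(6.0, 0.0, 1.0))
    for k in (0, 5, 11):
        proj = model.forward_view(act, k)
        u = (np.arange(33) - 16) * 4.8
        prof = proj[:, 11]
        mu = (u * prof).sum() / prof.sum()
        sig = np.sqrt(((u - mu) ** 2 * prof).sum() / prof.sum())
        assert sig == pytest.approx(6.0, rel=0.05)


def test_counts_conserved_across_views():
    """No attenuation: a centred source projects the same total into every
    view (line-integral conservation)."""
    xx = np.arange(33) - 16.0
    X, Y = np.meshgrid(xx, xx, indexing="ij")
    blob = np.exp(-(X**2 + Y**2) / (2 * 3.0**2))[:, :, None] * \
        np.exp(-((np.arange(23) - 11.0)**2) / 8.0)[None, None, :]
    blob[blob < 1e-5 * blob.max()] = 0.0
    act = ImageVolume(blob, (4.8,) * 3, "activity")
    ps = forward_project(act, SMALL, PSFModel(1.5, 0.012, 1.0))
    totals = ps.counts[0].sum(axis=(1, 2))
    assert np.ptp(totals) / totals.mean() < 0.01


def test_counts_linear_in_time_and_concentration():
    cfg1 = cp.PhantomConfig(ef_nominal=65, activity_conc=1000.0)
    cfg2 = cp.PhantomConfig(ef_nominal=65, activity_conc=2000.0)
    a = simulate_gated_acquisition(cfg1, SMALL, seed=0, matrix=32, nz=24)
    b = simulate_gated_acquisition(cfg2, SMALL, seed=0, matrix=32, nz=24)
    np.testing.assert_allclose(b.noiseless_mean, 2 * a.noiseless_mean, rtol=1e-12)
    slow = AcquisitionProtocol("LEHR", 180.0, 16, 11.25, 50.0, 250.0, 32, 4.8, 8)
    c = simulate_gated_acquisition(cfg1, slow, seed=0, matrix=32, nz=24)
    np.testing.assert_allclose(c.noiseless_mean, 2 * a.noiseless_mean, rtol=1e-12)


def test_gated_means_sum_to_ungated_total():
    """8 gates x 4 sub-phases partition the cycle exactly like 1 gate x 32."""
    cfg = cp.PhantomConfig(ef_nominal=65)
    gated = simulate_gated_acquisition(cfg, SMALL, seed=0, matrix=32, nz=24,
                                       n_subphases=4)
    ungated_proto = AcquisitionProtocol("LEHR", 180.0, 16, 11.25, 25.0, 250.0,
                                        32, 4.8, 1)
    ungated = simulate_gated_acquisition(cfg, ungated_proto, seed=0, matrix=32,
                                         nz=24, n_subphases=32)
    gate_total = gated.noiseless_mean.sum(axis=0)
    np.testing.assert_allclose(gate_total, ungated.noiseless_mean[0], rtol=1e-6)


def test_gate_windows_are_centred_and_uniform():
    s = gate_phase_samples(8, 4)
    assert s.shape == (8, 4)
    union = np.sort(s.ravel())
    np.testing.assert_allclose(np.diff(union), 1 / 32, atol=1e-12)


def test_poisson_counts_match_expected_mean():
    cfg = cp.PhantomConfig(ef_nominal=65)
    proto = AcquisitionProtocol("LEHR", 180.0, 4, 45.0, 25.0, 250.0, 32, 4.8, 1)
    base = simulate_gated_acquisition(cfg, proto, seed=0, matrix=32, nz=24)
    acc = np.zeros_like(base.noiseless_mean)
    for seed in range(100):
        acc += simulate_gated_acquisition(cfg, proto, seed=seed, matrix=32,
                                          nz=24).counts
    acc /= 100
    view_means = acc.sum(axis=(2, 3))
    expected = base.noiseless_mean.sum(axis=(2, 3))
    np.testing.assert_allclose(view_means, expected, rtol=0.01)


def test_same_seed_reproduces_projections():
    cfg = cp.PhantomConfig(ef_nominal=55)
    a = simulate_gated_acquisition(cfg, SMALL, seed=42, matrix=32, nz=24)
    b = simulate_gated_acquisition(cfg, SMALL, seed=42, matrix=32, nz=24)
    np.testing.assert_array_equal(a.counts, b.counts)
    c = simulate_gated_acquisition(cfg, SMALL, seed=43, matrix=32, nz=24)
    assert not np.array_equal(a.counts, c.counts)


def test_activity_outside_fov_rejected():
    act = np.zeros((33, 33, 9))
    act[0, 5, 4] = 10.0  # on the grid boundary
    vol = ImageVolume(act, (4.8,) * 3, "activity")
    with pytest.raises(ValueError, match="clipped|boundary"):
        forward_project(vol, SMALL, PSFModel(1.5, 0.0, 1.0))
    # outside the magnified central field of the focused protocol
    act2 = np.zeros((33, 33, 9))
    act2[2, 16, 4] = 10.0
    vol2 = ImageVolume(act2, (4.8,) * 3, "activity")
    with pytest.raises(ValueError, match="magnified"):
        forward_project(vol2, SMALL, PSFModel(1.5, 0.0, 2.0))


def test_magnification_doubles_central_sensitivity():
    act = np.zeros((33, 33, 9))
    act[16, 16, 4] = 1000.0
    vol = ImageVolume(act, (4.8,) * 3, "activity")
    plain = forward_project(vol, SMALL, PSFModel(1.5, 0.0, 1.0))
    mag = forward_project(vol, SMALL, PSFModel(1.5, 0.0, 2.0))
    ratio = mag.counts.sum() / plain.counts.sum()
    assert ratio == pytest.approx(2.0, rel=0.05)


def test_projection_set_roundtrip(tmp_path):
    cfg = cp.PhantomConfig(ef_nominal=65)
    ps = simulate_gated_acquisition(cfg, SMALL, seed=9, matrix=32, nz=24)
    ps.save(tmp_path / "proj")
    back = ProjectionSet.load(tmp_path / "proj")
    np.testing.assert_array_equal(back.counts, ps.counts)
    np.testing.assert_allclose(back.angles_deg, ps.angles_deg)
    assert back.protocol == ps.protocol
    assert back.count_scale == ps.count_scale
    assert back.grid_shape == ps.grid_shape
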