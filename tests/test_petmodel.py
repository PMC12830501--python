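"""Acquisition model: projector, attenuation, Poisson simulation, OSEM."""

import numpy as np
import pytest

from gaprc.kernels import WATER
from gaprc.petmodel import (OSEM, ReconConfig, ScannerGeometry, Sinogram,
                            SystemModel, back_project, expected_sinogram,
                            forward_project, insert_lesion_sinogram,
                            make_mu_map, mc_annihilation_image,
                            osem_reconstruct, simulate_acquisition,
                            split_half_acquisition)
from gaprc.prc import PRCOperator
from gaprc.segmentation import TissueMaskSet
from gaprc.volumes import ActivityVolume, CTVolume, Grid

VOX = (2.0, 2.0, 2.0)


def _geom(n_angles=24, n_radial=24, n_planes=1):
    return ScannerGeometry(n_angles, n_radial, VOX[0], n_planes)


def _origin(shape):
    return tuple(-(s - 1) / 2.0 * v for s, v in zip(shape, VOX))


def _act(data):
    data = np.asarray(data, dtype=float)
    return ActivityVolume(data, VOX, _origin(data.shape))


def _model(shape, mu=None, psf=0.0, prc=None, geom=None):
    geom = geom or _geom(n_planes=shape[2])
    mu_map = None
    if mu is not None:
        mu_map = ActivityVolume(mu, VOX, _origin(shape))
    return SystemModel(geom, VOX, mu_map=mu_map, psf_fwhm=psf,
                       prc=prc or PRCOperator.none())


# ---------------------------------------------------------------------------
# mu map
# ---------------------------------------------------------------------------

def test_mu_map_anchors_and_formula():
    hu = np.array([[[-1000.0, 0.0, 500.0, -2000.0]]])
    ct = CTVolume(hu, VOX)
    mu = make_mu_map(ct).data
    assert mu[0, 0, 0] == 0.0
    assert mu[0, 0, 1] == pytest.approx(0.0096)
    # independent evaluation of the stated piecewise-linear rule at HU 500
    assert mu[0, 0, 2] == pytest.approx(0.0096 * (1 + 0.5 * 500 / 1000))
    assert mu[0, 0, 3] == 0.0  # clipped


# ---------------------------------------------------------------------------
# projector
# ---------------------------------------------------------------------------

def test_zero_image_projects_to_zero():
    shape = (16, 16, 1)
    sino = forward_project(_act(np.zeros(shape)), _model(shape))
    assert np.all(sino.counts == 0)


def test_point_source_per_view_counts_conservation():
    """Without attenuation/PSF/PRC every view's total equals the voxel
    activity times voxel volume (in mL)."""
    shape = (16, 16, 1)
    img = np.zeros(shape)
    img[9, 6, 0] = 1000.0
    sino = forward_project(_act(img), _model(shape))
    expected = 1000.0 * np.prod(VOX) / 1000.0
    per_view = sino.counts.sum(axis=1)[:, 0]
    np.testing.assert_allclose(per_view, expected, rtol=1e-6)


def test_central_point_source_beer_lambert_attenuation():
    """Uniform disc of mu around a central point source: every view is
    attenuated by exp(-mu * chord) with chord the disc diameter."""
    shape = (33, 33, 1)
    mu_val = 0.0096
    x = (np.arange(33) - 16.0) * VOX[0]
    gx, gy = np.meshgrid(x, x, indexing="ij")
    r_vox = 12
    disc = (gx ** 2 + gy ** 2 <= (r_vox * VOX[0]) ** 2)
    mu = np.zeros(shape)
    mu[disc, 0] = mu_val
    img = np.zeros(shape)
    img[16, 16, 0] = 1.0
    y0 = forward_project(_act(img), _model(shape)).counts
    y1 = forward_project(_act(img), _model(shape, mu=mu)).counts
    ratio = y1.sum(axis=1)[:, 0] / y0.sum(axis=1)[:, 0]
    chord = 2 * r_vox * VOX[0]
    # voxelisation perturbs the chord by up to ~1 voxel per ray
    np.testing.assert_allclose(ratio, np.exp(-mu_val * chord), rtol=0.04)


def test_back_project_of_zero_is_zero_and_nonnegative(rng):
    shape = (12, 12, 1)
    model = _model(shape)
    g = model.geometry
    zero = Sinogram(np.zeros((g.n_angles, g.n_radial, 1)), g)
    assert np.all(back_project(zero, model, shape).data == 0)
    uniform = Sinogram(np.ones((g.n_angles, g.n_radial, 1)), g)
    assert np.all(back_project(uniform, model, shape).data >= 0)


def test_full_system_adjointness_with_psf_and_prc(small_kernels, rng):
    """<A x, y> == <x, A^T y> including attenuation, PSF and the
    range-correction operator (1e-8 relative)."""
    from gaprc.petmodel import _backward_raw, _forward_raw

    shape = (16, 16, 2)
    vox = small_kernels["water"].voxel_size
    label = np.zeros(shape, dtype=int)
    label[8:] = 1
    from gaprc.kernels import LUNG
    masks = TissueMaskSet((LUNG, WATER), label, Grid(shape, vox))
    prc = PRCOperator.tdsv([small_kernels["lung"], small_kernels["water"]],
                           masks)
    geom = ScannerGeometry(20, 20, vox[0], shape[2])
    mu = ActivityVolume(rng.random(shape) * 0.01, vox)
    model = SystemModel(geom, vox, mu_map=mu, psf_fwhm=4.0, prc=prc)
    proj = model._projector(shape)
    att = model.attenuation(shape)
    x = rng.random(shape)
    y = rng.random((geom.n_angles * geom.n_radial, shape[2]))
    lhs = np.vdot(_forward_raw(x, model, proj, att), y)
    rhs = np.vdot(x, _backward_raw(y, model, proj, att))
    assert lhs == pytest.approx(rhs, rel=1e-8)


# ---------------------------------------------------------------------------
# acquisition simulation
# ---------------------------------------------------------------------------

def _toy_phantom(shape=(16, 16, 1)):
    hu = np.full(shape, -1000.0)
    hu[4:12, 4:12] = 0.0
    act = np.zeros(shape)
    act[5:11, 5:11] = 100.0
    origin = _origin(shape)
    return CTVolume(hu, VOX, origin), ActivityVolume(act, VOX, origin)


def test_expected_counts_scale_linearly_with_budget(small_kernels):
    ct, act = _toy_phantom()
    model = _model(ct.hu.shape)
    a = expected_sinogram(act, ct, model, small_kernels, 1000.0)
    b = expected_sinogram(act, ct, model, small_kernels, 2000.0)
    np.testing.assert_allclose(2.0 * a.counts, b.counts, rtol=1e-12)


def test_zero_activity_gives_empty_sinogram(small_kernels):
    ct, act = _toy_phantom()
    zero = act.with_data(np.zeros_like(act.data))
    sino = simulate_acquisition(zero, ct, _model(ct.hu.shape), 1000.0, 1,
                                kernels=small_kernels)
    assert sino.counts.sum() == 0


def test_poisson_sampling_matches_expectation(small_kernels):
    """Mean over 200 replicates within 3 sigma of the expectation bin-wise
    for ~99% of bins."""
    ct, act = _toy_phantom()
    model = _model(ct.hu.shape)
    ybar = expected_sinogram(act, ct, model, small_kernels, 20_000.0)
    reps = np.stack([
        simulate_acquisition(act, ct, model, 20_000.0, 100 + i,
                             kernels=small_kernels).counts
        for i in range(200)])
    mean = reps.mean(axis=0)
    sigma = np.sqrt(np.maximum(ybar.counts, 1e-12) / 200)
    ok = np.abs(mean - ybar.counts) <= 3 * sigma + 1e-9
    assert ok.mean() > 0.98


def test_lesion_insertion_zero_lesion_is_noop(small_kernels):
    ct, act = _toy_phantom()
    model = _model(ct.hu.shape)
    sino = simulate_acquisition(act, ct, model, 5000.0, 3,
                                kernels=small_kernels)
    zero = act.with_data(np.zeros_like(act.data))
    out = insert_lesion_sinogram(sino, zero, ct, model, 4,
                                 kernels=small_kernels,
                                 range_model="lesion_kernel",
                                 lesion_tissue="water")
    np.testing.assert_array_equal(out.counts, sino.counts)


def test_lesion_insertion_adds_expected_counts(small_kernels):
    ct, act = _toy_phantom()
    model = _model(ct.hu.shape)
    sino = simulate_acquisition(act, ct, model, 50_000.0, 3,
                                kernels=small_kernels)
    lesion = act.with_data(np.zeros_like(act.data))
    lesion.data[8, 8, 0] = 500.0
    out = insert_lesion_sinogram(sino, lesion, ct, model, 5,
                                 kernels=small_kernels,
                                 range_model="lesion_kernel",
                                 lesion_tissue="water")
    added = out.counts.sum() - sino.counts.sum()
    from gaprc.petmodel import lesion_expected_sinogram
    exp = (lesion_expected_sinogram(lesion, ct, model, small_kernels,
                                    range_model="lesion_kernel",
                                    lesion_tissue="water") * sino.scale).sum()
    assert added == pytest.approx(exp, abs=4 * np.sqrt(exp))


def test_lesion_expectation_is_linear_in_activity(small_kernels):
    from gaprc.petmodel import lesion_expected_sinogram
    ct, act = _toy_phantom()
    model = _model(ct.hu.shape)
    lesion = act.with_data(np.zeros_like(act.data))
    lesion.data[8, 8, 0] = 500.0
    double = lesion.with_data(2.0 * lesion.data)
    a = lesion_expected_sinogram(lesion, ct, model, small_kernels,
                                 range_model="lesion_kernel",
                                 lesion_tissue="water")
    b = lesion_expected_sinogram(double, ct, model, small_kernels,
                                 range_model="lesion_kernel",
                                 lesion_tissue="water")
    np.testing.assert_allclose(2.0 * a, b, rtol=1e-12)


def test_lesion_insertion_requires_noisy_host(small_kernels):
    ct, act = _toy_phantom()
    model = _model(ct.hu.shape)
    ybar = expected_sinogram(act, ct, model, small_kernels, 1000.0)
    with pytest.raises(ValueError, match="noisy"):
        insert_lesion_sinogram(ybar, act, ct, model, 1, kernels=small_kernels)


def test_mc_annihilation_image_conserves_activity(small_kernels):
    ct, act = _toy_phantom((16, 16, 5))
    lesion = act.with_data(np.zeros_like(act.data))
    lesion.data[8, 8, 2] = 900.0
    out = mc_annihilation_image(lesion, ct, 20_000, seed=2)
    # total activity preserved up to the fraction escaping the FOV
    assert out.data.sum() == pytest.approx(
        900.0 * out.meta["annihilated_fraction"], rel=1e-12)
    assert out.meta["annihilated_fraction"] > 0.5
    # blur spreads activity beyond the source voxel
    assert out.data[8, 8, 2] < 900.0
    assert (out.data > 0).sum() > 1


# ---------------------------------------------------------------------------
# half splitting
# ---------------------------------------------------------------------------

def test_half_split_expectation_and_independence(small_kernels):
    ct, act = _toy_phantom((8, 8, 1))
    model = _model(ct.hu.shape, geom=_geom(8, 8, 1))
    ybar = expected_sinogram(act, ct, model, small_kernels, 4000.0)
    h1s, h2s = [], []
    for i in range(200):
        h1, h2 = split_half_acquisition(act, ct, model, 4000.0, 300 + i,
                                        kernels=small_kernels)
        h1s.append(h1.counts)
        h2s.append(h2.counts)
    h1s = np.stack(h1s)
    h2s = np.stack(h2s)
    total_mean = (h1s + h2s).mean(axis=0)
    sigma = np.sqrt(np.maximum(ybar.counts, 1e-12) / 200)
    assert (np.abs(total_mean - ybar.counts) <= 3 * sigma + 1e-9).mean() > 0.97
    # independence: per-bin covariance consistent with zero
    c1 = h1s - h1s.mean(axis=0)
    c2 = h2s - h2s.mean(axis=0)
    cov = (c1 * c2).mean(axis=0)
    var = np.sqrt(h1s.var(axis=0) * h2s.var(axis=0))
    mask = var > 0
    assert np.abs(cov[mask] / var[mask]).mean() < 0.1


def test_half_split_reproducible_under_seed(small_kernels):
    ct, act = _toy_phantom((8, 8, 1))
    model = _model(ct.hu.shape, geom=_geom(8, 8, 1))
    a = split_half_acquisition(act, ct, model, 1000.0, 7, kernels=small_kernels)
    b = split_half_acquisition(act, ct, model, 1000.0, 7, kernels=small_kernels)
    np.testing.assert_array_equal(a[0].counts, b[0].counts)
    np.testing.assert_array_equal(a[1].counts, b[1].counts)


# ---------------------------------------------------------------------------
# OSEM
# ---------------------------------------------------------------------------

def test_osem_rmse_decreases_on_noiseless_data():
    """Matched model, noiseless data: image RMSE vs truth is non-increasing
    over 20 iterations."""
    shape = (24, 24, 1)
    x = (np.arange(24) - 11.5) * VOX[0]
    gx, gy = np.meshgrid(x, x, indexing="ij")
    truth = np.exp(-(gx ** 2 + gy ** 2) / (2 * 8.0 ** 2))[..., None] * 100.0
    body = (gx ** 2 + gy ** 2 <= 20.0 ** 2)[..., None]
    truth = truth * body
    model = _model(shape, geom=_geom(30, 34, 1))
    ybar = forward_project(_act(truth), model)
    sino = Sinogram(ybar.counts, model.geometry, is_noisy=True)
    rmses = []

    def cb(it, img):
        vvol = np.prod(VOX) / 1000.0
        rmses.append(float(np.sqrt(((img / vvol - truth) ** 2).mean())))

    OSEM(sino, model, ReconConfig(20, 4, voxel_size=VOX),
         img_shape=shape).fit(track_loglik=False, callback=cb)
    diffs = np.diff(rmses)
    assert np.all(diffs <= 1e-9)
    assert rmses[-1] < rmses[0] * 0.5


def test_osem_zero_sinogram_converges_to_zero():
    shape = (12, 12, 1)
    model = _model(shape)
    g = model.geometry
    sino = Sinogram(np.zeros((g.n_angles, g.n_radial, 1)), g, is_noisy=True)
    img = osem_reconstruct(sino, model, ReconConfig(2, 2, voxel_size=VOX),
                           img_shape=shape)
    assert np.all(img.data == 0)


def test_osem_nonnegative_output(small_kernels):
    ct, act = _toy_phantom()
    model = _model(ct.hu.shape)
    sino = simulate_acquisition(act, ct, model, 2000.0, 9,
                                kernels=small_kernels)
    img = osem_reconstruct(sino, model, ReconConfig(2, 4, voxel_size=VOX),
                           img_shape=ct.hu.shape)
    assert np.all(img.data >= 0)


def test_delta_prc_osem_bitwise_equals_plain_osem(small_kernels):
    from gaprc.kernels import AnnihilationEndpoints, build_kernel
    ct, act = _toy_phantom()
    shape = ct.hu.shape
    model = _model(shape)
    sino = simulate_acquisition(act, ct, model, 2000.0, 9,
                                kernels=small_kernels)
    ep = AnnihilationEndpoints(np.zeros((10, 3)), 10, seed=0, material=WATER)
    delta = build_kernel(ep, VOX, 0.5, WATER)
    model_delta = _model(shape, prc=PRCOperator.tissue_independent(delta))
    cfg = ReconConfig(2, 4, voxel_size=VOX)
    a = osem_reconstruct(sino, model, cfg, img_shape=shape)
    b = osem_reconstruct(sino, model_delta, cfg, img_shape=shape)
    np.testing.assert_array_equal(a.data, b.data)


def test_matched_range_model_beats_uncorrected_on_noiseless_data(small_kernels):
    """Data containing positron range: reconstruction with the matching
    range operator reaches lower image RMSE than the uncorrected one."""
    shape = (24, 24, 5)
    vox = small_kernels["water"].voxel_size
    origin = tuple(-(s - 1) / 2 * v for s, v in zip(shape, vox))
    hu = np.full(shape, 0.0)
    act = np.zeros(shape)
    act[8:16, 8:16, 1:4] = 100.0
    act[11:14, 11:14, 2] = 800.0
    ct = CTVolume(hu, vox, origin)
    truth = ActivityVolume(act, vox, origin)
    geom = ScannerGeometry(40, 34, vox[0], shape[2])
    model = SystemModel(geom, vox, mu_map=make_mu_map(ct), psf_fwhm=0.0)
    ybar = expected_sinogram(truth, ct, model, small_kernels, 1e7)
    sino = Sinogram(ybar.counts, geom, is_noisy=True, scale=ybar.scale)
    cfg = ReconConfig(4, 8, voxel_size=vox)
    from gaprc.segmentation import classify_tissue
    op = PRCOperator.tdsv(small_kernels, classify_tissue(ct))
    rec_prc = OSEM(sino, model.with_prc(op), cfg).fit(track_loglik=False).image
    rec_none = OSEM(sino, model, cfg).fit(track_loglik=False).image
    rmse_prc = np.sqrt(((rec_prc.data - act) ** 2).mean())
    rmse_none = np.sqrt(((rec_none.data - act) ** 2).mean())
    assert rmse_prc < rmse_none


def test_osem_results_summary_mentions_configuration(small_kernels):
    ct, act = _toy_phantom()
    model = _model(ct.hu.shape)
    sino = simulate_acquisition(act, ct, model, 2000.0, 9,
                                kernels=small_kernels)
    res = OSEM(sino, model, ReconConfig(2, 2, voxel_size=VOX),
               img_shape=ct.hu.shape).fit()
    text = res.summary()
    assert "2 x 2" in text
    assert "log-likelihood" in text
    assert len(res.loglik) == 2
    # likelihood is non-decreasing for plain (no-PRC) EM on these data
    assert res.loglik[-1] >= res.loglik[0]


def test_recon_config_validation():
    with pytest.raises(ValueError):
        ReconConfig(0, 1)
    with pytest.raises(ValueError):
        ReconConfig(1, 1, prc_backprojection="sideways")
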