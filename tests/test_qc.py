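import numpy as np
import pytest
from scipy import fft as spfft
from scipy import ndimage

from bdtem.qc import (
    displacement_field,
    focus_score,
    ncc,
    radial_power_spectrum,
    ssnr,
)

# --- radial power spectrum --------------------------------------------------


def test_constant_image_zero_power():
    spec = radial_power_spectrum(np.full((64, 64), 3.0), n_bins=16)
    assert np.all(spec.power == 0)


def test_sinusoid_power_concentration():
    n = 128
    f0 = 16 / n  # cycles/pixel, exactly on the grid
    x = np.arange(n)
    img = np.sin(2 * np.pi * f0 * x)[None, :] * np.ones((n, 1))
    spec = radial_power_spectrum(img, n_bins=n // 2, window=None)
    target = np.argmin(np.abs(spec.freq_bins - f0))
    assert spec.power[target] * (spec.freq_bins == spec.freq_bins[target]).sum() > 0
    # >90% of total power lands in the bin containing f0
    counts = _bin_occupancy(img.shape, n // 2)
    totals = spec.power * counts[np.isin(_bin_centers(n // 2), spec.freq_bins)]
    assert totals[target] / totals.sum() > 0.9


def _bin_centers(n_bins):
    return np.arange(1, n_bins + 1) * 0.5 / n_bins


def _bin_occupancy(shape, n_bins):
    fy = spfft.fftfreq(shape[0])
    fx = spfft.fftfreq(shape[1])
    r = np.hypot(fy[:, None], fx[None, :])
    idx = np.round(r / 0.5 * n_bins).astype(int)
    mask = (idx >= 1) & (r <= 0.5)
    counts = np.bincount(idx[mask], minlength=n_bins + 1)[1:]
    return counts[counts > 0]


def test_parseval_bookkeeping(rng):
    # total binned power equals the direct sum of spectral power over
    # the sub-Nyquist region, DC excluded (independent summation oracle)
    img = rng.standard_normal((96, 96))
    n_bins = 48
    spec = radial_power_spectrum(img, n_bins=n_bins, window=None)
    counts = _bin_occupancy(img.shape, n_bins)
    binned_total = float((spec.power * counts).sum())
    centered = img - img.mean()
    p = np.abs(spfft.fft2(centered)) ** 2
    fy = spfft.fftfreq(96)
    fx = spfft.fftfreq(96)
    r = np.hypot(fy[:, None], fx[None, :])
    oracle = float(p[(r > 0) & (r <= 0.5)].sum())
    assert binned_total == pytest.approx(oracle, rel=1e-12)


def test_spectrum_rotation_invariance(rng):
    img = rng.standard_normal((128, 128))
    a = radial_power_spectrum(img, n_bins=32)
    b = radial_power_spectrum(np.rot90(img), n_bins=32)
    np.testing.assert_allclose(a.power, b.power, rtol=1e-9)


def test_spectrum_rejects_small():
    with pytest.raises(ValueError):
        radial_power_spectrum(np.zeros((16, 16)))


# --- ssnr -------------------------------------------------------------------


def test_ssnr_pure_noise_near_zero(rng):
    vals_noise, vals_signal = [], []
    sig = _texture(rng, 256)
    for _ in range(10):
        noise_refs = [rng.standard_normal((256, 256)) for _ in range(2)]
        probe = rng.standard_normal((256, 256))
        vals_noise.append(ssnr(probe, noise_refs).spectral_snr)
        vals_signal.append(ssnr(sig + rng.standard_normal((256, 256)), noise_refs).spectral_snr)
    assert np.mean(vals_noise) < 0.05 * np.mean(vals_signal)


def _texture(rng, n):
    t = ndimage.gaussian_filter(rng.standard_normal((n, n)), 3.0) * 10.0
    return t


def test_ssnr_flat_spectrum_ratio(rng):
    # signal = white noise var a^2 on top of noise var b^2:
    # SNR(f) ~ a^2/b^2 flat across bins (periodogram-ratio expectation)
    a, b = 3.0, 1.5
    n = 512
    img = a * rng.standard_normal((n, n)) + b * rng.standard_normal((n, n))
    noise = [b * rng.standard_normal((n, n)) for _ in range(4)]
    curve = ssnr(img, noise, n_bins=32)
    expected = a * a / (b * b)
    # total variance of img is a^2 + b^2 -> SNR = a^2/b^2 after subtraction
    good = curve.valid & (curve.freq_bins > 0.03)  # lowest bins are sparse
    assert np.all(np.abs(curve.snr[good] - expected) / expected < 0.2)


def test_ssnr_decreases_with_noise(rng):
    n = 256
    sig = _texture(rng, n)
    vals = []
    for scale in (1.0, 2.0):
        snrs = []
        for _ in range(5):
            img = sig + scale * rng.standard_normal((n, n))
            noise = [scale * rng.standard_normal((n, n)) for _ in range(2)]
            snrs.append(ssnr(img, noise).spectral_snr)
        vals.append(np.mean(snrs))
    assert vals[1] < vals[0]


def test_ssnr_gain_invariance(rng):
    img = _texture(rng, 128) + rng.standard_normal((128, 128))
    noise = [rng.standard_normal((128, 128))]
    c1 = ssnr(img, noise)
    c2 = ssnr(img * 7.5, [n * 7.5 for n in noise])
    np.testing.assert_allclose(c1.snr, c2.snr, rtol=1e-9)
    assert c1.spectral_snr == pytest.approx(c2.spectral_snr, rel=1e-9)


def test_ssnr_requires_noise():
    with pytest.raises(ValueError):
        ssnr(np.zeros((64, 64)), [])


def test_ssnr_integral_is_trapezoid(rng):
    img = rng.standard_normal((128, 128))
    noise = [rng.standard_normal((128, 128))]
    c = ssnr(img, noise)
    expected = np.trapezoid(c.snr[c.valid], c.freq_bins[c.valid])
    assert c.spectral_snr == pytest.approx(float(expected))


# --- focus score ------------------------------------------------------------


def test_focus_blur_decreases_score(rng):
    img = rng.standard_normal((256, 256))
    blurred = ndimage.gaussian_filter(img, 2.0)
    assert focus_score(blurred, 0.5) < focus_score(img, 0.5)


def test_focus_constant_zero():
    assert focus_score(np.full((64, 64), 5.0), 0.5) == 0.0


def test_focus_white_noise_annulus_fraction(rng):
    # flat spectrum: score ~ fraction of non-DC samples above the cutoff
    n, cutoff = 256, 0.5
    fy = spfft.fftfreq(n)
    r = np.hypot(fy[:, None], fy[None, :])
    frac = float((r > cutoff * 0.5).sum() / (r > 0).sum())
    scores = [focus_score(rng.standard_normal((n, n)), cutoff, window=None) for _ in range(5)]
    assert np.mean(scores) == pytest.approx(frac, rel=0.02)


def test_focus_cutoff_validation():
    with pytest.raises(ValueError):
        focus_score(np.zeros((64, 64)), 1.5)


# --- ncc --------------------------------------------------------------------


def test_ncc_identity(rng):
    a = rng.standard_normal((32, 32))
    assert ncc(a, a) == pytest.approx(1.0)
    assert ncc(a, -a) == pytest.approx(-1.0)


def test_ncc_constant_invalid():
    assert np.isnan(ncc(np.ones((8, 8)), np.ones((8, 8))))


def test_ncc_matches_bruteforce(rng):
    for _ in range(5):
        a = rng.standard_normal((24, 24))
        b = rng.standard_normal((24, 24))
        am, bm = a.mean(), b.mean()
        num = den_a = den_b = 0.0
        for i in range(24):  # direct double loop oracle
            for j in range(24):
                num += (a[i, j] - am) * (b[i, j] - bm)
                den_a += (a[i, j] - am) ** 2
                den_b += (b[i, j] - bm) ** 2
        oracle = num / np.sqrt(den_a * den_b)
        assert abs(ncc(a, b) - oracle) < 1e-10


# --- displacement field -----------------------------------------------------


def _scene(n, seed=0):
    from bdtem.simulate import make_specimen

    return make_specimen(n, n, seed=seed).raster


def test_displacement_identity():
    ref = _scene(256)
    fld = displacement_field(ref, ref, grid_spacing=64, block_size=32, search_radius=8)
    v = fld.vectors[fld.valid]
    assert len(v) > 0
    assert np.abs(v).max() < 1e-6


def test_displacement_pure_shift():
    ref = _scene(256)
    warped = np.roll(np.roll(ref, -2, axis=0), 3, axis=1)
    fld = displacement_field(ref, warped, grid_spacing=64, block_size=32, search_radius=8)
    v = fld.vectors[fld.valid]
    np.testing.assert_allclose(v, np.broadcast_to((3.0, -2.0), v.shape), atol=0.05)


def _smooth_field(n, max_disp, seed):
    rng = np.random.default_rng(seed)
    c = np.linspace(-1, 1, n)
    x, y = np.meshgrid(c, c)
    ux = rng.normal(size=6) @ np.stack([np.ones_like(x), x, y, x * x, x * y, y * y]).reshape(6, -1)
    uy = rng.normal(size=6) @ np.stack([np.ones_like(x), x, y, y * y, x * y, x * x]).reshape(6, -1)
    ux = ux.reshape(n, n)
    uy = uy.reshape(n, n)
    peak = np.hypot(ux, uy).max()
    return ux / peak * max_disp, uy / peak * max_disp


def _warp(ref, ux, uy):
    n = ref.shape[0]
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    return ndimage.map_coordinates(ref, [yy - uy, xx - ux], order=3, mode="nearest")


def _true_displacement_at(ux, uy, px, py):
    """Solve q - u(q) = p by fixed point: the exact motion of the feature
    at p under warped(q) = ref(q - u(q))."""
    n = ux.shape[0]
    qx, qy = float(px), float(py)
    for _ in range(50):
        dqx = ndimage.map_coordinates(ux, [[qy], [qx]], order=1)[0]
        dqy = ndimage.map_coordinates(uy, [[qy], [qx]], order=1)[0]
        qx_new, qy_new = px + dqx, py + dqy
        if abs(qx_new - qx) < 1e-6 and abs(qy_new - qy) < 1e-6:
            break
        qx, qy = qx_new, qy_new
    return qx - px, qy - py


def test_displacement_recovers_smooth_field():
    n = 512
    ref = _scene(n, seed=4)
    ux, uy = _smooth_field(n, 15.0, seed=8)
    warped = _warp(ref, ux, uy)
    fld = displacement_field(ref, warped, grid_spacing=64, block_size=48, search_radius=20)
    errs = []
    for (px, py), (dx, dy), ok in zip(fld.grid_points, fld.vectors, fld.valid):
        if not ok:
            continue
        tx, ty = _true_displacement_at(ux, uy, px, py)
        errs.append((dx - tx, dy - ty))
    errs = np.asarray(errs)
    assert len(errs) >= 25
    rms = float(np.sqrt((errs**2).sum(axis=1).mean()))
    assert rms < 0.5


def test_displacement_roundtrip_inverse():
    n = 384
    ref = _scene(n, seed=5)
    ux, uy = _smooth_field(n, 8.0, seed=9)
    warped = _warp(ref, ux, uy)
    fwd = displacement_field(ref, warped, grid_spacing=64, block_size=48, search_radius=14)
    bwd = displacement_field(warped, ref, grid_spacing=64, block_size=48, search_radius=14)
    # forward vector at p plus backward vector at p + fwd(p) ~ 0
    sums = []
    for (px, py), (dx, dy), ok in zip(fwd.grid_points, fwd.vectors, fwd.valid):
        if not ok:
            continue
        qx, qy = px + dx, py + dy
        k = np.argmin(np.hypot(bwd.grid_points[:, 0] - qx, bwd.grid_points[:, 1] - qy))
        if not bwd.valid[k]:
            continue
        bx, by = bwd.vectors[k]
        # compare with backward vector nearest the displaced point
        sums.append((dx + bx, dy + by))
    sums = np.asarray(sums)
    assert len(sums) >= 10
    # smooth field: nearest-grid-point mismatch bounded by field gradient
    rms = float(np.sqrt((sums**2).sum(axis=1).mean()))
    assert rms < 0.75 + 8.0 * (64.0 / n)


def test_displacement_border_points_skipped():
    ref = _scene(128)
    fld = displacement_field(ref, ref, grid_spacing=32, block_size=24, search_radius=8)
    assert (~fld.valid).sum() > 0  # border grid points flagged, not errors
    assert np.isnan(fld.vectors[~fld.valid]).all()


def test_displacement_invalid_on_unrelated(rng):
    a = rng.standard_normal((128, 128))
    b = rng.standard_normal((128, 128))
    fld = displacement_field(a, b, grid_spacing=64, block_size=32, search_radius=8)
    assert fld.stats["n_valid"] <= len(fld.grid_points) // 2


def test_displacement_block_size_validation():
    with pytest.raises(ValueError):
        displacement_field(np.zeros((64, 64)), np.zeros((64, 64)), 16, 40, 8)
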