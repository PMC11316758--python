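"""Image-quality metrics: radially averaged power spectra, frequency-
resolved SNR with noise-spectrum subtraction, an FFT focus score, and
NCC block-matching displacement fields.

The spectral pipeline is: subtract the mean, apply a separable Hann
taper (unless disabled), 2-D FFT, squared modulus, then radial binning
of all frequency samples with radial frequency at or below Nyquist
(0.5 cycles/pixel); the DC term is always excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as spfft
from skimage.feature import match_template

__all__ = [
    "RadialSpectrum",
    "SSNRCurve",
    "DisplacementField",
    "radial_power_spectrum",
    "ssnr",
    "focus_score",
    "displacement_field",
    "ncc",
]


@dataclass(frozen=True)
class RadialSpectrum:
    freq_bins: np.ndarray  # bin centers, cycles/pixel in (0, 0.5]
    power: np.ndarray  # mean power per bin
    n_bins: int
    window_id: str

    def __post_init__(self) -> None:
        assert np.all(np.diff(self.freq_bins) > 0)
        assert np.all(self.power >= 0)


@dataclass(frozen=True)
class SSNRCurve:
    freq_bins: np.ndarray
    snr: np.ndarray  # clamped at 0; NaN-free
    valid: np.ndarray  # bins with usable noise power
    spectral_snr: float  # trapezoidal integral over valid bins

    def to_dict(self) -> dict:
        return {
            "freq_bins": self.freq_bins.tolist(),
            "snr": self.snr.tolist(),
            "valid": self.valid.tolist(),
            "spectral_snr": self.spectral_snr,
        }


def _window(shape: tuple, window: str | None) -> np.ndarray | None:
    if window is None or window == "none":
        return None
    if window == "hann":
        wy = np.hanning(shape[0])
        wx = np.hanning(shape[1])
        return np.outer(wy, wx)
    raise ValueError(f"unknown window {window!r}")


def _power2d(raster: np.ndarray, window: str | None) -> np.ndarray:
    img = np.asarray(raster, dtype=float)
    img = img - img.mean()
    w = _window(img.shape, window)
    if w is not None:
        img = img * w
    f = spfft.fft2(img)
    return np.abs(f) ** 2


def _radial_freq(shape: tuple) -> np.ndarray:
    fy = spfft.fftfreq(shape[0])
    fx = spfft.fftfreq(shape[1])
    return np.hypot(fy[:, None], fx[None, :])


def radial_power_spectrum(
    raster: np.ndarray, n_bins: int | None = None, window: str | None = "hann"
) -> RadialSpectrum:
    """Radially averaged 2-D power spectrum.

    Frequency samples with radius in ``(0, 0.5]`` cycles/pixel are
    assigned to ``round(r / 0.5 * n_bins)`` and averaged per bin; DC and
    the corner region beyond Nyquist are excluded.  ``n_bins`` defaults
    to ``min(shape) // 2`` (integer radius steps up to Nyquist).
    """
    raster = np.asarray(raster, dtype=float)
    if raster.ndim != 2 or min(raster.shape) < 32:
        raise ValueError("raster must be 2-D and at least 32x32")
    if n_bins is None:
        n_bins = min(raster.shape) // 2
    window_id = window or "none"
    p = _power2d(raster, window)
    r = _radial_freq(raster.shape)
    idx = np.round(r / 0.5 * n_bins).astype(int)
    mask = (idx >= 1) & (r <= 0.5)
    idx_m = idx[mask]
    sums = np.bincount(idx_m, weights=p[mask], minlength=n_bins + 1)
    counts = np.bincount(idx_m, minlength=n_bins + 1)
    occupied = counts[1:] > 0
    centers = np.arange(1, n_bins + 1)[occupied] * 0.5 / n_bins
    power = sums[1:][occupied] / counts[1:][occupied]
    return RadialSpectrum(
        freq_bins=centers, power=power, n_bins=n_bins, window_id=window_id
    )


def ssnr(
    image: np.ndarray,
    noise_images: list,
    n_bins: int | None = None,
    window: str | None = "hann",
) -> SSNRCurve:
    """Frequency-resolved SNR against a mean noise power spectrum.

    ``SNR(f) = max(0, (P_img(f) - P_noise(f)) / P_noise(f))``; the
    scalar ``spectral_snr`` is the trapezoidal integral of SNR over the
    valid bins.  Bins where the noise power vanishes are flagged invalid
    and excluded from the integral.
    """
    if not noise_images:
        raise ValueError("at least one noise image is required")
    img_spec = radial_power_spectrum(image, n_bins=n_bins, window=window)
    noise_powers = []
    for n_img in noise_images:
        if np.shape(n_img) != np.shape(image):
            raise ValueError("noise image shape mismatch")
        ns = radial_power_spectrum(n_img, n_bins=img_spec.n_bins, window=window)
        noise_powers.append(ns.power)
    p_noise = np.mean(noise_powers, axis=0)
    valid = p_noise > 0
    snr = np.zeros_like(img_spec.power)
    snr[valid] = np.maximum(
        0.0, (img_spec.power[valid] - p_noise[valid]) / p_noise[valid]
    )
    if valid.sum() >= 2:
        integral = float(np.trapezoid(snr[valid], img_spec.freq_bins[valid]))
    else:
        integral = 0.0
    return SSNRCurve(
        freq_bins=img_spec.freq_bins, snr=snr, valid=valid, spectral_snr=integral
    )


def focus_score(
    raster: np.ndarray, cutoff_frac: float = 0.5, window: str | None = "hann"
) -> float:
    """Fraction of DC-excluded spectral power above ``cutoff_frac`` of
    the Nyquist frequency (radially).  Higher is sharper."""
    if not (0.0 < cutoff_frac < 1.0):
        raise ValueError("cutoff_frac must be in (0, 1)")
    p = _power2d(np.asarray(raster, dtype=float), window)
    r = _radial_freq(p.shape)
    nondc = r > 0
    total = p[nondc].sum()
    if total == 0:
        return 0.0
    return float(p[nondc & (r > cutoff_frac * 0.5)].sum() / total)


def ncc(block_a: np.ndarray, block_b: np.ndarray) -> float:
    """Zero-mean, unit-variance normalized cross-correlation of two
    equally shaped blocks; NaN for a constant block."""
    a = np.asarray(block_a, dtype=float).ravel()
    b = np.asarray(block_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("blocks must have equal shapes")
    a = a - a.mean()
    b = b - b.mean()
    na = np.sqrt((a * a).sum())
    nb = np.sqrt((b * b).sum())
    if na == 0 or nb == 0:
        return float("nan")
    return float((a * b).sum() / (na * nb))


@dataclass(frozen=True)
class DisplacementField:
    grid_points: np.ndarray  # (n, 2) array of (x, y) centers
    vectors: np.ndarray  # (n, 2) array of (dx, dy), NaN where invalid
    valid: np.ndarray  # bool per point
    confidence: np.ndarray  # peak NCC per point (NaN where skipped)

    @property
    def stats(self) -> dict:
        v = self.vectors[self.valid]
        if len(v) == 0:
            return {"n_valid": 0, "max": 0.0, "rms": 0.0, "mean": 0.0}
        mags = np.hypot(v[:, 0], v[:, 1])
        return {
            "n_valid": int(len(v)),
            "max": float(mags.max()),
            "rms": float(np.sqrt((mags**2).mean())),
            "mean": float(mags.mean()),
        }

    def to_dict(self) -> dict:
        return {
            "grid_points": self.grid_points.tolist(),
            "vectors": self.vectors.tolist(),
            "valid": self.valid.tolist(),
            "confidence": self.confidence.tolist(),
            "stats": self.stats,
        }


def _subpixel_peak(surface: np.ndarray, py: int, px: int) -> tuple:
    """Quadratic 1-D refinements through the integer peak of an NCC
    surface; falls back to the integer peak at the border.

    A near-perfect peak (NCC ~ 1) means the match is already exact at
    integer precision; refinement would only add asymmetry bias."""
    if surface[py, px] >= 1.0 - 1e-9:
        return 0.0, 0.0

    def refine(vm1: float, v0: float, vp1: float) -> float:
        denom = vm1 - 2.0 * v0 + vp1
        if denom >= 0:  # not a maximum; keep integer peak
            return 0.0
        delta = 0.5 * (vm1 - vp1) / denom
        return float(np.clip(delta, -0.5, 0.5))

    dy = dx = 0.0
    if 0 < py < surface.shape[0] - 1:
        dy = refine(surface[py - 1, px], surface[py, px], surface[py + 1, px])
    if 0 < px < surface.shape[1] - 1:
        dx = refine(surface[py, px - 1], surface[py, px], surface[py, px + 1])
    return dx, dy


def displacement_field(
    reference: np.ndarray,
    warped: np.ndarray,
    grid_spacing: int,
    block_size: int,
    search_radius: int,
    ncc_threshold: float = 0.2,
) -> DisplacementField:
    """Block-matching displacement field on an evenly spaced grid.

    For each grid point, the reference block of ``block_size`` pixels is
    matched by normalized cross-correlation inside a
    ``±search_radius`` window of the warped image; the integer peak is
    refined to subpixel by quadratic fits along each axis.  Vectors are
    reported as warped-position minus reference-position.  Points whose
    blocks leave the image are skipped (invalid, not an error); matches
    with peak NCC below ``ncc_threshold`` are marked invalid.
    """
    ref = np.asarray(reference, dtype=float)
    war = np.asarray(warped, dtype=float)
    if ref.shape != war.shape:
        raise ValueError("reference and warped must have equal shapes")
    if block_size >= 2 * grid_spacing:
        raise ValueError("block_size must be < 2 * grid_spacing")
    h, w = ref.shape
    half = block_size // 2
    ys = np.arange(grid_spacing // 2, h, grid_spacing)
    xs = np.arange(grid_spacing // 2, w, grid_spacing)
    points, vectors, valid, conf = [], [], [], []
    for cy in ys:
        for cx in xs:
            points.append((cx, cy))
            y0, x0 = cy - half, cx - half
            y1, x1 = y0 + block_size, x0 + block_size
            sy0, sx0 = y0 - search_radius, x0 - search_radius
            sy1, sx1 = y1 + search_radius, x1 + search_radius
            if y0 < 0 or x0 < 0 or y1 > h or x1 > w or sy0 < 0 or sx0 < 0 or sy1 > h or sx1 > w:
                vectors.append((np.nan, np.nan))
                valid.append(False)
                conf.append(np.nan)
                continue
            block = ref[y0:y1, x0:x1]
            search = war[sy0:sy1, sx0:sx1]
            if block.std() == 0 or search.std() == 0:
                vectors.append((np.nan, np.nan))
                valid.append(False)
                conf.append(np.nan)
                continue
            surface = match_template(search, block, pad_input=False)
            py, px = np.unravel_index(np.argmax(surface), surface.shape)
            peak = float(surface[py, px])
            sub_dx, sub_dy = _subpixel_peak(surface, py, px)
            dx = px - search_radius + sub_dx
            dy = py - search_radius + sub_dy
            ok = peak >= ncc_threshold
            vectors.append((dx, dy) if ok else (np.nan, np.nan))
            valid.append(ok)
            conf.append(peak)
    return DisplacementField(
        grid_points=np.asarray(points, dtype=float),
        vectors=np.asarray(vectors, dtype=float),
        valid=np.asarray(valid, dtype=bool),
        confidence=np.asarray(conf, dtype=float),
    )
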