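"""Synthetic specimen generation and acquisition simulation.

Produces subtile rasters with a fully known ground truth: nominal and
jittered stage offsets, the exact per-subtile displacement field applied
(a smooth low-order polynomial plus a radial term whose amplitude grows
with deflection radius), dose-scaled shot + read noise, contrast
attenuation with deflection, and a hard circular beam boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import MontagePlan, SupertileSpec, subtile_origin

__all__ = [
    "SceneParams",
    "SyntheticScene",
    "OpticsModel",
    "TileRecord",
    "AcquisitionResult",
    "make_specimen",
    "acquire_subtile",
    "acquire_montage",
    "to_uint16",
]

_N_POLY = 6  # coefficients of a 2nd-order 2-D polynomial per component


def _smooth_noise(shape: tuple, scale_px: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance band-limited noise with correlation length ~scale_px,
    built by cubic-spline upsampling of a coarse white-noise grid (much
    faster than a large-kernel Gaussian filter)."""
    h, w = shape
    scale = max(1.0, float(scale_px))
    coarse = rng.standard_normal(
        (int(np.ceil(h / scale)) + 4, int(np.ceil(w / scale)) + 4)
    )
    fine = ndimage.zoom(coarse, scale, order=3, mode="nearest", grid_mode=True)
    fine = fine[:h, :w]
    sd = fine.std()
    return fine / sd if sd > 0 else fine


@dataclass(frozen=True)
class SceneParams:
    """Texture parameters for the synthetic specimen."""

    feature_density: float = 1.0  # scales membrane + blob counts
    membrane_thickness_range: tuple = (2.0, 6.0)  # px
    blob_radius_range: tuple = (4.0, 30.0)  # px
    background_level: float = 0.75  # bright field background in [0, 1]
    background_smoothness_px: float = 40.0

    def to_dict(self) -> dict:
        return {
            "feature_density": self.feature_density,
            "membrane_thickness_range": list(self.membrane_thickness_range),
            "blob_radius_range": list(self.blob_radius_range),
            "background_level": self.background_level,
            "background_smoothness_px": self.background_smoothness_px,
        }


@dataclass(frozen=True)
class SyntheticScene:
    raster: np.ndarray  # float64 in [0, 1], shape (height, width)
    seed: int
    params: SceneParams

    @property
    def width_px(self) -> int:
        return self.raster.shape[1]

    @property
    def height_px(self) -> int:
        return self.raster.shape[0]


def make_specimen(
    width_px: int,
    height_px: int,
    seed: int = 0,
    params: SceneParams | None = None,
) -> SyntheticScene:
    """Generate a reproducible textured specimen image.

    The texture combines a smooth band-limited background, dark
    curvilinear ridges (membrane proxies, traced along iso-contours of a
    smooth random field), and dark disk blobs with soft edges
    (vesicle / mitochondrion proxies).  Deterministic given
    ``(seed, params, size)``.
    """
    if width_px < 1 or height_px < 1:
        raise ValueError("scene dimensions must be positive")
    params = params or SceneParams()
    rng = np.random.default_rng(np.random.SeedSequence([seed, width_px, height_px]))

    # band-limited background around the nominal brightness
    bg = _smooth_noise((height_px, width_px), params.background_smoothness_px, rng)
    img = params.background_level + 0.03 * bg

    if params.feature_density > 0:
        # membranes: darken near iso-levels of a second smooth field;
        # several levels give a tangle of closed curvilinear ridges
        fld = _smooth_noise((height_px, width_px), 25.0, rng)
        n_levels = max(1, round(4 * params.feature_density))
        lo, hi = params.membrane_thickness_range
        # |grad| converts field distance to pixel distance
        gy, gx = np.gradient(fld)
        gmag = np.hypot(gx, gy) + 1e-9
        for level in rng.uniform(-1.2, 1.2, size=n_levels):
            half_w = rng.uniform(lo, hi) / 2.0
            dist_px = np.abs(fld - level) / gmag
            img -= 0.45 * np.exp(-0.5 * (dist_px / half_w) ** 2)

        # blobs: each darkens only a local patch (3 sigma support)
        n_blobs = round(
            params.feature_density * width_px * height_px / 20000.0
        )
        r_lo, r_hi = params.blob_radius_range
        for _ in range(n_blobs):
            cx = rng.uniform(0, width_px)
            cy = rng.uniform(0, height_px)
            r = rng.uniform(r_lo, r_hi)
            depth = rng.uniform(0.15, 0.5)
            sigma = 0.5 * r
            ext = int(np.ceil(3 * sigma)) + 1
            x0, x1 = max(0, int(cx) - ext), min(width_px, int(cx) + ext + 1)
            y0, y1 = max(0, int(cy) - ext), min(height_px, int(cy) + ext + 1)
            yy, xx = np.mgrid[y0:y1, x0:x1]
            d2 = (xx - cx) ** 2 + (yy - cy) ** 2
            img[y0:y1, x0:x1] -= depth * np.exp(-0.5 * d2 / sigma**2)

    np.clip(img, 0.0, 1.0, out=img)
    return SyntheticScene(raster=img, seed=seed, params=params)


@dataclass(frozen=True)
class OpticsModel:
    """Deflection-dependent image degradation model.

    ``distortion_scale`` is the maximum displacement in pixels applied
    to a subtile at unit (Euclidean) deflection radius; ``snr_falloff``
    attenuates contrast by ``(1 - snr_falloff) ** radius``;
    ``dose_per_ms`` sets the expected counts per pixel per millisecond
    at unit intensity (``0`` disables noise entirely — identity optics);
    ``read_noise_sd`` is additive Gaussian noise in intensity units.
    ``boundary_radius_px`` is the hard circular beam boundary measured
    from the optic axis; tiles are masked to ``background_level``
    outside it.  ``jitter_sd_px`` adds integer stage jitter per
    supertile.
    """

    boundary_radius_px: float = float("inf")
    distortion_scale: float = 0.0
    snr_falloff: float = 0.0
    dose_per_ms: float = 0.0
    read_noise_sd: float = 0.0
    jitter_sd_px: float = 0.0
    background_level: float = 0.75

    def to_dict(self) -> dict:
        return {
            "boundary_radius_px": self.boundary_radius_px,
            "distortion_scale": self.distortion_scale,
            "snr_falloff": self.snr_falloff,
            "dose_per_ms": self.dose_per_ms,
            "read_noise_sd": self.read_noise_sd,
            "jitter_sd_px": self.jitter_sd_px,
            "background_level": self.background_level,
        }

    @staticmethod
    def from_dict(d: dict) -> "OpticsModel":
        return OpticsModel(**d)


def to_uint16(intensity: np.ndarray) -> np.ndarray:
    """Deterministic [0, 1] float -> 16-bit conversion used everywhere."""
    return np.round(np.clip(intensity, 0.0, 1.0) * 65535.0).astype(np.uint16)


def _polynomial_displacement(
    tile_px: int, coeffs: np.ndarray, amplitude: float
) -> tuple:
    """Evaluate a 2nd-order polynomial + radial displacement field on the
    tile, normalized so its maximum magnitude equals ``amplitude``.

    ``coeffs`` has shape (2, _N_POLY + 1): per component, six polynomial
    coefficients (1, x, y, x^2, x*y, y^2) and one barrel term weight.
    Coordinates are normalized to [-1, 1] across the tile.
    """
    c = np.linspace(-1.0, 1.0, tile_px)
    x, y = np.meshgrid(c, c)
    basis = np.stack([np.ones_like(x), x, y, x * x, x * y, y * y])
    r2 = x * x + y * y
    fields = []
    for comp, axis in zip(coeffs, (x, y)):
        f = np.tensordot(comp[:_N_POLY], basis, axes=1) + comp[_N_POLY] * r2 * axis
        fields.append(f)
    dx, dy = fields
    mag = np.hypot(dx, dy)
    peak = mag.max()
    if peak > 0 and amplitude > 0:
        dx = dx / peak * amplitude
        dy = dy / peak * amplitude
    else:
        dx = np.zeros_like(dx)
        dy = np.zeros_like(dy)
    return dx, dy


@dataclass
class TileRecord:
    """Ground truth for one acquired subtile."""

    supertile_row: int
    supertile_col: int
    subtile_index: tuple  # (i, j) signed deflection offsets
    nominal_origin_xy: tuple  # planned top-left (x, y) in scene pixels
    true_origin_xy: tuple  # nominal + stage jitter
    deflection_radius: float
    distortion_coeffs: list  # [] when no distortion applied
    distortion_amplitude_px: float
    contrast_scale: float
    noise_seed: list  # SeedSequence entropy words; [] for identity optics
    mean_counts: float  # pre-rescale expected-count sample mean (0 = noise-free)
    boundary_clipped: bool

    def to_dict(self) -> dict:
        return {
            "supertile_row": self.supertile_row,
            "supertile_col": self.supertile_col,
            "subtile_index": list(self.subtile_index),
            "nominal_origin_xy": list(self.nominal_origin_xy),
            "true_origin_xy": list(self.true_origin_xy),
            "deflection_radius": self.deflection_radius,
            "distortion_coeffs": self.distortion_coeffs,
            "distortion_amplitude_px": self.distortion_amplitude_px,
            "contrast_scale": self.contrast_scale,
            "noise_seed": self.noise_seed,
            "mean_counts": self.mean_counts,
            "boundary_clipped": self.boundary_clipped,
        }


@dataclass
class AcquisitionResult:
    plan: MontagePlan
    optics: OpticsModel
    seed: int
    tiles: dict = field(default_factory=dict)  # (st_row, st_col, i, j) -> uint16
    records: list = field(default_factory=list)

    def record_for(self, st_row: int, st_col: int, i: int, j: int) -> TileRecord:
        for rec in self.records:
            if (
                rec.supertile_row == st_row
                and rec.supertile_col == st_col
                and rec.subtile_index == (i, j)
            ):
                return rec
        raise KeyError((st_row, st_col, i, j))

    def manifest(self) -> dict:
        return {
            "plan": self.plan.to_dict(),
            "optics": self.optics.to_dict(),
            "seed": self.seed,
            "tiles": [rec.to_dict() for rec in self.records],
        }


def acquire_subtile(
    scene: SyntheticScene,
    stage_origin_px: tuple,
    subtile_index: tuple,
    spec: SupertileSpec,
    optics: OpticsModel,
    exposure_s: float,
    seed,
) -> tuple:
    """Simulate acquisition of one subtile.

    Extracts the tile window at its nominal offset, warps it by a smooth
    per-subtile displacement field (amplitude ``distortion_scale`` times
    the Euclidean deflection radius), attenuates contrast by
    ``(1 - snr_falloff) ** radius``, converts intensity to expected
    counts ``dose_per_ms * exposure_ms * intensity``, samples Poisson
    shot noise plus Gaussian read noise, rescales to 16 bits, and masks
    pixels outside the circular beam boundary to the background level.

    Returns ``(tile_uint16, TileRecord)``.  ``seed`` may be an int or a
    ``numpy.random.SeedSequence``.
    """
    i, j = subtile_index
    x0, y0 = (int(stage_origin_px[0]), int(stage_origin_px[1]))
    t = spec.tile_px
    if x0 < 0 or y0 < 0 or x0 + t > scene.width_px or y0 + t > scene.height_px:
        raise IndexError(
            f"tile window ({x0},{y0})+{t} outside scene "
            f"{scene.width_px}x{scene.height_px}"
        )
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    radius = float(np.hypot(i, j))

    amplitude = optics.distortion_scale * radius
    if amplitude > 0:
        coeffs = rng.standard_normal((2, _N_POLY + 1))
        dx, dy = _polynomial_displacement(t, coeffs, amplitude)
        yy, xx = np.mgrid[0:t, 0:t].astype(float)
        # sample the scene at the displaced source coordinates
        img = ndimage.map_coordinates(
            scene.raster,
            [np.clip(yy + y0 + dy, 0, scene.height_px - 1),
             np.clip(xx + x0 + dx, 0, scene.width_px - 1)],
            order=1,
            mode="nearest",
        )
        coeff_list = coeffs.tolist()
    else:
        img = scene.raster[y0 : y0 + t, x0 : x0 + t].copy()
        coeff_list = []

    contrast = (1.0 - optics.snr_falloff) ** radius
    if contrast != 1.0:
        m = img.mean()
        img = m + (img - m) * contrast

    mean_counts = 0.0
    if optics.dose_per_ms > 0:
        dose = optics.dose_per_ms * exposure_s * 1e3
        lam = np.clip(img, 0.0, None) * dose
        counts = rng.poisson(lam).astype(float)
        if optics.read_noise_sd > 0:
            counts += rng.normal(0.0, optics.read_noise_sd * dose, size=counts.shape)
        mean_counts = float(counts.mean())
        img = counts / dose

    clipped = False
    if np.isfinite(optics.boundary_radius_px):
        # pixel coordinates relative to the optic axis: the center tile
        # spans [-t/2, t/2] and deflection moves the window by pitch steps
        cx = i * spec.pitch_px - t / 2.0
        cy = j * spec.pitch_px - t / 2.0
        yy, xx = np.mgrid[0:t, 0:t]
        r2 = (xx + 0.5 + cx) ** 2 + (yy + 0.5 + cy) ** 2
        outside = r2 > optics.boundary_radius_px**2
        if outside.any():
            clipped = True
            img = np.where(outside, optics.background_level, img)

    record = TileRecord(
        supertile_row=-1,
        supertile_col=-1,
        subtile_index=(i, j),
        nominal_origin_xy=(x0, y0),
        true_origin_xy=(x0, y0),
        deflection_radius=radius,
        distortion_coeffs=coeff_list,
        distortion_amplitude_px=amplitude,
        contrast_scale=contrast,
        noise_seed=list(ss.entropy) if isinstance(ss.entropy, (list, tuple)) else [int(ss.entropy)],
        mean_counts=mean_counts,
        boundary_clipped=clipped,
    )
    return to_uint16(img), record


def acquire_montage(
    plan: MontagePlan,
    scene: SyntheticScene,
    optics: OpticsModel,
    exposure_s: float = 0.120,
    seed: int = 0,
    margin_px: int = 0,
) -> AcquisitionResult:
    """Acquire every tile of a plan against a synthetic scene.

    Supertiles are visited in serpentine order over the stage grid and
    subtiles in spiral order within each supertile.  Each tile's RNG is
    seeded from ``(seed, supertile flat index, subtile position)`` so any
    tile is reproducible in isolation.  ``margin_px`` shifts the plan
    origin into the scene so stage jitter never runs off the edge; all
    recorded origins are in scene coordinates.
    """
    if (
        scene.width_px < plan.montage_extent_cols_px + 2 * margin_px
        or scene.height_px < plan.montage_extent_rows_px + 2 * margin_px
    ):
        raise IndexError(
            "scene too small: montage needs "
            f"{plan.montage_extent_cols_px + 2 * margin_px}x"
            f"{plan.montage_extent_rows_px + 2 * margin_px} px, "
            f"scene is {scene.width_px}x{scene.height_px}"
        )
    result = AcquisitionResult(plan=plan, optics=optics, seed=seed)
    order = list(plan.subtile_order)
    for st_flat, (r, c, x, y) in enumerate(_serpentine(plan)):
        jitter_rng = np.random.default_rng(np.random.SeedSequence([seed, 7919, st_flat]))
        if optics.jitter_sd_px > 0:
            jx, jy = np.round(
                jitter_rng.normal(0.0, optics.jitter_sd_px, size=2)
            ).astype(int)
        else:
            jx = jy = 0
        for t_idx, (i, j) in enumerate(order):
            nx, ny = subtile_origin((x + margin_px, y + margin_px), (i, j), plan.spec)
            tx, ty = nx + jx, ny + jy
            tx = int(np.clip(tx, 0, scene.width_px - plan.spec.tile_px))
            ty = int(np.clip(ty, 0, scene.height_px - plan.spec.tile_px))
            ss = np.random.SeedSequence([seed, st_flat, t_idx])
            tile, rec = acquire_subtile(
                scene, (tx, ty), (i, j), plan.spec, optics, exposure_s, ss
            )
            rec.supertile_row = r
            rec.supertile_col = c
            rec.nominal_origin_xy = (nx, ny)
            rec.true_origin_xy = (tx, ty)
            rec.noise_seed = [seed, st_flat, t_idx]
            result.tiles[(r, c, i, j)] = tile
            result.records.append(rec)
    return result


def _serpentine(plan: MontagePlan):
    """Stage positions in serpentine (boustrophedon) row order."""
    grid = {}
    for r, c, x, y in plan.stage_positions:
        grid[(r, c)] = (x, y)
    for r in range(plan.n_rows):
        cols = range(plan.n_cols) if r % 2 == 0 else range(plan.n_cols - 1, -1, -1)
        for c in cols:
            x, y = grid[(r, c)]
            yield r, c, x, y
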