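"""Supertile and montage tiling arithmetic.

A *supertile* is a grid of camera subtiles acquired at a single stage
position by deflecting the beam; neighboring subtiles overlap by a fixed
fraction of the tile side.  A *montage* covers a rectangular section ROI
with a regular grid of supertiles that themselves overlap by a fixed
pixel count.

Coordinate conventions
----------------------
All raster coordinates are 0-based with the origin at the ROI top-left;
``x`` indexes columns, ``y`` indexes rows, and a tile of width ``w``
placed at ``x`` occupies the half-open interval ``[x, x + w)``.

Deflection (subtile) indices ``(i, j)`` are signed offsets from the
undeflected, on-axis center subtile: ``i`` steps along ``x`` (columns),
``j`` along ``y`` (rows).  Physical deflection offsets are the index
times the subtile pitch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "SupertileSpec",
    "MontagePlan",
    "DeflectionPattern",
    "make_supertile_spec",
    "spiral_order",
    "plan_montage",
    "montage_unique_pixels",
    "max_full_tiles_rect",
    "max_full_tiles_cruciform",
    "subtile_origin",
]


class ParameterError(ValueError):
    """Raised when a plan or spec parameter is out of its valid domain."""


@dataclass(frozen=True)
class SupertileSpec:
    """Geometry of one supertile: a ``grid_rows x grid_cols`` grid of
    square subtiles of side ``tile_px`` overlapping by
    ``intra_overlap_px`` pixels."""

    tile_px: int
    grid_rows: int
    grid_cols: int
    intra_overlap_frac: float
    intra_overlap_px: int
    pitch_px: int
    extent_rows_px: int
    extent_cols_px: int

    @property
    def tiles_per_supertile(self) -> int:
        return self.grid_rows * self.grid_cols

    def to_dict(self) -> dict:
        return {
            "tile_px": self.tile_px,
            "grid_rows": self.grid_rows,
            "grid_cols": self.grid_cols,
            "intra_overlap_frac": self.intra_overlap_frac,
            "intra_overlap_px": self.intra_overlap_px,
            "pitch_px": self.pitch_px,
            "extent_rows_px": self.extent_rows_px,
            "extent_cols_px": self.extent_cols_px,
        }

    @staticmethod
    def from_dict(d: dict) -> "SupertileSpec":
        return make_supertile_spec(
            d["tile_px"], d["grid_rows"], d["grid_cols"], d["intra_overlap_frac"]
        )


def make_supertile_spec(
    tile_px: int, grid_rows: int, grid_cols: int, intra_overlap_frac: float
) -> SupertileSpec:
    """Build a :class:`SupertileSpec`, deriving overlap pixels, pitch and
    stitched extents.

    ``intra_overlap_px = round(intra_overlap_frac * tile_px)`` and the
    stitched extent per axis is ``n * tile_px - (n - 1) * overlap``.
    """
    if tile_px < 1 or grid_rows < 1 or grid_cols < 1:
        raise ParameterError("tile_px and grid dimensions must be >= 1")
    if not (0.0 <= intra_overlap_frac < 1.0):
        raise ParameterError("intra_overlap_frac must be in [0, 1)")
    overlap = round(intra_overlap_frac * tile_px)
    if not (0 <= overlap < tile_px):
        raise ParameterError("derived overlap out of range")
    pitch = tile_px - overlap
    ext_r = (grid_rows - 1) * pitch + tile_px
    ext_c = (grid_cols - 1) * pitch + tile_px
    return SupertileSpec(
        tile_px=tile_px,
        grid_rows=grid_rows,
        grid_cols=grid_cols,
        intra_overlap_frac=intra_overlap_frac,
        intra_overlap_px=overlap,
        pitch_px=pitch,
        extent_rows_px=ext_r,
        extent_cols_px=ext_c,
    )


@dataclass(frozen=True)
class DeflectionPattern:
    """Acquisition order of subtile indices, on-axis center first, then
    outward ring by ring (Chebyshev radius)."""

    indices: tuple  # tuple of (i, j) signed grid offsets, (0, 0) first
    pitch_px: int

    @property
    def offsets_px(self) -> tuple:
        """(dx, dy) deflection offsets in pixels, same order as indices."""
        return tuple((i * self.pitch_px, j * self.pitch_px) for i, j in self.indices)

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self):
        return iter(self.indices)


def spiral_order(grid_rows: int, grid_cols: int, pitch_px: int = 1) -> DeflectionPattern:
    """Spiral acquisition order over a ``grid_rows x grid_cols`` subtile grid.

    Starts at the on-axis tile ``(0, 0)`` and proceeds outward ring by
    ring; within each Chebyshev ring the order starts at ``(+1, 0)``
    (one pitch east of center) and proceeds counter-clockwise in the
    ``(i=x, j=y)`` plane.  The chirality is fixed by convention.

    For even grid dimensions the center is the tile whose absolute index
    floor-divides the grid, so signed offsets along an even axis of size
    ``n`` run from ``-(n // 2)`` to ``n - 1 - n // 2``.
    """
    if grid_rows < 1 or grid_cols < 1:
        raise ParameterError("grid dimensions must be >= 1")
    j_lo, j_hi = -(grid_rows // 2), grid_rows - 1 - grid_rows // 2
    i_lo, i_hi = -(grid_cols // 2), grid_cols - 1 - grid_cols // 2
    max_ring = max(abs(j_lo), abs(j_hi), abs(i_lo), abs(i_hi))

    def in_grid(i: int, j: int) -> bool:
        return i_lo <= i <= i_hi and j_lo <= j <= j_hi

    order = [(0, 0)]
    for r in range(1, max_ring + 1):
        ring = [
            (i, j)
            for i in range(-r, r + 1)
            for j in range(-r, r + 1)
            if max(abs(i), abs(j)) == r
        ]
        # CCW starting from angle 0 (east of center)
        ring.sort(key=lambda ij: math.atan2(ij[1], ij[0]) % (2 * math.pi))
        order.extend(ij for ij in ring if in_grid(*ij))
    return DeflectionPattern(indices=tuple(order), pitch_px=pitch_px)


@dataclass(frozen=True)
class MontagePlan:
    """Full acquisition plan for one section ROI."""

    pixel_size_nm: float
    section_width_px: int
    section_height_px: int
    spec: SupertileSpec
    inter_overlap_px: int
    step_row_px: int
    step_col_px: int
    n_rows: int
    n_cols: int
    stage_positions: tuple = field(repr=False)  # (row, col, x_px, y_px)
    subtile_order: DeflectionPattern = field(repr=False)
    montage_extent_rows_px: int = 0
    montage_extent_cols_px: int = 0

    @property
    def n_supertiles(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def n_tiles(self) -> int:
        return self.n_supertiles * self.spec.tiles_per_supertile

    @property
    def total_pixels(self) -> int:
        """All acquired pixels, overlaps counted every time."""
        return self.n_tiles * self.spec.tile_px**2

    def to_dict(self) -> dict:
        nm = self.pixel_size_nm
        return {
            "pixel_size_nm": nm,
            "section_px": [self.section_width_px, self.section_height_px],
            "spec": self.spec.to_dict(),
            "inter_overlap_px": self.inter_overlap_px,
            "step_px": [self.step_col_px, self.step_row_px],
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "stage_positions": [
                {
                    "row": r,
                    "col": c,
                    "x_px": x,
                    "y_px": y,
                    "x_nm": x * nm,
                    "y_nm": y * nm,
                }
                for (r, c, x, y) in self.stage_positions
            ],
            "subtile_order": [list(ij) for ij in self.subtile_order],
            "montage_extent_px": [
                self.montage_extent_cols_px,
                self.montage_extent_rows_px,
            ],
        }

    @staticmethod
    def from_dict(d: dict) -> "MontagePlan":
        spec = SupertileSpec.from_dict(d["spec"])
        w_px, h_px = d["section_px"]
        nm = d["pixel_size_nm"]
        return plan_montage(
            w_px * nm, h_px * nm, nm, spec, d["inter_overlap_px"]
        )


def plan_montage(
    section_width_nm: float,
    section_height_nm: float,
    pixel_size_nm: float,
    spec: SupertileSpec,
    inter_overlap_px: int,
) -> MontagePlan:
    """Lay out a regular supertile grid covering a section ROI.

    The section pixel extent is ``ceil(size_nm / pixel_size_nm)`` and the
    supertile count per axis is ``max(1, ceil((section - extent) / step) + 1)``
    with ``step = extent - inter_overlap_px``, so the montage always
    covers (and may overshoot) the ROI.
    """
    if section_width_nm <= 0 or section_height_nm <= 0 or pixel_size_nm <= 0:
        raise ParameterError("section size and pixel size must be positive")
    step_r = spec.extent_rows_px - inter_overlap_px
    step_c = spec.extent_cols_px - inter_overlap_px
    if step_r <= 0 or step_c <= 0:
        raise ParameterError(
            "inter_overlap_px must be smaller than the supertile extent"
        )
    w_px = math.ceil(section_width_nm / pixel_size_nm)
    h_px = math.ceil(section_height_nm / pixel_size_nm)
    n_cols = max(1, math.ceil((w_px - spec.extent_cols_px) / step_c) + 1)
    n_rows = max(1, math.ceil((h_px - spec.extent_rows_px) / step_r) + 1)
    positions = tuple(
        (r, c, c * step_c, r * step_r) for r in range(n_rows) for c in range(n_cols)
    )
    return MontagePlan(
        pixel_size_nm=pixel_size_nm,
        section_width_px=w_px,
        section_height_px=h_px,
        spec=spec,
        inter_overlap_px=inter_overlap_px,
        step_row_px=step_r,
        step_col_px=step_c,
        n_rows=n_rows,
        n_cols=n_cols,
        stage_positions=positions,
        subtile_order=spiral_order(spec.grid_rows, spec.grid_cols, spec.pitch_px),
        montage_extent_rows_px=(n_rows - 1) * step_r + spec.extent_rows_px,
        montage_extent_cols_px=(n_cols - 1) * step_c + spec.extent_cols_px,
    )


def montage_unique_pixels(plan: MontagePlan) -> int:
    """Number of distinct pixels in the stitched montage (overlap pixels
    counted once): the product of the montage extents."""
    return plan.montage_extent_rows_px * plan.montage_extent_cols_px


def subtile_origin(
    stage_origin_xy: tuple, subtile_index: tuple, spec: SupertileSpec
) -> tuple:
    """Nominal top-left ``(x, y)`` of subtile ``(i, j)`` for a supertile
    whose stitched footprint has top-left ``stage_origin_xy``."""
    i, j = subtile_index
    x0, y0 = stage_origin_xy
    return (
        x0 + (i + spec.grid_cols // 2) * spec.pitch_px,
        y0 + (j + spec.grid_rows // 2) * spec.pitch_px,
    )


# --- beam-boundary capacity -------------------------------------------------


def _tile_fits(i: int, j: int, radius: float, tile_px: float, pitch_px: float) -> bool:
    """A tile at grid index (i, j) fits iff all four of its corners lie
    inside (or on) the circle of given radius centered on the axis; the
    grid is anchored with tile (0, 0) centered on the axis."""
    half = tile_px / 2.0
    # farthest corner of the tile from the origin
    cx, cy = abs(i) * pitch_px + half, abs(j) * pitch_px + half
    return cx * cx + cy * cy <= radius * radius + 1e-9


def _fit_bound(radius: float, pitch_px: float) -> int:
    return int(radius // pitch_px) + 1


def max_full_tiles_rect(
    boundary_radius_px: float, tile_px: int, pitch_px: int, max_index: int | None = None
) -> tuple:
    """Largest contiguous axis-aligned rectangle of full tiles fitting
    inside the circular beam boundary.

    Returns ``(rows, cols, count)``; ties are broken toward the squarer
    rectangle (smaller ``|rows - cols|``), then toward more rows.
    A radius too small for even the center tile yields ``(0, 0, 0)``.
    ``max_index`` optionally bounds candidate grid indices to
    ``|i|, |j| <= max_index`` (needed for very large radii).
    """
    if boundary_radius_px <= 0:
        raise ParameterError("boundary radius must be positive")
    if not _tile_fits(0, 0, boundary_radius_px, tile_px, pitch_px):
        return (0, 0, 0)
    b = _fit_bound(boundary_radius_px, pitch_px)
    if max_index is not None:
        b = min(b, max_index)
    fits = {
        (i, j)
        for i in range(-b, b + 1)
        for j in range(-b, b + 1)
        if _tile_fits(i, j, boundary_radius_px, tile_px, pitch_px)
    }
    best = (0, 0, 0)
    best_key = None
    for i0 in range(-b, b + 1):
        for i1 in range(i0, b + 1):
            for j0 in range(-b, b + 1):
                for j1 in range(j0, b + 1):
                    # corner tiles dominate: the fitting set is symmetric
                    # and monotone toward the axis
                    corners = [(i0, j0), (i0, j1), (i1, j0), (i1, j1)]
                    if not all(c in fits for c in corners):
                        continue
                    rows, cols = j1 - j0 + 1, i1 - i0 + 1
                    count = rows * cols
                    key = (count, -abs(rows - cols), rows)
                    if best_key is None or key > best_key:
                        best_key = key
                        best = (rows, cols, count)
    return best


def max_full_tiles_cruciform(
    boundary_radius_px: float, tile_px: int, pitch_px: int, max_index: int | None = None
) -> tuple:
    """All grid tiles whose four corners fit inside the circular beam
    boundary — the convex-by-row "cruciform" packing.

    Returns ``(count, positions)`` with positions sorted row-major.
    ``max_index`` bounds the candidate grid as in
    :func:`max_full_tiles_rect`.
    """
    if boundary_radius_px <= 0:
        raise ParameterError("boundary radius must be positive")
    if not _tile_fits(0, 0, boundary_radius_px, tile_px, pitch_px):
        return (0, ())
    b = _fit_bound(boundary_radius_px, pitch_px)
    if max_index is not None:
        b = min(b, max_index)
    positions = tuple(
        sorted(
            (i, j)
            for j in range(-b, b + 1)
            for i in range(-b, b + 1)
            if _tile_fits(i, j, boundary_radius_px, tile_px, pitch_px)
        )
    )
    return (len(positions), positions)
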