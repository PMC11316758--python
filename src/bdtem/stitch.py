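"""Translation-only registration and compositing of overlapping tiles.

Pairwise offsets are measured by normalized cross-correlation in the
nominal overlap region, global positions solved by confidence-weighted
linear least squares with one anchored tile, and the mosaic rendered
with linear feather blending.  Elastic / nonlinear alignment is out of
scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import match_template

from .qc import _subpixel_peak

__all__ = ["PairOffset", "TilePositionSolution", "pair_offset", "solve_positions", "composite"]


@dataclass(frozen=True)
class PairOffset:
    tile_a: object
    tile_b: object
    nominal_offset: tuple  # (dx, dy): nominal top-left of b minus a
    measured_offset: tuple  # subpixel (dx, dy)
    confidence: float  # peak NCC; NaN when match not attempted
    valid: bool

    def to_dict(self) -> dict:
        return {
            "tile_a": list(self.tile_a) if isinstance(self.tile_a, tuple) else self.tile_a,
            "tile_b": list(self.tile_b) if isinstance(self.tile_b, tuple) else self.tile_b,
            "nominal_offset": list(self.nominal_offset),
            "measured_offset": list(self.measured_offset),
            "confidence": self.confidence,
            "valid": self.valid,
        }


def pair_offset(
    tile_a: np.ndarray,
    tile_b: np.ndarray,
    nominal_offset: tuple,
    search_radius: int = 16,
    ids: tuple = ("a", "b"),
    min_overlap_px: int = 64,
) -> PairOffset:
    """Measure the translation of ``tile_b`` relative to ``tile_a``.

    A template from the interior of the nominal overlap of ``tile_b`` is
    matched by NCC within ``±search_radius`` in ``tile_a`` and the peak
    refined to subpixel.  Too-small or constant overlap yields a
    low-confidence, invalid result at the nominal offset rather than an
    error.
    """
    a = np.asarray(tile_a, dtype=float)
    b = np.asarray(tile_b, dtype=float)
    dx, dy = int(round(nominal_offset[0])), int(round(nominal_offset[1]))
    ha, wa = a.shape
    hb, wb = b.shape
    # overlap rectangle in a's coordinates
    ox0, oy0 = max(0, dx), max(0, dy)
    ox1, oy1 = min(wa, dx + wb), min(ha, dy + hb)
    fallback = PairOffset(
        tile_a=ids[0],
        tile_b=ids[1],
        nominal_offset=(float(nominal_offset[0]), float(nominal_offset[1])),
        measured_offset=(float(nominal_offset[0]), float(nominal_offset[1])),
        confidence=float("nan"),
        valid=False,
    )
    if min(ox1 - ox0, oy1 - oy0) < max(min_overlap_px, 2 * search_radius + 8):
        return fallback
    # template: overlap interior shrunk by the search radius
    tx0, ty0 = ox0 + search_radius, oy0 + search_radius
    tx1, ty1 = ox1 - search_radius, oy1 - search_radius
    template = b[ty0 - dy : ty1 - dy, tx0 - dx : tx1 - dx]
    search = a[oy0:oy1, ox0:ox1]
    if template.size == 0 or template.std() == 0 or search.std() == 0:
        return fallback
    surface = match_template(search, template, pad_input=False)
    py, px = np.unravel_index(np.argmax(surface), surface.shape)
    peak = float(surface[py, px])
    sub_dx, sub_dy = _subpixel_peak(surface, py, px)
    measured = (
        nominal_offset[0] - search_radius + px + sub_dx,
        nominal_offset[1] - search_radius + py + sub_dy,
    )
    return PairOffset(
        tile_a=ids[0],
        tile_b=ids[1],
        nominal_offset=(float(nominal_offset[0]), float(nominal_offset[1])),
        measured_offset=(float(measured[0]), float(measured[1])),
        confidence=peak,
        valid=peak >= 0.2,
    )


@dataclass(frozen=True)
class TilePositionSolution:
    positions: dict  # tile id -> (x, y) subpixel
    anchor: object
    residuals: dict  # (tile_a, tile_b) -> (rx, ry)

    @property
    def mean_residual(self) -> float:
        if not self.residuals:
            return 0.0
        r = np.asarray(list(self.residuals.values()), dtype=float)
        return float(np.hypot(r[:, 0], r[:, 1]).mean())

    def to_dict(self) -> dict:
        return {
            "positions": {str(k): list(v) for k, v in self.positions.items()},
            "anchor": str(self.anchor),
            "residuals": {str(k): list(v) for k, v in self.residuals.items()},
            "mean_residual": self.mean_residual,
        }


def solve_positions(
    pair_offsets: list,
    anchor: object,
    anchor_position: tuple = (0.0, 0.0),
) -> TilePositionSolution:
    """Confidence-weighted least-squares tile positions from pairwise
    offsets, with the anchor tile fixed at ``anchor_position``.

    Minimizes ``sum_w ||(p_b - p_a) - measured||^2``.  Raises
    ``ValueError`` naming the connected components if the pair graph is
    disconnected.
    """
    tiles = sorted({p.tile_a for p in pair_offsets} | {p.tile_b for p in pair_offsets})
    if anchor not in tiles:
        tiles = [anchor] + tiles
    # connectivity check (union-find)
    parent = {t: t for t in tiles}

    def find(t):
        while parent[t] != t:
            parent[t] = parent[parent[t]]
            t = parent[t]
        return t

    for p in pair_offsets:
        ra, rb = find(p.tile_a), find(p.tile_b)
        if ra != rb:
            parent[ra] = rb
    components = {}
    for t in tiles:
        components.setdefault(find(t), []).append(t)
    if len(components) > 1:
        raise ValueError(
            "pair graph is disconnected; components: "
            + "; ".join(str(sorted(map(str, c))) for c in components.values())
        )

    index = {t: k for k, t in enumerate(tiles)}
    n = len(tiles)
    rows = len(pair_offsets) + 1
    a_mat = np.zeros((rows, n))
    bx = np.zeros(rows)
    by = np.zeros(rows)
    w_anchor = 1e6
    a_mat[0, index[anchor]] = w_anchor
    bx[0] = w_anchor * anchor_position[0]
    by[0] = w_anchor * anchor_position[1]
    for k, p in enumerate(pair_offsets, start=1):
        w = p.confidence if np.isfinite(p.confidence) and p.confidence > 0 else 1e-3
        a_mat[k, index[p.tile_b]] = w
        a_mat[k, index[p.tile_a]] = -w
        bx[k] = w * p.measured_offset[0]
        by[k] = w * p.measured_offset[1]
    sol_x, *_ = np.linalg.lstsq(a_mat, bx, rcond=None)
    sol_y, *_ = np.linalg.lstsq(a_mat, by, rcond=None)
    positions = {t: (float(sol_x[index[t]]), float(sol_y[index[t]])) for t in tiles}
    residuals = {}
    for p in pair_offsets:
        rx = (positions[p.tile_b][0] - positions[p.tile_a][0]) - p.measured_offset[0]
        ry = (positions[p.tile_b][1] - positions[p.tile_a][1]) - p.measured_offset[1]
        residuals[(p.tile_a, p.tile_b)] = (rx, ry)
    return TilePositionSolution(positions=positions, anchor=anchor, residuals=residuals)


def composite(
    tiles: dict, solution: TilePositionSolution, blend: str = "feather"
) -> np.ndarray:
    """Render tiles onto an integer canvas at their solved positions.

    ``blend="feather"`` weights each tile by its distance to its own
    border, giving a linear cross-fade (convex combination) in overlaps;
    ``blend="first"`` keeps the first tile written.  Canvas size is the
    bounding box of the placed tiles; output dtype is float64.
    """
    if blend not in ("feather", "first"):
        raise ValueError("blend must be 'feather' or 'first'")
    placed = []
    for tid, arr in tiles.items():
        x, y = solution.positions[tid]
        placed.append((int(round(x)), int(round(y)), np.asarray(arr, dtype=float)))
    x_min = min(p[0] for p in placed)
    y_min = min(p[1] for p in placed)
    x_max = max(p[0] + p[2].shape[1] for p in placed)
    y_max = max(p[1] + p[2].shape[0] for p in placed)
    h, w = y_max - y_min, x_max - x_min
    acc = np.zeros((h, w))
    wsum = np.zeros((h, w))
    for x, y, arr in placed:
        th, tw = arr.shape
        if blend == "feather":
            ry = np.minimum(np.arange(th), np.arange(th)[::-1]) + 1.0
            rx = np.minimum(np.arange(tw), np.arange(tw)[::-1]) + 1.0
            wgt = np.minimum.outer(ry, rx)
        else:
            wgt = np.ones((th, tw))
        ys, xs = y - y_min, x - x_min
        view_a = acc[ys : ys + th, xs : xs + tw]
        view_w = wsum[ys : ys + th, xs : xs + tw]
        if blend == "first":
            empty = view_w == 0
            view_a[empty] = arr[empty]
            view_w[empty] = 1.0
        else:
            view_a += wgt * arr
            view_w += wgt
    out = np.divide(acc, wsum, out=np.zeros_like(acc), where=wsum > 0)
    return out
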