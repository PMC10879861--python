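"""Fusing a rectangular grid of small-FOV cubes into one large-FOV cube.

Large-area SRS maps are acquired as overlapping tiles; this module places
the tiles on a canvas and feathers the overlaps.  Tile positions default to
the nominal grid (tile pitch = tile size − overlap).  With ``refine=True``
the translation of each tile relative to its left/top neighbor is estimated
on the mean-over-channels image by an exhaustive integer-offset search
minimizing the sum of squared differences over the overlap region, within
±25% of the nominal overlap; the search window is tiny, so exhaustive
matching is exact and deterministic.  Registration is translation-only
(stage/galvo tiling has negligible rotation) with integer-pixel offsets.

Blending is a linear feather: each tile carries a separable weight ramp over
its overlap margins; the canvas is the weight-normalized sum, so non-overlap
regions are copied exactly and agreeing tiles merge without seams.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import HyperspectralCube

__all__ = ["TileGrid", "stitch_grid"]


@dataclass
class TileGrid:
    """Rectangular grid of tiles with a nominal neighbor overlap (pixels)."""

    rows: int
    cols: int
    tiles: list[list[HyperspectralCube]]
    nominal_overlap_px: int

    def __post_init__(self):
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid must have at least one tile")
        if len(self.tiles) != self.rows or any(len(r) != self.cols for r in self.tiles):
            raise ValueError("tiles do not match the declared grid shape")
        first = self.tiles[0][0]
        th, tw, _ = first.shape
        for row in self.tiles:
            for t in row:
                if t.axis != first.axis:
                    raise ValueError("tiles are on different wavenumber axes")
                if t.pixel_size_um != first.pixel_size_um:
                    raise ValueError("tiles have different pixel sizes")
                if t.shape != first.shape:
                    raise ValueError("tiles have different shapes")
        if not (0 <= self.nominal_overlap_px < min(th, tw)):
            raise ValueError("overlap must be non-negative and smaller than the tile")


def _estimate_offset(ref: np.ndarray, mov: np.ndarray, nominal: tuple[int, int],
                     search: int) -> tuple[int, int]:
    """Best integer displacement of ``mov`` relative to ``ref``.

    ``nominal`` is the expected (dy, dx) of mov's origin in ref coordinates;
    candidates within ±``search`` of it are scored by mean squared difference
    over the overlap, ties broken toward the nominal offset then
    lexicographically — deterministic.
    """
    h, w = ref.shape
    best = None
    for ddy in range(-search, search + 1):
        for ddx in range(-search, search + 1):
            dy, dx = nominal[0] + ddy, nominal[1] + ddx
            r0, r1 = max(0, dy), min(h, dy + h)
            c0, c1 = max(0, dx), min(w, dx + w)
            if r1 - r0 < 1 or c1 - c0 < 1:
                continue
            a = ref[r0:r1, c0:c1]
            b = mov[r0 - dy:r1 - dy, c0 - dx:c1 - dx]
            score = float(np.mean((a - b) ** 2))
            key = (score, abs(ddy) + abs(ddx), ddy, ddx)
            if best is None or key < best[0]:
                best = (key, (dy, dx))
    assert best is not None
    return best[1]


def _feather_weights(th: int, tw: int, overlap: int) -> np.ndarray:
    """Separable linear ramp over the overlap margins (always > 0)."""
    ramp_r = np.ones(th)
    ramp_c = np.ones(tw)
    if overlap > 0:
        edge = np.arange(1, overlap + 1) / (overlap + 1)
        n = min(overlap, th)
        ramp_r[:n] = np.minimum(ramp_r[:n], edge[:n])
        ramp_r[-n:] = np.minimum(ramp_r[-n:], edge[:n][::-1])
        n = min(overlap, tw)
        ramp_c[:n] = np.minimum(ramp_c[:n], edge[:n])
        ramp_c[-n:] = np.minimum(ramp_c[-n:], edge[:n][::-1])
    return ramp_r[:, None] * ramp_c[None, :]


def stitch_grid(grid: TileGrid, refine: bool = False) -> HyperspectralCube:
    """Fuse a tile grid into one cube (see module docstring).

    Estimated tile origins are stored in ``provenance["tile_origins"]`` as a
    rows×cols list of (row, col) pairs.
    """
    th, tw, m = grid.tiles[0][0].shape
    ov = grid.nominal_overlap_px
    means = [[t.data.mean(axis=2) for t in row] for row in grid.tiles]
    search = max(1, round(0.25 * ov)) if (refine and ov > 0) else 0

    origins = np.zeros((grid.rows, grid.cols, 2), dtype=int)
    for r in range(grid.rows):
        for c in range(grid.cols):
            if r == 0 and c == 0:
                continue
            if c > 0:  # place relative to left neighbor
                base = origins[r, c - 1]
                nominal = (0, tw - ov)
                ref, mov = means[r][c - 1], means[r][c]
            else:      # first column: place relative to top neighbor
                base = origins[r - 1, c]
                nominal = (th - ov, 0)
                ref, mov = means[r - 1][c], means[r][c]
            if search:
                dy, dx = _estimate_offset(ref, mov, nominal, search)
            else:
                dy, dx = nominal
            origins[r, c] = base + (dy, dx)

    origins[:, :, 0] -= origins[:, :, 0].min()
    origins[:, :, 1] -= origins[:, :, 1].min()
    out_h = int(origins[:, :, 0].max()) + th
    out_w = int(origins[:, :, 1].max()) + tw

    acc = np.zeros((out_h, out_w, m))
    wacc = np.zeros((out_h, out_w))
    weights = _feather_weights(th, tw, ov)
    for r in range(grid.rows):
        for c in range(grid.cols):
            oy, ox = origins[r, c]
            acc[oy:oy + th, ox:ox + tw] += weights[:, :, None] * grid.tiles[r][c].data
            wacc[oy:oy + th, ox:ox + tw] += weights
    filled = wacc > 0
    out = np.zeros_like(acc)
    out[filled] = acc[filled] / wacc[filled][:, None]

    first = grid.tiles[0][0]
    prov = {
        "stitched": True,
        "grid": (grid.rows, grid.cols),
        "nominal_overlap_px": ov,
        "refined": bool(refine),
        "tile_origins": origins.tolist(),
    }
    return HyperspectralCube(out, first.axis, first.pixel_size_um, prov)
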