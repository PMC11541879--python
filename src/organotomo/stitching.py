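"""Correlation-calibrated stitching of laterally tiled tomograms.

The motorized stage that presents adjacent fields of view has limited
positioning precision, so nominal tile offsets are wrong by a few
voxels.  Calibration maximizes the Pearson correlation of the RI values
in each pair's overlap over an exhaustive integer search window (one 2D
lateral offset per pair, computed jointly over all z — a stage error
applies to the whole stack).  Pairwise estimates are reconciled into
global tile positions over a maximum-correlation spanning tree, and the
tiles are composited slice by slice with Laplacian-pyramid blending
across the overlap seams.
"""

from __future__ import annotations

import math
import warnings

import networkx as nx
import numpy as np
from scipy import ndimage

from .types import OffsetEstimate, RITomogram, TileSet

__all__ = [
    "estimate_pairwise_offset",
    "reconcile_offsets",
    "stitch_mosaic",
    "adjacent_pairs",
    "stitch_tileset",
]

DEFAULT_SEARCH_RADIUS = 10


def _overlap_views(a: np.ndarray, b: np.ndarray, offset: tuple[int, int]):
    """Overlapping subvolumes of tile a at (0,0) and tile b at `offset`."""
    ox, oy = offset
    ax0, ax1 = max(0, ox), min(a.shape[0], ox + b.shape[0])
    ay0, ay1 = max(0, oy), min(a.shape[1], oy + b.shape[1])
    if ax1 <= ax0 or ay1 <= ay0:
        return None, None
    va = a[ax0:ax1, ay0:ay1, :]
    vb = b[ax0 - ox : ax1 - ox, ay0 - oy : ay1 - oy, :]
    return va, vb


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x.ravel().astype(np.float64)
    y = y.ravel().astype(np.float64)
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:  # exactly constant: r undefined
        return math.nan
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0.0:
        return math.nan
    return float(xc @ yc) / denom


def estimate_pairwise_offset(
    tile_i: RITomogram,
    tile_j: RITomogram,
    nominal: tuple[int, int],
    search_radius_vox: int = DEFAULT_SEARCH_RADIUS,
    pair: tuple[int, int] = (0, 1),
) -> OffsetEstimate:
    """Calibrate the lateral offset of ``tile_j`` relative to ``tile_i``.

    Exhaustively evaluates every integer ``(dx, dy)`` within
    ``±search_radius_vox`` of the nominal offset and returns the one
    maximizing the Pearson correlation of the overlapping RI voxels
    (all z jointly).  Ties break toward the smallest Euclidean
    displacement from nominal, then lexicographically.

    When the overlap is constant-valued (zero variance, correlation
    undefined), the nominal offset is returned with ``fallback=True``
    and a warning.
    """
    a, b = tile_i.values, tile_j.values
    best = None  # (r, dist2, (dx, dy), overlap_count)
    any_defined = False
    for ddx in range(-search_radius_vox, search_radius_vox + 1):
        for ddy in range(-search_radius_vox, search_radius_vox + 1):
            cand = (nominal[0] + ddx, nominal[1] + ddy)
            va, vb = _overlap_views(a, b, cand)
            if va is None or va.shape[0] * va.shape[1] < 4:
                continue
            r = _pearson(va, vb)
            if math.isnan(r):
                continue
            any_defined = True
            key = (-r, ddx * ddx + ddy * ddy, cand)
            if best is None or key < best[0]:
                best = (key, cand, va.size)
    if not any_defined:
        warnings.warn(
            f"pair {pair}: overlap has zero variance; falling back to nominal offset",
            stacklevel=2,
        )
        va, vb = _overlap_views(a, b, nominal)
        return OffsetEstimate(
            pair=pair,
            offset_vox=tuple(nominal),
            pearson_r=math.nan,
            overlap_vox=0 if va is None else va.size,
            fallback=True,
        )
    key, cand, count = best
    return OffsetEstimate(
        pair=pair, offset_vox=cand, pearson_r=-key[0], overlap_vox=count
    )


def adjacent_pairs(grid: tuple[int, int]) -> list[tuple[int, int]]:
    """Index pairs of row-major grid tiles that share an edge."""
    rows, cols = grid
    pairs = []
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            if c + 1 < cols:
                pairs.append((i, i + 1))
            if r + 1 < rows:
                pairs.append((i, i + cols))
    return pairs


def reconcile_offsets(
    estimates: list[OffsetEstimate], n_tiles: int
) -> tuple[dict[int, tuple[int, int]], dict[tuple[int, int], tuple[int, int]]]:
    """Turn pairwise offsets into global integer tile positions.

    Tile 0 is anchored at the origin; the remaining tiles are placed by
    accumulating pairwise offsets along a maximum-correlation spanning
    tree of the pair graph.  Cyclic inconsistencies among the estimates
    do not affect the (deterministic) tree result but are reported as
    per-edge loop residuals.

    Returns
    -------
    (positions, residuals)
        ``positions[tile] = (x, y)`` and, for every non-tree edge, the
        residual ``estimated − implied`` offset.
    """
    g = nx.Graph()
    g.add_nodes_from(range(n_tiles))
    for e in estimates:
        i, j = e.pair
        w = -1.0 if math.isnan(e.pearson_r) else e.pearson_r
        g.add_edge(i, j, weight=w, estimate=e)
    if not nx.is_connected(g):
        comps = list(nx.connected_components(g))
        unreachable = sorted(set(range(n_tiles)) - comps[0])
        raise ValueError(f"pairwise estimates do not connect all tiles; unreachable: {unreachable}")
    # deterministic MST: stable tie-break on (weight, endpoints)
    tree = nx.Graph()
    tree.add_nodes_from(g.nodes)
    for i, j, data in sorted(
        g.edges(data=True), key=lambda e: (-e[2]["weight"], e[0], e[1])
    ):
        if nx.has_path(tree, i, j):
            continue
        tree.add_edge(i, j, **data)
    positions: dict[int, tuple[int, int]] = {0: (0, 0)}
    for parent, child in nx.bfs_edges(tree, 0):
        est: OffsetEstimate = tree.edges[parent, child]["estimate"]
        dx, dy = est.offset_vox
        if est.pair == (child, parent):
            dx, dy = -dx, -dy
        px, py = positions[parent]
        positions[child] = (px + dx, py + dy)
    residuals: dict[tuple[int, int], tuple[int, int]] = {}
    for e in estimates:
        i, j = e.pair
        if tree.has_edge(i, j):
            continue
        implied = (positions[j][0] - positions[i][0], positions[j][1] - positions[i][1])
        residuals[(i, j)] = (e.offset_vox[0] - implied[0], e.offset_vox[1] - implied[1])
    return positions, residuals


# ---------------------------------------------------------------------------
# Laplacian-pyramid blending

def _reduce(img: np.ndarray) -> np.ndarray:
    return ndimage.gaussian_filter(img, 1.0, mode="nearest")[::2, ::2]


def _expand(img: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    up = np.zeros(shape, dtype=img.dtype)
    up[::2, ::2] = img
    up = ndimage.gaussian_filter(up, 1.0, mode="nearest")
    norm = np.zeros(shape, dtype=img.dtype)
    norm[::2, ::2] = 1.0
    norm = ndimage.gaussian_filter(norm, 1.0, mode="nearest")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(norm > 0, up / norm, 0.0)
    return out


def _pyramid_blend(a: np.ndarray, b: np.ndarray, mask_b: np.ndarray, levels: int) -> np.ndarray:
    """Blend two 2D images with a Laplacian pyramid; mask_b in [0,1] weights b."""
    if levels <= 0:
        return a * (1 - mask_b) + b * mask_b
    ga, gb, gm = [a.astype(np.float64)], [b.astype(np.float64)], [mask_b.astype(np.float64)]
    for _ in range(levels):
        if min(ga[-1].shape) < 4:
            break
        ga.append(_reduce(ga[-1]))
        gb.append(_reduce(gb[-1]))
        gm.append(_reduce(gm[-1]))
    blended = ga[-1] * (1 - gm[-1]) + gb[-1] * gm[-1]
    for k in range(len(ga) - 2, -1, -1):
        la = ga[k] - _expand(ga[k + 1], ga[k].shape)
        lb = gb[k] - _expand(gb[k + 1], gb[k].shape)
        blended = _expand(blended, ga[k].shape) + la * (1 - gm[k]) + lb * gm[k]
    return blended


def stitch_mosaic(
    tiles: TileSet,
    positions: dict[int, tuple[int, int]],
    pyramid_levels: int | None = None,
) -> RITomogram:
    """Composite calibrated tiles into a seamless mosaic.

    Per axial slice, tiles are merged by Laplacian-pyramid blending with
    a half-overlap seam mask (default level count
    ``floor(log2(overlap_vox))``).  Outside overlap regions the mosaic
    equals the contributing tile exactly, and blended values are clipped
    to the contributing tiles' per-slice range so blending never leaves
    the data's intensity range.
    """
    ov = tiles.overlap_vox
    if pyramid_levels is None:
        pyramid_levels = max(0, int(math.floor(math.log2(max(ov, 1)))))
    elif ov > 0 and pyramid_levels > int(math.floor(math.log2(max(ov, 1)))):
        raise ValueError(
            f"{pyramid_levels} pyramid levels exceed what a {ov}-voxel overlap supports"
        )
    n = len(tiles.tiles)
    xs = [positions[i][0] for i in range(n)]
    ys = [positions[i][1] for i in range(n)]
    x0, y0 = min(xs), min(ys)
    nx_, ny_ = (
        max(positions[i][0] + tiles.tiles[i].shape[0] for i in range(n)) - x0,
        max(positions[i][1] + tiles.tiles[i].shape[1] for i in range(n)) - y0,
    )
    nz = tiles.tiles[0].shape[2]
    mosaic = np.zeros((nx_, ny_, nz), dtype=np.float64)
    filled = np.zeros((nx_, ny_), dtype=bool)  # lateral coverage so far
    coverage = np.zeros((nx_, ny_), dtype=np.int16)
    lo = np.full((nx_, ny_, nz), np.inf)
    hi = np.full((nx_, ny_, nz), -np.inf)

    for i in range(n):
        t = tiles.tiles[i]
        px, py = positions[i][0] - x0, positions[i][1] - y0
        sx, sy = slice(px, px + t.shape[0]), slice(py, py + t.shape[1])
        region = (sx, sy)
        tile_vals = t.values.astype(np.float64)
        new_cov = np.zeros((nx_, ny_), dtype=bool)
        new_cov[region] = True
        overlap2d = new_cov & filled
        lo[sx, sy, :] = np.minimum(lo[sx, sy, :], tile_vals)
        hi[sx, sy, :] = np.maximum(hi[sx, sy, :], tile_vals)
        if not overlap2d.any():
            mosaic[sx, sy, :] = tile_vals
        else:
            # seam mask: weight toward the nearer tile centre (half-overlap seam)
            dist_old = ndimage.distance_transform_edt(filled)
            dist_new = ndimage.distance_transform_edt(new_cov)
            mask_b2d = np.where(new_cov & ~filled, 1.0, 0.0)
            seam = overlap2d
            mask_b2d[seam] = (dist_new[seam] > dist_old[seam]).astype(np.float64)
            a_fill = mosaic.copy()
            # fill each image's uncovered area with the other's values so the
            # pyramid blends real data everywhere
            only_new = new_cov & ~filled
            a_fill[only_new, :] = 0.0
            a_fill[sx, sy, :] = np.where(
                filled[sx, sy, None], mosaic[sx, sy, :], tile_vals
            )
            b_fill = a_fill.copy()
            b_fill[sx, sy, :] = tile_vals
            out = np.empty_like(a_fill)
            for z in range(nz):
                out[:, :, z] = _pyramid_blend(
                    a_fill[:, :, z], b_fill[:, :, z], mask_b2d, pyramid_levels
                )
            both = filled | new_cov
            mosaic[both, :] = out[both, :]
            # exactness outside overlap bands
            mosaic[only_new, :] = b_fill[only_new, :]
            keep_old = filled & ~new_cov
            mosaic[keep_old, :] = a_fill[keep_old, :]
        filled |= new_cov
        coverage[region] += 1

    # clip to contributing range (pyramid ringing guard)
    multi = coverage > 1
    if multi.any():
        mosaic[multi, :] = np.clip(mosaic[multi, :], lo[multi, :], hi[multi, :])
    t0 = tiles.tiles[0]
    return RITomogram(
        values=mosaic,
        voxel_spacing_um=t0.voxel_spacing_um,
        n_medium=t0.n_medium,
        origin_um=(
            t0.origin_um[0] + x0 * t0.voxel_spacing_um[0],
            t0.origin_um[1] + y0 * t0.voxel_spacing_um[1],
        ),
        timestamp_h=t0.timestamp_h,
        identifier="mosaic[" + ",".join(t.identifier for t in tiles.tiles) + "]",
    )


def stitch_tileset(
    tiles: TileSet,
    grid: tuple[int, int],
    search_radius_vox: int = DEFAULT_SEARCH_RADIUS,
    pyramid_levels: int | None = None,
) -> tuple[RITomogram, list[OffsetEstimate], dict[int, tuple[int, int]]]:
    """End-to-end stitching of a grid tile set.

    Convenience wrapper: estimate every adjacent pair's offset, reconcile
    into global positions, and blend.  Returns the mosaic, the pairwise
    estimates, and the positions.
    """
    nominal = tiles.nominal_offsets_vox
    estimates = []
    for i, j in adjacent_pairs(grid):
        nom_ij = (nominal[j][0] - nominal[i][0], nominal[j][1] - nominal[i][1])
        estimates.append(
            estimate_pairwise_offset(
                tiles.tiles[i], tiles.tiles[j], nom_ij, search_radius_vox, pair=(i, j)
            )
        )
    positions, _ = reconcile_offsets(estimates, len(tiles.tiles))
    mosaic = stitch_mosaic(tiles, positions, pyramid_levels)
    return mosaic, estimates, positions
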