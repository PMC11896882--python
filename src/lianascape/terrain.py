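"""Terrain indices from a digital elevation model.

The only topographic covariate the analyses need is the relative slope
position (RSP), a dimensionless index in [0, 1]::

    RSP = AACL / (AACL + ABRL)

where AACL is the altitude above the channel network and ABRL the altitude
below the ridge network.  Channels are derived from D8 (steepest-descent)
flow accumulation; ridges are the channels of the negated DEM, so the whole
construction is symmetric: negating the DEM exchanges AACL and ABRL and maps
RSP to 1 - RSP (up to cells with tied elevations).

RSP is 0 on channel cells and exactly 1 on summit cells such as the tops of
the large termite mounds that dominate the microtopography at sites like the
one this package models: a summit is a terminal cell of the inverted surface,
so its altitude below ridge is identically zero.

Cells where D8 flow terminates (local minima, and boundary cells with no
lower neighbour) are counted as part of the network: they act as local base
levels.  Closed depressions in noisy real-world DEMs should be removed first
with :func:`fill_pits` (priority-flood).
"""

from __future__ import annotations

import heapq

import numpy as np

from .io import Raster

__all__ = [
    "fill_pits",
    "d8_downslope",
    "flow_accumulation",
    "channel_network",
    "altitude_above_network",
    "relative_slope_position",
]

# D8 neighbour offsets (row, col)
_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_DIST = np.array([np.hypot(dr, dc) for dr, dc in _OFFSETS])


def fill_pits(dem: np.ndarray) -> np.ndarray:
    """Priority-flood depression filling (raises closed pits to spill level).

    Returns a copy; does not add gradient epsilons, so filled areas are flat.
    """
    z = np.asarray(dem, dtype=float)
    nr, nc = z.shape
    filled = np.full_like(z, np.inf)
    closed = np.zeros(z.shape, dtype=bool)
    heap: list[tuple[float, int, int]] = []
    for i in range(nr):
        for j in range(nc):
            if i in (0, nr - 1) or j in (0, nc - 1):
                filled[i, j] = z[i, j]
                closed[i, j] = True
                heapq.heappush(heap, (z[i, j], i, j))
    while heap:
        level, i, j = heapq.heappop(heap)
        for dr, dc in _OFFSETS:
            r, c = i + dr, j + dc
            if 0 <= r < nr and 0 <= c < nc and not closed[r, c]:
                closed[r, c] = True
                filled[r, c] = max(z[r, c], level)
                heapq.heappush(heap, (filled[r, c], r, c))
    return filled


def d8_downslope(dem: np.ndarray) -> np.ndarray:
    """Flat index of the steepest strictly-lower D8 neighbour, -1 if none.

    Slope is drop over distance (diagonal neighbours are sqrt(2) cells away);
    ties go to the first neighbour in a fixed scan order, which makes the
    routing deterministic.
    """
    z = np.asarray(dem, dtype=float)
    nr, nc = z.shape
    best_slope = np.zeros((nr, nc))
    down = np.full((nr, nc), -1, dtype=np.int64)
    for k, (dr, dc) in enumerate(_OFFSETS):
        drop = np.full((nr, nc), -np.inf)
        r0, r1 = max(0, -dr), min(nr, nr - dr)
        c0, c1 = max(0, -dc), min(nc, nc - dc)
        drop[r0:r1, c0:c1] = z[r0:r1, c0:c1] - z[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        slope = drop / _DIST[k]
        better = slope > best_slope
        down[better] = (np.arange(nr * nc).reshape(nr, nc) + dr * nc + dc)[better]
        best_slope = np.where(better, slope, best_slope)
    return down.ravel()


def flow_accumulation(dem: np.ndarray, down: np.ndarray | None = None) -> np.ndarray:
    """D8 flow accumulation in cells (each cell contributes itself)."""
    z = np.asarray(dem, dtype=float)
    if down is None:
        down = d8_downslope(z)
    order = np.argsort(z.ravel(), kind="stable")[::-1]  # high to low
    acc = np.ones(z.size)
    for c in order:
        d = down[c]
        if d >= 0:
            acc[d] += acc[c]
    return acc.reshape(z.shape)


def channel_network(dem: np.ndarray, threshold_cells: float | None = None,
                    down: np.ndarray | None = None) -> np.ndarray:
    """Boolean channel mask: accumulation >= threshold, plus terminal cells.

    Default threshold is 1% of the grid cell count.
    """
    z = np.asarray(dem, dtype=float)
    if down is None:
        down = d8_downslope(z)
    if threshold_cells is None:
        threshold_cells = max(2.0, 0.01 * z.size)
    if threshold_cells > z.size:
        raise ValueError(f"channel threshold {threshold_cells} exceeds cell count {z.size}")
    acc = flow_accumulation(z, down)
    mask = acc >= threshold_cells
    mask.ravel()[down < 0] = True  # flow terminates: local base level
    return mask


def altitude_above_network(dem: np.ndarray, threshold_cells: float | None = None) -> np.ndarray:
    """Elevation drop from each cell to the channel cell its D8 path reaches."""
    z = np.asarray(dem, dtype=float)
    down = d8_downslope(z)
    mask = channel_network(z, threshold_cells, down).ravel()
    zf = z.ravel()
    base = np.empty_like(zf)
    order = np.argsort(zf, kind="stable")  # low to high: downslope cell done first
    for c in order:
        base[c] = zf[c] if mask[c] else base[down[c]]
    return (zf - base).reshape(z.shape)


def relative_slope_position(dem: Raster | np.ndarray,
                            threshold_cells: float | None = None) -> np.ndarray:
    """Per-cell RSP = AACL / (AACL + ABRL); 0/0 (flat terrain) -> 0.5."""
    z = dem.values if isinstance(dem, Raster) else np.asarray(dem, dtype=float)
    aacl = altitude_above_network(z, threshold_cells)
    abrl = altitude_above_network(-z, threshold_cells)
    total = aacl + abrl
    with np.errstate(invalid="ignore"):
        rsp = np.where(total > 0, aacl / np.where(total > 0, total, 1.0), 0.5)
    return rsp
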