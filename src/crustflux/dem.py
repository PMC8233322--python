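"""Raster conditioning and flow routing for supraglacial catchment geometry.

The pipeline is the standard hydrological one, applied to ice-surface DEMs:
detrend (moving plane fit) and Gaussian-smooth the raster, fill closed
depressions up to a threshold depth (deeper sinks -- crevasse-like features --
are retained), route flow by steepest descent over 8 neighbours (D8), extract
the stream network above a flow-accumulation threshold, and measure along-path
flow distance from every interfluve cell to the nearest stream cell.  Bank
geometry (the strip of crust draining "immediately" into a stream) and the
mean surface slope feed the throughflow flux model.

Grid convention: row-major, origin upper-left, cell-centre registration,
NaN for nodata; all areas are ``count * resolution**2``.  No geographic
projection handling -- grids are synthetic or local.

D8 neighbour order (and deterministic tie-break priority) is
E, SE, S, SW, W, NW, N, NE, coded 0..7; code -1 marks an outlet (flow leaves
the grid, or terminates in a retained deep sink).
"""

from __future__ import annotations

import heapq
import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "DemGrid",
    "HydroParams",
    "D8Result",
    "StreamSet",
    "BankGeometry",
    "OFFSETS",
    "detrend",
    "gaussian_smooth",
    "fill_sinks",
    "d8_route",
    "extract_streams",
    "flow_distance_to_stream",
    "bank_geometry",
    "mean_slope",
    "derive_streams",
    "write_ascii_grid",
    "read_ascii_grid",
]

# (drow, dcol) in tie-break priority order E, SE, S, SW, W, NW, N, NE
OFFSETS = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]
_DIAGONAL = [abs(dr) + abs(dc) == 2 for dr, dc in OFFSETS]


@dataclass
class DemGrid:
    """An elevation raster in metres with square cells; NaN marks nodata."""

    z: np.ndarray
    resolution: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)  # (x, y) of the lower-left corner

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 2:
            raise ValueError("elevation must be a 2-D grid")
        if not (self.resolution > 0):
            raise ValueError("resolution must be positive")

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.z)

    def copy_with(self, z: np.ndarray) -> "DemGrid":
        return DemGrid(z=z, resolution=self.resolution, origin=self.origin)


@dataclass(frozen=True)
class HydroParams:
    """Routing parameters: maximum sink-fill depth (m), stream-defining flow
    accumulation threshold (m^2), and bank-strip width (m)."""

    sink_fill_max_depth: float = 0.51
    stream_accum_threshold: float = 165.0
    bank_width: float = 1.0

    def __post_init__(self) -> None:
        for name in ("sink_fill_max_depth", "stream_accum_threshold", "bank_width"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive")


def detrend(dem: DemGrid, window: int = 31) -> tuple[DemGrid, DemGrid]:
    """Split the raster into low- and high-frequency surfaces by a moving
    local plane fit.

    The low-frequency surface is, at each cell, the least-squares plane over
    the surrounding ``window x window`` neighbourhood (clipped at the raster
    edge) evaluated at that cell; high = dem - low, so low + high
    reconstructs the input exactly.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    nrows, ncols = dem.z.shape
    if window > min(nrows, ncols):
        raise ValueError("window larger than grid")

    valid = dem.valid
    z = np.where(valid, dem.z, 0.0)
    w = valid.astype(float)
    rows, cols = np.mgrid[0:nrows, 0:ncols].astype(float)

    def boxsum(a: np.ndarray) -> np.ndarray:
        return ndimage.uniform_filter(a, size=window, mode="constant", cval=0.0) * window**2

    N = boxsum(w)
    Sx = boxsum(w * cols)
    Sy = boxsum(w * rows)
    Sxx = boxsum(w * cols**2)
    Syy = boxsum(w * rows**2)
    Sxy = boxsum(w * cols * rows)
    Sz = boxsum(z)
    Sxz = boxsum(z * cols)
    Syz = boxsum(z * rows)

    A = np.stack(
        [
            np.stack([N, Sx, Sy], axis=-1),
            np.stack([Sx, Sxx, Sxy], axis=-1),
            np.stack([Sy, Sxy, Syy], axis=-1),
        ],
        axis=-2,
    )
    b = np.stack([Sz, Sxz, Syz], axis=-1)
    coef = np.linalg.solve(A, b[..., None])[..., 0]
    low = coef[..., 0] + coef[..., 1] * cols + coef[..., 2] * rows
    low = np.where(valid, low, np.nan)
    high = dem.z - low
    return dem.copy_with(low), dem.copy_with(high)


def gaussian_smooth(dem: DemGrid, kernel: int = 11) -> DemGrid:
    """Normalised Gaussian smoothing with the kernel half-width spanning two
    standard deviations (sigma = (kernel - 1) / 4); constant fields pass
    through unchanged, and nodata is handled by normalised convolution."""
    if kernel < 3 or kernel % 2 == 0:
        raise ValueError("kernel must be odd and >= 3")
    sigma = (kernel - 1) / 4.0
    radius = (kernel - 1) // 2
    valid = dem.valid
    z = np.where(valid, dem.z, 0.0)
    w = valid.astype(float)
    num = ndimage.gaussian_filter(z, sigma=sigma, truncate=radius / sigma, mode="constant")
    den = ndimage.gaussian_filter(w, sigma=sigma, truncate=radius / sigma, mode="constant")
    out = np.where(valid & (den > 0), num / np.where(den > 0, den, 1.0), np.nan)
    return dem.copy_with(out)


def _priority_flood(dem: DemGrid) -> np.ndarray:
    """Filled surface F >= z with no internal depressions (priority flood)."""
    z = dem.z
    nrows, ncols = z.shape
    valid = dem.valid
    if not valid.any():
        raise ValueError("all-nodata grid")
    F = np.full_like(z, np.inf)
    F[~valid] = np.nan
    visited = ~valid

    # seeds: valid cells on the raster border or adjacent (8-way) to nodata
    border = np.zeros_like(valid)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    near_nodata = ndimage.binary_dilation(~valid, structure=np.ones((3, 3), bool))
    seeds = valid & (border | near_nodata)

    heap: list[tuple[float, int, int]] = []
    for r, c in zip(*np.nonzero(seeds)):
        F[r, c] = z[r, c]
        visited[r, c] = True
        heapq.heappush(heap, (z[r, c], int(r), int(c)))

    while heap:
        level, r, c = heapq.heappop(heap)
        for dr, dc in OFFSETS:
            nr, nc = r + dr, c + dc
            if 0 <= nr < nrows and 0 <= nc < ncols and not visited[nr, nc]:
                visited[nr, nc] = True
                F[nr, nc] = max(z[nr, nc], level)
                heapq.heappush(heap, (F[nr, nc], nr, nc))
    return F


def fill_sinks(dem: DemGrid, params: HydroParams = HydroParams()) -> DemGrid:
    """Fill closed depressions whose depth (pour level minus basin minimum) is
    at most the threshold; deeper depressions are retained untouched.

    Idempotent: refilling a filled grid changes nothing (retained deep sinks
    stay deep and are reverted identically).
    """
    F = _priority_flood(dem)
    z = dem.z
    raised = np.isfinite(z) & (F > z + 1e-12)
    out = np.where(np.isfinite(z), F, np.nan)
    if raised.any():
        labels, nlab = ndimage.label(raised, structure=np.ones((3, 3), int))
        depth = ndimage.maximum(F - z, labels=labels, index=np.arange(1, nlab + 1))
        deep = np.atleast_1d(depth) > params.sink_fill_max_depth
        for lab in np.nonzero(deep)[0] + 1:
            sel = labels == lab
            out[sel] = z[sel]
    return dem.copy_with(out)


@dataclass
class D8Result:
    """D8 directions (codes 0..7, -1 outlet, -2 nodata) and flow accumulation
    in m^2 (including each cell's own area).  ``unresolved`` lists interior
    cells that could not drain (minima of retained deep sinks); they act as
    internal outlets."""

    directions: np.ndarray
    accumulation: np.ndarray
    resolution: float
    unresolved: list[tuple[int, int]] = field(default_factory=list)


def d8_route(dem: DemGrid) -> D8Result:
    """Steepest-descent single-direction routing with deterministic tie-break.

    Gradient ties pick the lowest direction code (E before SE before S, ...).
    Flats (plateaus left by depression filling) are drained by breadth-first
    assignment toward the nearest already-draining cell of equal elevation
    (their pour point).  Accumulation is computed over the receiver forest.
    """
    z = dem.z
    nrows, ncols = z.shape
    res = dem.resolution
    valid = dem.valid
    directions = np.full((nrows, ncols), -2, dtype=np.int8)

    pad = np.full((nrows + 2, ncols + 2), np.nan)
    pad[1:-1, 1:-1] = z
    best_grad = np.full((nrows, ncols), 0.0)
    best_dir = np.full((nrows, ncols), -1, dtype=np.int8)
    has_boundary = np.zeros((nrows, ncols), dtype=bool)  # off-grid or nodata neighbour
    for code, (dr, dc) in enumerate(OFFSETS):
        zn = pad[1 + dr : 1 + dr + nrows, 1 + dc : 1 + dc + ncols]
        dist = res * (math.sqrt(2.0) if _DIAGONAL[code] else 1.0)
        with np.errstate(invalid="ignore"):
            grad = (z - zn) / dist
        nb_invalid = ~np.isfinite(zn)
        has_boundary |= nb_invalid
        # strictly-greater comparison in ascending code order => lowest code wins ties
        improved = np.isfinite(grad) & (grad > best_grad)
        best_dir = np.where(improved, code, best_dir)
        best_grad = np.where(improved, grad, best_grad)

    downhill = valid & (best_dir >= 0)
    directions[downhill] = best_dir[downhill]
    # cells with no downhill neighbour but touching the boundary drain off-grid
    outlet = valid & ~downhill & has_boundary
    directions[outlet] = -1

    # flats: valid cells still undirected; drain toward an equal-elevation
    # neighbour that already drains (BFS from the resolved rim)
    undirected = valid & ~downhill & ~outlet
    if undirected.any():
        queue: deque[tuple[int, int]] = deque()
        resolved = valid & ~undirected
        for r, c in zip(*np.nonzero(undirected)):
            for code, (dr, dc) in enumerate(OFFSETS):
                nr, nc = r + dr, c + dc
                if (
                    0 <= nr < nrows
                    and 0 <= nc < ncols
                    and resolved[nr, nc]
                    and abs(z[nr, nc] - z[r, c]) <= 1e-12
                ):
                    directions[r, c] = code
                    undirected[r, c] = False
                    queue.append((int(r), int(c)))
                    break
        while queue:
            r, c = queue.popleft()
            for code, (dr, dc) in enumerate(OFFSETS):
                nr, nc = r + dr, c + dc
                if (
                    0 <= nr < nrows
                    and 0 <= nc < ncols
                    and undirected[nr, nc]
                    and abs(z[nr, nc] - z[r, c]) <= 1e-12
                ):
                    # neighbour drains into the newly resolved cell
                    rev = (code + 4) % 8
                    directions[nr, nc] = rev
                    undirected[nr, nc] = False
                    queue.append((nr, nc))

    unresolved = [(int(r), int(c)) for r, c in zip(*np.nonzero(undirected))]
    for r, c in unresolved:
        directions[r, c] = -1  # internal outlet (retained deep sink)

    accumulation = _accumulate(directions, valid, res)
    return D8Result(directions=directions, accumulation=accumulation, resolution=res, unresolved=unresolved)


def _receiver_index(directions: np.ndarray) -> np.ndarray:
    """Flat index of each cell's receiver; -1 for outlets/nodata."""
    nrows, ncols = directions.shape
    rows, cols = np.mgrid[0:nrows, 0:ncols]
    recv = np.full((nrows, ncols), -1, dtype=np.int64)
    for code, (dr, dc) in enumerate(OFFSETS):
        sel = directions == code
        recv[sel] = (rows[sel] + dr) * ncols + (cols[sel] + dc)
    return recv.ravel()


def _accumulate(directions: np.ndarray, valid: np.ndarray, res: float) -> np.ndarray:
    nrows, ncols = directions.shape
    recv = _receiver_index(directions)
    acc = np.where(valid.ravel(), res * res, 0.0)
    indeg = np.zeros(nrows * ncols, dtype=np.int64)
    pointed = recv[recv >= 0]
    np.add.at(indeg, pointed, 1)
    stack = list(np.nonzero((indeg == 0) & valid.ravel())[0])
    while stack:
        i = stack.pop()
        j = recv[i]
        if j >= 0:
            acc[j] += acc[i]
            indeg[j] -= 1
            if indeg[j] == 0:
                stack.append(int(j))
    out = acc.reshape(nrows, ncols)
    out[~valid] = np.nan
    return out


def extract_streams(accumulation: np.ndarray, params: HydroParams = HydroParams()) -> np.ndarray:
    """Boolean stream mask: accumulation at or above the threshold."""
    with np.errstate(invalid="ignore"):
        return np.isfinite(accumulation) & (accumulation >= params.stream_accum_threshold)


def flow_distance_to_stream(
    directions: np.ndarray, stream_mask: np.ndarray, resolution: float
) -> np.ndarray:
    """Along-path distance (m) from each cell to the first stream cell on its
    D8 path; 0 on stream cells, inf where the path leaves the grid (or dies in
    a retained sink) without meeting a stream, NaN on nodata."""
    nrows, ncols = directions.shape
    dist = np.full((nrows, ncols), np.nan)
    dist[stream_mask] = 0.0
    step = np.array(
        [resolution * (math.sqrt(2.0) if d else 1.0) for d in _DIAGONAL]
    )
    valid = directions >= -1
    known = stream_mask.copy()

    for r0 in range(nrows):
        for c0 in range(ncols):
            if not valid[r0, c0] or known[r0, c0]:
                continue
            path: list[tuple[int, int, float]] = []
            r, c = r0, c0
            while True:
                if known[r, c]:
                    base = dist[r, c]
                    break
                code = directions[r, c]
                if code < 0:
                    base = math.inf
                    path.append((r, c, 0.0))
                    break
                dr, dc = OFFSETS[code]
                path.append((r, c, step[code]))
                r, c = r + dr, c + dc
                if not (0 <= r < nrows and 0 <= c < ncols) or not valid[r, c]:
                    raise ValueError("flow direction leads off the valid grid interior")
            total = base
            for r, c, s in reversed(path):
                if math.isinf(total):
                    dist[r, c] = math.inf
                else:
                    total = total + s
                    dist[r, c] = total
                known[r, c] = True
    return dist


@dataclass(frozen=True)
class BankGeometry:
    bank_area: float  # m^2 of interfluve within bank_width of a stream
    bank_length: float  # m of discharging bank (= bank_area / bank_width)
    mean_distance: float  # mean flow distance over interfluve cells (m)


def bank_geometry(
    flow_distance: np.ndarray,
    stream_mask: np.ndarray,
    params: HydroParams = HydroParams(),
    resolution: float = 1.0,
) -> BankGeometry:
    """Bank-strip area/length and mean distance-to-stream over the interfluve.

    Interfluve = valid non-stream cells.  With an empty stream network the
    bank area is 0 and the mean distance is reported as infinite.
    """
    interfluve = np.isfinite(flow_distance) | np.isinf(flow_distance)
    interfluve &= ~stream_mask & ~np.isnan(flow_distance)
    d = flow_distance[interfluve]
    bank_cells = int(np.sum(d <= params.bank_width))
    bank_area = bank_cells * resolution**2
    if d.size == 0 or not np.isfinite(d).any():
        mean_d = math.inf
    else:
        mean_d = float(np.mean(d[np.isfinite(d)]))
    return BankGeometry(
        bank_area=bank_area,
        bank_length=bank_area / params.bank_width,
        mean_distance=mean_d,
    )


def mean_slope(dem: DemGrid) -> float:
    """Mean per-cell gradient magnitude (m/m) by central differences,
    nodata excluded."""
    gy, gx = np.gradient(dem.z, dem.resolution)
    mag = np.sqrt(gx**2 + gy**2)
    if not np.isfinite(mag).any():
        raise ValueError("no valid cells for slope computation")
    return float(np.nanmean(mag))


@dataclass
class StreamSet:
    """Bundle of the derived routing products for one DEM."""

    d8: D8Result
    stream_mask: np.ndarray
    flow_distance: np.ndarray
    bank: BankGeometry
    params: HydroParams


def derive_streams(dem: DemGrid, params: HydroParams = HydroParams()) -> StreamSet:
    """Full conditioning-to-bank-geometry chain on an (already detrended /
    smoothed, if desired) elevation grid: fill, route, threshold streams,
    measure flow distance and bank geometry."""
    filled = fill_sinks(dem, params)
    d8 = d8_route(filled)
    mask = extract_streams(d8.accumulation, params)
    dist = flow_distance_to_stream(d8.directions, mask, dem.resolution)
    bank = bank_geometry(dist, mask, params, dem.resolution)
    return StreamSet(d8=d8, stream_mask=mask, flow_distance=dist, bank=bank, params=params)


def write_ascii_grid(dem: DemGrid, path, nodata: float = -9999.0) -> None:
    """Write the raster as an ESRI ASCII grid (text)."""
    nrows, ncols = dem.z.shape
    z = np.where(dem.valid, dem.z, nodata)
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {dem.origin[0]}\n"
        f"yllcorner {dem.origin[1]}\n"
        f"cellsize {dem.resolution}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, z, fmt="%.6f")


def read_ascii_grid(path) -> DemGrid:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    meta: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
        ):
            meta[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    z = np.loadtxt(lines[n_header:])
    z = np.atleast_2d(z)
    nodata = meta.get("nodata_value", -9999.0)
    z[z == nodata] = np.nan
    return DemGrid(
        z=z,
        resolution=meta.get("cellsize", 1.0),
        origin=(meta.get("xllcorner", 0.0), meta.get("yllcorner", 0.0)),
    )
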