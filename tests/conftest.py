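import numpy as np
import pytest

from crustflux.dem import OFFSETS, DemGrid
from crustflux.hydraulics import CrustProperties
from crustflux.synthetic import DEFAULT_CLASS_PROPORTIONS, SyntheticConfig


@pytest.fixture
def crust():
    """Study-site crust properties: K=0.28 m/d, slope 0.022, porosity 0.22, d=0.29 m."""
    return CrustProperties()


@pytest.fixture
def proportions():
    return DEFAULT_CLASS_PROPORTIONS


@pytest.fixture
def small_valley():
    """8x8 DEM: a V-shaped valley draining east along the centre row."""
    rows, cols = np.mgrid[0:8, 0:8].astype(float)
    z = 10.0 - 0.5 * cols + 0.3 * np.abs(rows - 3.5)
    return DemGrid(z=z, resolution=1.0)


@pytest.fixture
def default_cfg():
    return SyntheticConfig()


# ---------------------------------------------------------------------------
# brute-force oracles for the routing operations, independent of the
# vectorised implementations: naive per-cell path walking.
# ---------------------------------------------------------------------------

def walk_path(directions, r, c):
    """Yield the cells of the D8 path starting at (r, c), inclusive."""
    nrows, ncols = directions.shape
    seen = set()
    while True:
        yield r, c
        assert (r, c) not in seen, "cycle in flow directions"
        seen.add((r, c))
        code = directions[r, c]
        if code < 0:
            return
        dr, dc = OFFSETS[code]
        r, c = r + dr, c + dc
        if not (0 <= r < nrows and 0 <= c < ncols):
            return


def brute_force_accumulation(directions, valid, resolution):
    """Accumulation by walking every cell's full path and crediting each
    visited cell with the walker's area."""
    nrows, ncols = directions.shape
    acc = np.where(valid, 0.0, np.nan)
    area = resolution**2
    for r0 in range(nrows):
        for c0 in range(ncols):
            if not valid[r0, c0]:
                continue
            for r, c in walk_path(directions, r0, c0):
                acc[r, c] += area
    return acc


def brute_force_flow_distance(directions, stream_mask, resolution):
    """Flow distance by independently walking each cell's path to the first
    stream cell, summing per-step lengths."""
    nrows, ncols = directions.shape
    dist = np.full((nrows, ncols), np.nan)
    for r0 in range(nrows):
        for c0 in range(ncols):
            if directions[r0, c0] == -2:
                continue
            total = 0.0
            found = False
            prev = None
            for r, c in walk_path(directions, r0, c0):
                if prev is not None:
                    dr, dc = r - prev[0], c - prev[1]
                    total += resolution * (2.0**0.5 if dr and dc else 1.0)
                if stream_mask[r, c]:
                    found = True
                    break
                prev = (r, c)
            dist[r0, c0] = total if found else np.inf
    return dist
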