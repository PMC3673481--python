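"""Synthetic Baltic-like seascape: grid, bathymetry, currents, clines.

The generator emulates the features of a semi-enclosed brackish basin
that drive the downstream analyses, without reproducing any real
bathymetry: an elongated basin with an irregular coastline, depth
increasing away from the shore, a non-divergent time-varying circulation
(double gyre plus a coastal boundary current, built from a streamfunction
so the discrete velocity field is exactly divergence-free), a salinity
gradient that decays monotonically with along-water distance from the
basin entrance, and a north-south temperature cline.

Grid convention: arrays are indexed ``[iy, ix]``; a *cell* is the flat
index ``iy * nx + ix``.  Positions are continuous (x, y) in km with the
origin at the lower-left corner of the grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, sparse
from scipy.sparse.csgraph import dijkstra

from .core import ENV_COLUMNS
from .dispersal import VelocityField

SHALLOW_CUTOFF_M = 12.0  # spawning/release cells are coastal, depth <= 12 m


@dataclass
class Seascape:
    """Gridded basin: land mask, depth, cell geometry, entrance reference."""

    nx: int
    ny: int
    cell_size: float  # km
    land_mask: np.ndarray  # (ny, nx) bool, True = land
    depth: np.ndarray  # (ny, nx) metres, NaN on land
    entrance_cell: int  # flat index; the basin's connection to the open sea

    def __post_init__(self) -> None:
        water = ~self.land_mask
        if not water.any():
            raise ValueError("seascape has no water cells")
        if not water.flat[self.entrance_cell]:
            raise ValueError("entrance cell is on land")
        if np.any(self.depth[water] <= 0):
            raise ValueError("depth must be positive on water cells")

    @property
    def water_mask(self) -> np.ndarray:
        return ~self.land_mask

    def cell_xy(self, cells) -> np.ndarray:
        """Cell-centre coordinates in km, shape (n, 2)."""
        cells = np.atleast_1d(cells)
        iy, ix = np.divmod(cells, self.nx)
        return np.column_stack(((ix + 0.5) * self.cell_size, (iy + 0.5) * self.cell_size))

    def cell_at(self, x, y) -> np.ndarray:
        """Flat cell index containing continuous position(s) (km)."""
        ix = np.clip((np.asarray(x) / self.cell_size).astype(int), 0, self.nx - 1)
        iy = np.clip((np.asarray(y) / self.cell_size).astype(int), 0, self.ny - 1)
        return iy * self.nx + ix

    def shallow_cells(self, cutoff: float = SHALLOW_CUTOFF_M) -> np.ndarray:
        """Flat indices of water cells with depth <= cutoff, sorted."""
        ok = self.water_mask & (np.nan_to_num(self.depth, nan=np.inf) <= cutoff)
        return np.flatnonzero(ok.ravel())


@dataclass
class SitePlacement:
    """Sampling sites on the shallow coast with their 5-cell release blocks."""

    labels: list[str]
    site_cells: np.ndarray  # flat index of each site's focal cell
    release_cells: dict[str, np.ndarray]  # label -> 5 flat indices

    def all_release_cells(self) -> np.ndarray:
        return np.concatenate([self.release_cells[l] for l in self.labels])


def _basin_mask(nx: int, ny: int, rng: np.random.Generator) -> np.ndarray:
    """Irregular elongated basin; returns land mask (True = land)."""
    y, x = np.mgrid[0:ny, 0:nx]
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    # normalized elliptical radius with low-frequency angular perturbation
    theta = np.arctan2((y - cy) / ny, (x - cx) / nx)
    wobble = np.zeros_like(theta)
    for k, amp in ((2, 0.10), (3, 0.07), (5, 0.05)):
        phase = rng.uniform(0, 2 * np.pi)
        wobble += amp * np.sin(k * theta + phase)
    r = np.sqrt(((x - cx) / (0.46 * nx)) ** 2 + ((y - cy) / (0.40 * ny)) ** 2)
    water = r < 1.0 + wobble
    # keep the largest connected water body only
    lab, nlab = ndimage.label(water)
    if nlab == 0:
        raise ValueError("degenerate basin: no water")
    sizes = ndimage.sum(water, lab, index=range(1, nlab + 1))
    water = lab == (1 + int(np.argmax(sizes)))
    return ~water


def build_seascape(
    nx: int = 60,
    ny: int = 40,
    cell_size: float = 15.0,
    seed: int = 0,
    span_days: float = 60.0,
    snapshot_hours: float = 6.0,
    max_speed: float = 0.12,
) -> tuple[Seascape, VelocityField]:
    """Generate a basin and its time-varying surface velocity field.

    The velocity field is derived from a streamfunction psi sampled at
    ``snapshot_hours`` intervals: u = d(psi)/dy, v = -d(psi)/dx with
    central differences, which makes the discrete divergence (central
    differences of u, v) identically zero.  psi is tapered to zero on
    land and on the one-cell coastal halo, so velocities vanish exactly
    on land.

    Parameters
    ----------
    nx, ny : grid dimensions (>= 8 each).
    cell_size : km per cell (default 15, giving a basin of Baltic-like extent).
    span_days : temporal extent of the stored snapshots.
    max_speed : m/s; the field is rescaled so its maximum speed is this.
    """
    if nx < 8 or ny < 8:
        raise ValueError("grid too small: need nx, ny >= 8")
    rng = np.random.default_rng(seed)
    land = _basin_mask(nx, ny, rng)

    # distance (cells) from each water cell to the nearest land cell
    dist = ndimage.distance_transform_edt(~land)
    depth = np.where(land, np.nan, 10.0 * dist - 2.0 + rng.uniform(0.0, 2.0, land.shape))
    depth = np.where(land, np.nan, np.maximum(depth, 1.0))

    # entrance: westernmost shallow water cell (mid-height preference)
    shallow = (~land) & (depth <= SHALLOW_CUTOFF_M)
    ys, xs = np.nonzero(shallow)
    order = np.lexsort((np.abs(ys - ny / 2), xs))
    entrance = int(ys[order[0]] * nx + xs[order[0]])

    sea = Seascape(nx, ny, cell_size, land, depth, entrance)

    # --- streamfunction snapshots ---
    taper = np.clip((dist - 1.0) / 3.0, 0.0, 1.0)  # 0 on land + halo
    yy, xx = np.mgrid[0:ny, 0:nx]
    xn = xx / (nx - 1)
    yn = yy / (ny - 1)
    n_snap = int(round(span_days * 24.0 / snapshot_hours)) + 1
    times = np.arange(n_snap) * snapshot_hours  # hours
    eps, period_h = 0.25, 10.0 * 24.0
    psi = np.empty((n_snap, ny, nx))
    for k, t in enumerate(times):
        a = eps * np.sin(2 * np.pi * t / period_h)
        b = 1.0 - 2.0 * a
        f = a * xn**2 + b * xn
        gyre = np.sin(np.pi * f) * np.sin(np.pi * yn)
        coast = 0.6 * np.exp(-dist / 2.5) * np.sin(np.pi * xn)
        amp = 1.0 + 0.3 * np.sin(2 * np.pi * t / (6.0 * 24.0) + 1.0)
        psi[k] = amp * (gyre + coast) * taper

    # u = dpsi/dy, v = -dpsi/dx (central differences, zero-padded edges)
    u = np.zeros_like(psi)
    v = np.zeros_like(psi)
    u[:, 1:-1, :] = (psi[:, 2:, :] - psi[:, :-2, :]) / 2.0
    v[:, :, 1:-1] = -(psi[:, :, 2:] - psi[:, :, :-2]) / 2.0
    speed = np.sqrt(u**2 + v**2).max()
    if speed > 0:
        scale = max_speed / speed
        u *= scale
        v *= scale

    field = VelocityField(u=u, v=v, times=times, cell_size=cell_size, land_mask=land)
    return sea, field


def place_sites(
    seascape: Seascape,
    n_sites: int = 15,
    seed: int = 0,
    cutoff: float = SHALLOW_CUTOFF_M,
    cells_per_site: int = 5,
) -> SitePlacement:
    """Spread ``n_sites`` sampling sites evenly along the shallow coast.

    Shallow cells are ordered by angle around the basin centroid (a proxy
    for position along the coastline path); focal cells are taken at
    evenly spaced ranks, and each site receives its ``cells_per_site``
    nearest shallow cells (including the focal cell), never reusing a
    cell across sites.
    """
    shallow = seascape.shallow_cells(cutoff)
    if len(shallow) < cells_per_site * n_sites:
        raise ValueError(
            f"only {len(shallow)} shallow cells for {n_sites} sites "
            f"x {cells_per_site} cells"
        )
    rng = np.random.default_rng(seed)
    xy = seascape.cell_xy(shallow)
    centroid = xy.mean(axis=0)
    ang = np.arctan2(xy[:, 1] - centroid[1], xy[:, 0] - centroid[0])
    order = np.argsort(ang)
    start = rng.integers(len(order))
    ranks = (start + (np.arange(n_sites) * len(order)) // n_sites) % len(order)
    focal = shallow[order[ranks]]

    labels = [f"S{i + 1:02d}" for i in range(n_sites)]
    taken: set[int] = set()
    release: dict[str, np.ndarray] = {}
    for lab, fc in zip(labels, focal):
        fxy = seascape.cell_xy(fc)[0]
        d = np.linalg.norm(xy - fxy, axis=1)
        block = []
        for j in np.argsort(d):
            c = int(shallow[j])
            if c not in taken:
                block.append(c)
                taken.add(c)
            if len(block) == cells_per_site:
                break
        if len(block) < cells_per_site:
            raise ValueError("ran out of unused shallow cells")
        release[lab] = np.array(block)
    return SitePlacement(labels, focal.astype(int), release)


def _water_graph(seascape: Seascape) -> tuple[sparse.csr_matrix, np.ndarray]:
    """8-connected graph over water cells; edge weights in km."""
    nx_, ny_ = seascape.nx, seascape.ny
    water = seascape.water_mask
    idx = -np.ones((ny_, nx_), dtype=int)
    cells = np.flatnonzero(water.ravel())
    idx.ravel()[cells] = np.arange(len(cells))
    rows, cols, w = [], [], []
    steps = [(0, 1, 1.0), (1, 0, 1.0), (1, 1, np.sqrt(2)), (1, -1, np.sqrt(2))]
    for dy, dx, wt in steps:
        src_y, src_x = np.nonzero(water)
        ny2, nx2 = src_y + dy, src_x + dx
        ok = (ny2 >= 0) & (ny2 < ny_) & (nx2 >= 0) & (nx2 < nx_)
        ok[ok] &= water[ny2[ok], nx2[ok]]
        rows.append(idx[src_y[ok], src_x[ok]])
        cols.append(idx[ny2[ok], nx2[ok]])
        w.append(np.full(ok.sum(), wt * seascape.cell_size))
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    w = np.concatenate(w)
    g = sparse.csr_matrix(
        (np.concatenate([w, w]), (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
        shape=(len(cells), len(cells)),
    )
    return g, cells


def marine_distance_matrix(seascape: Seascape, sources, targets=None) -> np.ndarray:
    """Shortest water-path distances (km) between cells.

    8-connected paths through water; diagonal steps cost sqrt(2) x
    cell_size.  Disconnected pairs get ``inf``.
    """
    graph, cells = _water_graph(seascape)
    pos = -np.ones(seascape.nx * seascape.ny, dtype=int)
    pos[cells] = np.arange(len(cells))
    sources = np.atleast_1d(sources)
    targets = sources if targets is None else np.atleast_1d(targets)
    if np.any(pos[sources] < 0) or np.any(pos[targets] < 0):
        raise ValueError("marine distance requested for a land cell")
    d = dijkstra(graph, indices=pos[sources], directed=False)
    return d[:, pos[targets]]


def marine_distance(seascape: Seascape, cell_a: int, cell_b: int) -> float:
    """Water-path distance (km) between two cells; inf if land-separated."""
    return float(marine_distance_matrix(seascape, [cell_a], [cell_b])[0, 0])


def make_environment(
    seascape: Seascape,
    placement: SitePlacement,
    salinity_range: tuple[float, float] = (30.0, 2.0),
    temperature_range: tuple[float, float] = (6.0, 1.0),
    spawning_jitter: float = 0.5,
    noise: float = 0.0,
    seed: int = 0,
    latitude_origin: float = 54.0,
) -> pd.DataFrame:
    """Per-site environmental covariates with basin-scale clines.

    Salinity decreases monotonically (linearly) with water-path distance
    from the entrance cell, from ``salinity_range[0]`` at the entrance to
    ``salinity_range[1]`` at the far end.  April temperature follows a
    south-to-north linear trend over pseudo-latitude.  Spawning-time
    values are the April values plus N(0, spawning_jitter) noise; site
    noise N(0, noise) can be added to both clines.  Fishing pressure is a
    lognormal site effect (tonnes/yr scale).
    """
    rng = np.random.default_rng(seed)
    cells = placement.site_cells
    dist = marine_distance_matrix(seascape, [seascape.entrance_cell], cells)[0]
    if not np.all(np.isfinite(dist)):
        raise ValueError("a site is not water-connected to the entrance")
    dmax = dist.max() if dist.max() > 0 else 1.0
    s_hi, s_lo = salinity_range
    sal = s_hi - (s_hi - s_lo) * dist / dmax + rng.normal(0, noise, len(cells))

    xy = seascape.cell_xy(cells)
    lat = latitude_origin + xy[:, 1] / 111.0  # km -> degrees
    t_s, t_n = temperature_range
    yspan = seascape.ny * seascape.cell_size
    temp = t_s + (t_n - t_s) * xy[:, 1] / yspan + rng.normal(0, noise, len(cells))

    env = pd.DataFrame(
        {
            "salinity_april": sal,
            "temperature_april": temp,
            "salinity_spawning": sal + rng.normal(0, spawning_jitter, len(cells)),
            "temperature_spawning": temp + rng.normal(0, spawning_jitter, len(cells)),
            "latitude": lat,
            "distance_to_entrance": dist,
            "fishing_pressure": np.exp(rng.normal(8.0, 1.0, len(cells))),
        },
        index=pd.Index(placement.labels, name="site"),
    )
    return env[list(ENV_COLUMNS)]
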