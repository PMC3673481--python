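"""Lagrangian particle advection on gridded 2-D velocity fields.

Larval drift is modelled as passive transport of particles in the
surface layer: velocities are sampled on the cell grid at regular time
snapshots, interpolated bilinearly in space and linearly in time, and
integrated with fixed-step RK4.  A step that lands on a land cell is
reflected specularly off the coastline once (if still on land the
particle stays put for that step); a particle leaving the open domain
boundary is flagged LOST.

Units: positions are km (origin at the grid's lower-left corner), time
is hours, stored velocities are m/s (converted to km/h internally).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

M_PER_S_TO_KM_PER_H = 3.6


@dataclass
class VelocityField:
    """Velocity snapshots on the cell grid.

    ``u`` (eastward) and ``v`` (northward) have shape ``(nt, ny, nx)`` in
    m/s, evaluated at cell centres; ``times`` are the snapshot times in
    hours and must be evenly spaced; ``land_mask`` is True on land, where
    velocities are zero.
    """

    u: np.ndarray
    v: np.ndarray
    times: np.ndarray
    cell_size: float  # km
    land_mask: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.u.shape != self.v.shape or self.u.shape[0] != len(self.times):
            raise ValueError("u/v/times shapes inconsistent")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if not np.allclose(dt, dt[0]):
                raise ValueError("snapshot times must be evenly spaced")
        water = ~self.land_mask
        if not np.all(np.isfinite(self.u[:, water])) or not np.all(
            np.isfinite(self.v[:, water])
        ):
            raise ValueError("non-finite velocities on water cells")

    @property
    def ny(self) -> int:
        return self.u.shape[1]

    @property
    def nx(self) -> int:
        return self.u.shape[2]

    @property
    def t_span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])


def _interp_snapshot(comp: np.ndarray, gx: np.ndarray, gy: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of one (ny, nx) snapshot at grid coords.

    ``gx``/``gy`` are in node units (node j at cell centre j); values are
    clamped to the node hull, i.e. constant extrapolation within the
    outer half-cell ring.
    """
    ny, nx = comp.shape
    gx = np.clip(gx, 0.0, nx - 1.0)
    gy = np.clip(gy, 0.0, ny - 1.0)
    i0 = np.minimum(gx.astype(int), nx - 2)
    j0 = np.minimum(gy.astype(int), ny - 2)
    fx = gx - i0
    fy = gy - j0
    c00 = comp[j0, i0]
    c10 = comp[j0, i0 + 1]
    c01 = comp[j0 + 1, i0]
    c11 = comp[j0 + 1, i0 + 1]
    return (
        c00 * (1 - fx) * (1 - fy)
        + c10 * fx * (1 - fy)
        + c01 * (1 - fx) * fy
        + c11 * fx * fy
    )


def velocity_at(field: VelocityField, x, y, t: float) -> tuple[np.ndarray, np.ndarray]:
    """Interpolated velocity (m/s) at position(s) (km) and time t (hours).

    Bilinear in space between cell-centre nodes, linear in time between
    snapshots; reproduces stored values exactly at nodes and snapshots.
    """
    t0, t1 = field.t_span
    if t < t0 - 1e-9 or t > t1 + 1e-9:
        raise ValueError(f"time {t} outside field span [{t0}, {t1}]")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    gx = x / field.cell_size - 0.5
    gy = y / field.cell_size - 0.5
    nt = len(field.times)
    if nt == 1:
        k0 = k1 = 0
        w = 0.0
    else:
        step = field.times[1] - field.times[0]
        frac = np.clip((t - field.times[0]) / step, 0.0, nt - 1.0)
        k0 = min(int(frac), nt - 2)
        k1 = k0 + 1
        w = frac - k0
    u = (1 - w) * _interp_snapshot(field.u[k0], gx, gy)
    v = (1 - w) * _interp_snapshot(field.v[k0], gx, gy)
    if w > 0:
        u = u + w * _interp_snapshot(field.u[k1], gx, gy)
        v = v + w * _interp_snapshot(field.v[k1], gx, gy)
    return u, v


def _on_land(field: VelocityField, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    ix = np.clip((x / field.cell_size).astype(int), 0, field.nx - 1)
    iy = np.clip((y / field.cell_size).astype(int), 0, field.ny - 1)
    return field.land_mask[iy, ix]


def advect_many(
    field: VelocityField,
    starts: np.ndarray,
    t0: float,
    duration_days: float,
    dt_hours: float,
) -> tuple[np.ndarray, np.ndarray]:
    """RK4-advect many particles sharing a release time.

    Returns ``(end_positions, lost)``: positions in km (frozen at the
    point of loss for LOST particles) and a boolean LOST flag set when a
    particle crosses the open domain boundary.
    """
    if dt_hours <= 0:
        raise ValueError("dt must be positive")
    n_steps_f = duration_days * 24.0 / dt_hours
    n_steps = int(round(n_steps_f))
    if abs(n_steps_f - n_steps) > 1e-9:
        raise ValueError("duration must be an integer number of dt steps")
    t_end = t0 + duration_days * 24.0
    lo, hi = field.t_span
    if t0 < lo - 1e-9 or t_end > hi + 1e-9:
        raise ValueError("trajectory window outside velocity field span")

    cs = field.cell_size
    xmax, ymax = field.nx * cs, field.ny * cs
    pos = np.array(starts, dtype=float, copy=True)
    if pos.ndim == 1:
        pos = pos[None, :]
    lost = np.zeros(len(pos), dtype=bool)
    active = ~lost

    def vel(px, py, t):
        u, v = velocity_at(field, px, py, t)
        return u * M_PER_S_TO_KM_PER_H, v * M_PER_S_TO_KM_PER_H

    for s in range(n_steps):
        if not active.any():
            break
        t = t0 + s * dt_hours
        px, py = pos[active, 0], pos[active, 1]
        k1x, k1y = vel(px, py, t)
        k2x, k2y = vel(px + 0.5 * dt_hours * k1x, py + 0.5 * dt_hours * k1y, t + 0.5 * dt_hours)
        k3x, k3y = vel(px + 0.5 * dt_hours * k2x, py + 0.5 * dt_hours * k2y, t + 0.5 * dt_hours)
        k4x, k4y = vel(px + dt_hours * k3x, py + dt_hours * k3y, t + dt_hours)
        nxp = px + dt_hours / 6.0 * (k1x + 2 * k2x + 2 * k3x + k4x)
        nyp = py + dt_hours / 6.0 * (k1y + 2 * k2y + 2 * k3y + k4y)

        # open-boundary loss
        out = (nxp < 0) | (nxp > xmax) | (nyp < 0) | (nyp > ymax)
        # coastline reflection: mirror the position across the boundary of
        # the cell it came from, once, in each axis whose cell index changed
        land = np.zeros_like(out)
        inb = ~out
        land[inb] = _on_land(field, nxp[inb], nyp[inb])
        if land.any():
            li = np.flatnonzero(land)
            ox, oy = px[li], py[li]
            rx, ry = nxp[li].copy(), nyp[li].copy()
            old_ix = (ox / cs).astype(int)
            old_iy = (oy / cs).astype(int)
            new_ix = np.clip((rx / cs).astype(int), 0, field.nx - 1)
            new_iy = np.clip((ry / cs).astype(int), 0, field.ny - 1)
            cross_x = new_ix != old_ix
            bx = np.where(new_ix > old_ix, (old_ix + 1) * cs, old_ix * cs)
            rx[cross_x] = 2 * bx[cross_x] - rx[cross_x]
            cross_y = new_iy != old_iy
            by = np.where(new_iy > old_iy, (old_iy + 1) * cs, old_iy * cs)
            ry[cross_y] = 2 * by[cross_y] - ry[cross_y]
            still = (
                (rx < 0) | (rx > xmax) | (ry < 0) | (ry > ymax)
                | _on_land(field, np.clip(rx, 0, xmax), np.clip(ry, 0, ymax))
            )
            rx[still] = ox[still]
            ry[still] = oy[still]
            nxp[li] = rx
            nyp[li] = ry

        pos[np.flatnonzero(active)[~out], 0] = nxp[~out]
        pos[np.flatnonzero(active)[~out], 1] = nyp[~out]
        newly_lost = np.flatnonzero(active)[out]
        lost[newly_lost] = True
        active = ~lost
    return pos, lost


def advect(
    field: VelocityField,
    start: tuple[float, float],
    t0: float,
    duration_days: float,
    dt_hours: float,
) -> tuple[tuple[float, float] | None, bool]:
    """Advect a single particle; returns (end position or None, lost)."""
    pos, lost = advect_many(field, np.array([start]), t0, duration_days, dt_hours)
    if lost[0]:
        return None, True
    return (float(pos[0, 0]), float(pos[0, 1])), False


@dataclass
class ReleaseScheme:
    """Release design: particles per cell per event, events per year, years.

    Defaults mirror a multi-year spring-spawning design: 140 particles
    per cell per event, 25 events per year evenly spaced in a spring
    window (days 90-165), for 25 years, each trajectory lasting 21 days.
    """

    particles_per_cell: int = 140
    releases_per_year: int = 25
    n_years: int = 25
    duration_days: float = 21.0
    dt_hours: float = 1.0
    spring_window: tuple[float, float] = (90.0, 165.0)
    year_length_days: float = 365.0

    def __post_init__(self) -> None:
        if min(self.particles_per_cell, self.releases_per_year, self.n_years) < 1:
            raise ValueError("all counts must be >= 1")
        if (self.duration_days * 24.0) % self.dt_hours:
            raise ValueError("duration x 24 must be divisible by dt")

    @property
    def trajectories_per_cell(self) -> int:
        return self.particles_per_cell * self.releases_per_year * self.n_years

    def total_trajectories(self, n_cells: int) -> int:
        return self.trajectories_per_cell * n_cells

    def release_times(self) -> np.ndarray:
        """Release times in hours, evenly spaced in each year's window."""
        d0, d1 = self.spring_window
        if self.releases_per_year == 1:
            within = np.array([d0])
        else:
            within = np.linspace(d0, d1, self.releases_per_year)
        years = np.arange(self.n_years) * self.year_length_days
        return ((years[:, None] + within[None, :]).ravel()) * 24.0


@dataclass
class TrajectorySet:
    """End states of released particles.

    ``end_cell`` is the flat grid index of the final cell, or -1 for
    particles flagged LOST at the open boundary.
    """

    start_cell: np.ndarray
    start_time: np.ndarray
    end_x: np.ndarray
    end_y: np.ndarray
    end_cell: np.ndarray

    @property
    def n(self) -> int:
        return len(self.start_cell)

    @property
    def lost_fraction(self) -> float:
        return float(np.mean(self.end_cell < 0))


def run_releases(
    field: VelocityField,
    seascape,
    scheme: ReleaseScheme,
    release_cells: np.ndarray,
    seed: int = 0,
) -> TrajectorySet:
    """Run the full release design over a set of cells.

    For every release cell x release time, ``particles_per_cell``
    particles start at uniform-random positions within the cell and are
    advected for the scheme's duration.  All release windows must lie
    within the velocity field's stored span.
    """
    release_cells = np.asarray(release_cells, dtype=int)
    if len(release_cells) == 0:
        raise ValueError("no release cells")
    rng = np.random.default_rng(seed)
    cs = seascape.cell_size
    iy, ix = np.divmod(release_cells, seascape.nx)
    ppc = scheme.particles_per_cell

    starts_c, times_c, ends_x, ends_y, cells_c = [], [], [], [], []
    for t0 in scheme.release_times():
        ox = (ix[:, None] + rng.random((len(release_cells), ppc))) * cs
        oy = (iy[:, None] + rng.random((len(release_cells), ppc))) * cs
        starts = np.column_stack([ox.ravel(), oy.ravel()])
        pos, lost = advect_many(field, starts, t0, scheme.duration_days, scheme.dt_hours)
        end_cell = seascape.cell_at(pos[:, 0], pos[:, 1]).astype(int)
        end_cell[lost] = -1
        starts_c.append(np.repeat(release_cells, ppc))
        times_c.append(np.full(len(starts), t0))
        ends_x.append(pos[:, 0])
        ends_y.append(pos[:, 1])
        cells_c.append(end_cell)
    return TrajectorySet(
        start_cell=np.concatenate(starts_c),
        start_time=np.concatenate(times_c),
        end_x=np.concatenate(ends_x),
        end_y=np.concatenate(ends_y),
        end_cell=np.concatenate(cells_c),
    )
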