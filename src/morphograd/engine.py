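"""Brownian transport engine: secretion, diffusion, capture, turnover.

Ligand positions evolve by ``r(t + h) = r(t) + Gamma(t)`` with independent
zero-mean Gaussian increments whose total second moment is ``c*D*h``
(``c = 2*dim``), i.e. per-axis variance ``2*D*h``. A displacement is traced
as a segment against the geometry's surfaces: contact with a
receptor-bearing membrane triggers a Bernoulli binding trial with success
probability ``P_binding * R_unbound`` of that membrane's pool; any other
surface (or a failed trial) reflects specularly and the remainder of the
displacement continues. Bound pairs dissolve exactly ``T_t`` after binding
and, depending on the turnover variant, the ligand is re-secreted by its
originating ExE cell, cleared, or supplemented by a constant influx.

Randomness: each replicate uses one ``numpy.random.Generator`` seeded with
``config.seed + replicate``; seeding draws come first, then per-step
per-ligand displacement draws followed by binding trials in contact order,
so runs are bit-for-bit reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernel
from ._kernel import EPS, FREE, BOUND, UNSPAWNED
from .config import SimulationConfig, ConfigError
from .geometry import EmbryoGeometry, build_geometry

__all__ = [
    "brownian_step",
    "seed_ligands",
    "move_with_collisions",
    "Replicate",
    "SimResult",
    "run",
    "BounceCapError",
]

_VARIANT_CODES = {"constant_total": 0, "decreasing": 1, "increasing": 2}


class BounceCapError(RuntimeError):
    """A displacement needed more than the hard cap of 32 reflections."""


# ----------------------------------------------------------------------
# geometry compilation
# ----------------------------------------------------------------------
@dataclass
class EngineArrays:
    """Flat-array view of a geometry consumed by the numba kernel."""

    surf_orient: np.ndarray
    surf_c: np.ndarray
    surf_lo1: np.ndarray
    surf_hi1: np.ndarray
    surf_lo2: np.ndarray
    surf_hi2: np.ndarray
    surf_kind: np.ndarray
    surf_pool: np.ndarray
    surf_xlo: np.ndarray
    surf_xhi: np.ndarray
    surf_ylo: np.ndarray
    surf_yhi: np.ndarray
    surf_zlo: np.ndarray
    surf_zhi: np.ndarray
    bucket_ptr: np.ndarray
    bucket_idx: np.ndarray
    bucket_w: float
    n_buckets: int
    pool_total: np.ndarray
    x_min: float
    x_max: float
    y_top: float
    basal_y: float
    apical_y: float
    z_period: float
    qz_lo: float
    qz_hi: float
    sec_x_lo: np.ndarray
    sec_x_hi: np.ndarray
    sec_z_lo: np.ndarray
    sec_z_hi: np.ndarray
    exe_cells: np.ndarray
    width: float


def compile_geometry(geom: EmbryoGeometry) -> EngineArrays:
    """Flatten a geometry into kernel arrays (cached on the geometry)."""
    cached = getattr(geom, "_engine_arrays", None)
    if cached is not None:
        return cached

    surfaces = geom.surfaces
    n_s = len(surfaces)
    orient = np.empty(n_s, dtype=np.int8)
    c = np.empty(n_s, dtype=np.float64)
    lo1 = np.empty(n_s, dtype=np.float64)
    hi1 = np.empty(n_s, dtype=np.float64)
    lo2 = np.empty(n_s, dtype=np.float64)
    hi2 = np.empty(n_s, dtype=np.float64)
    kind = np.empty(n_s, dtype=np.int8)
    pool = np.empty(n_s, dtype=np.int64)
    for i, s in enumerate(surfaces):
        orient[i] = s.orient
        c[i] = s.c
        lo1[i], hi1[i] = s.lo1, s.hi1
        lo2[i], hi2[i] = s.lo2, s.hi2
        kind[i] = 1 if s.pool >= 0 else 0
        pool[i] = s.pool

    # per-surface bounding boxes (degenerate along the normal axis)
    xlo = np.empty(n_s)
    xhi = np.empty(n_s)
    ylo = np.empty(n_s)
    yhi = np.empty(n_s)
    zlo = np.empty(n_s)
    zhi = np.empty(n_s)
    for i, s in enumerate(surfaces):
        if s.orient == 0:
            xlo[i] = xhi[i] = s.c
            ylo[i], yhi[i] = s.lo1, s.hi1
            zlo[i], zhi[i] = s.lo2, s.hi2
        elif s.orient == 1:
            xlo[i], xhi[i] = s.lo1, s.hi1
            ylo[i] = yhi[i] = s.c
            zlo[i], zhi[i] = s.lo2, s.hi2
        else:
            xlo[i], xhi[i] = s.lo1, s.hi1
            ylo[i], yhi[i] = s.lo2, s.hi2
            zlo[i] = zhi[i] = s.c

    bucket_w = max(geom.config.pitch, 1.0)
    n_buckets = max(1, int(math.ceil(geom.width / bucket_w)))
    members: list[list[int]] = [[] for _ in range(n_buckets)]
    for i, s in enumerate(surfaces):
        x_lo, x_hi = s.x_extent()
        b0 = max(0, int((x_lo - 1e-9) / bucket_w))
        b1 = min(n_buckets - 1, int((x_hi + 1e-9) / bucket_w))
        for b in range(b0, b1 + 1):
            members[b].append(i)
    ptr = np.zeros(n_buckets + 1, dtype=np.int64)
    for b in range(n_buckets):
        ptr[b + 1] = ptr[b] + len(members[b])
    idx = np.empty(ptr[-1], dtype=np.int64)
    k = 0
    for b in range(n_buckets):
        for i in members[b]:
            idx[k] = i
            k += 1

    n_cells = len(geom.cells)
    sec_x_lo = np.zeros(max(n_cells, 1), dtype=np.float64)
    sec_x_hi = np.zeros(max(n_cells, 1), dtype=np.float64)
    sec_z_lo = np.zeros(max(n_cells, 1), dtype=np.float64)
    sec_z_hi = np.ones(max(n_cells, 1), dtype=np.float64)
    exe_cells = []
    for cell in geom.cells:
        sec_x_lo[cell.index] = cell.x_lo
        sec_x_hi[cell.index] = cell.x_hi
        sec_z_lo[cell.index] = cell.z_lo
        sec_z_hi[cell.index] = cell.z_hi
        if cell.tissue == "exe":
            exe_cells.append(cell.index)

    if geom.dim == 2:
        qz_lo, qz_hi = -1e300, 1e300
        z_period = 0.0
    elif geom.periodic_z:
        qz_lo, qz_hi = 0.0, geom.depth
        z_period = geom.depth
    else:
        qz_lo, qz_hi = 0.0, geom.depth
        z_period = 0.0

    arrays = EngineArrays(
        surf_orient=orient, surf_c=c, surf_lo1=lo1, surf_hi1=hi1,
        surf_lo2=lo2, surf_hi2=hi2, surf_kind=kind, surf_pool=pool,
        surf_xlo=xlo, surf_xhi=xhi, surf_ylo=ylo, surf_yhi=yhi,
        surf_zlo=zlo, surf_zhi=zhi,
        bucket_ptr=ptr, bucket_idx=idx, bucket_w=float(bucket_w),
        n_buckets=n_buckets,
        pool_total=geom.pool_total.astype(np.int64),
        x_min=0.0, x_max=geom.width, y_top=geom.height,
        basal_y=geom.basal_y, apical_y=geom.apical_y,
        z_period=z_period, qz_lo=qz_lo, qz_hi=qz_hi,
        sec_x_lo=sec_x_lo, sec_x_hi=sec_x_hi,
        sec_z_lo=sec_z_lo, sec_z_hi=sec_z_hi,
        exe_cells=np.asarray(exe_cells, dtype=np.int64),
        width=geom.width)
    geom._engine_arrays = arrays
    return arrays


# ----------------------------------------------------------------------
# elementary operations (also exposed for direct testing)
# ----------------------------------------------------------------------
def brownian_step(rng: np.random.Generator, dim: int, D: float, h: float,
                  n: int | None = None) -> np.ndarray:
    """Draw Brownian displacement vector(s) Gamma.

    Components are i.i.d. Gaussian with zero mean and per-axis variance
    ``c*D*h / dim`` where ``c = 2*dim``, so the total second moment is
    ``c*D*h``.
    """
    if D <= 0 or h <= 0 or dim not in (2, 3):
        raise ValueError("D and h must be positive and dim must be 2 or 3")
    c = 2 * dim
    sigma = math.sqrt(c * D * h / dim)
    if n is None:
        return rng.normal(0.0, sigma, size=dim)
    return rng.normal(0.0, sigma, size=(n, dim))


def seed_ligands(geom: EmbryoGeometry, mode: str, n: int,
                 rng: np.random.Generator):
    """Place ``n`` fresh ligands according to the secretion mode.

    Returns ``(pos, t_entered, in_cavity, origin_cell)`` where ``pos`` is
    ``(n, 3)`` (z = 0 in 2D). Apical/basolateral modes draw a uniformly
    chosen ExE cell per ligand and a uniform position on its apical/basal
    face, offset EPS into the adjacent compartment; ``uniform_cavity``
    scatters uniformly over the cavity. Basolateral seeding stamps the
    interstitial-entry time at 0.
    """
    if n < 1:
        raise ValueError("at least one ligand must be seeded")
    exe = geom.exe_cells()
    pos = np.zeros((n, 3), dtype=np.float64)
    t_entered = np.full(n, -1.0)
    in_cavity = np.ones(n, dtype=np.int8)
    origin = np.full(n, -1, dtype=np.int64)
    if mode in ("apical", "basolateral"):
        if not exe:
            raise ConfigError(
                f"secretion_mode={mode!r} requires ExE cells (exe_present=on)")
        pick = rng.integers(0, len(exe), size=n)
        x_lo = np.array([c.x_lo for c in exe])
        x_hi = np.array([c.x_hi for c in exe])
        z_lo = np.array([c.z_lo for c in exe])
        z_hi = np.array([c.z_hi for c in exe])
        pos[:, 0] = x_lo[pick] + (x_hi[pick] - x_lo[pick]) * rng.random(n)
        if geom.dim == 3:
            pos[:, 2] = z_lo[pick] + (z_hi[pick] - z_lo[pick]) * rng.random(n)
        origin[:] = np.array([c.index for c in exe])[pick]
        if mode == "apical":
            pos[:, 1] = geom.apical_y + EPS
        else:
            pos[:, 1] = geom.basal_y - EPS
            t_entered[:] = 0.0
            in_cavity[:] = 0
    elif mode == "uniform_cavity":
        pos[:, 0] = EPS + (geom.width - 2 * EPS) * rng.random(n)
        pos[:, 1] = geom.apical_y + EPS + \
            (geom.height - geom.apical_y - 2 * EPS) * rng.random(n)
        if geom.dim == 3:
            pos[:, 2] = geom.depth * rng.random(n)
    else:
        raise ConfigError(f"unknown secretion mode {mode!r}")
    return pos, t_entered, in_cavity, origin


def move_with_collisions(geom: EmbryoGeometry, position, displacement,
                         rng: np.random.Generator | None = None,
                         pool_bound: np.ndarray | None = None,
                         P_binding: float = 0.0):
    """Trace one ligand displacement through the geometry (single step).

    Returns ``(outcome, new_position, pool)`` with outcome "free" or
    "bound". ``pool_bound`` (mutable int64 array) holds current per-pool
    bound counts; omitted means all receptors unbound.
    """
    arr = compile_geometry(geom)
    if rng is None:
        rng = np.random.default_rng(0)
    if pool_bound is None:
        pool_bound = np.zeros_like(arr.pool_total)
    p = np.zeros(3)
    p[:len(position)] = position
    d = np.zeros(3)
    d[:len(displacement)] = displacement
    surfs = (arr.surf_orient, arr.surf_c, arr.surf_lo1, arr.surf_hi1,
             arr.surf_lo2, arr.surf_hi2, arr.surf_kind, arr.surf_pool,
             arr.surf_xlo, arr.surf_xhi, arr.surf_ylo, arr.surf_yhi,
             arr.surf_zlo, arr.surf_zhi)
    buckets = (arr.bucket_ptr, arr.bucket_idx, arr.bucket_w, arr.n_buckets)
    bounds = (arr.x_min, arr.x_max, arr.y_top, arr.basal_y, arr.apical_y,
              arr.z_period, arr.qz_lo, arr.qz_hi)
    pool_total = arr.pool_total if len(arr.pool_total) else np.ones(1, dtype=np.int64)
    if len(pool_bound) == 0:
        pool_bound = np.zeros(1, dtype=np.int64)
    outcome, x, y, z, pid = _kernel.advance_ligand(
        p[0], p[1], p[2], d[0], d[1], d[2], geom.dim,
        surfs, buckets, pool_bound, pool_total, P_binding, bounds, rng)
    if outcome < 0:
        raise BounceCapError(f"bounce cap exceeded at {position}")
    new = np.array([x, y, z])[:geom.dim]
    if outcome == 1:
        pool_bound[pid] += 1
        return "bound", new, int(pid)
    return "free", new, -1


# ----------------------------------------------------------------------
# full runs
# ----------------------------------------------------------------------
@dataclass
class Replicate:
    """Snapshots and event log of one replicate."""

    seed: int
    times: np.ndarray            # (n_snap,) s
    positions: np.ndarray        # (n_snap, n_slots, 3) um
    status: np.ndarray           # (n_snap, n_slots) int8
    pool_bound: np.ndarray       # (n_snap, n_pools) int64
    n_active: np.ndarray         # (n_snap,) int64
    events: pd.DataFrame         # t, event, ligand_id, pool_id, cell_id, d_edge, T_L

    def free_positions(self, snap: int, dim: int) -> np.ndarray:
        m = self.status[snap] == FREE
        return self.positions[snap, m, :dim]


@dataclass
class SimResult:
    """Outcome of ``run``: one :class:`Replicate` per seed."""

    config: SimulationConfig
    geometry: EmbryoGeometry
    replicates: list[Replicate]

    @property
    def times(self) -> np.ndarray:
        return self.replicates[0].times

    def snapshot_index(self, at_time: float) -> int:
        times = self.times
        hits = np.nonzero(np.isclose(times, at_time, rtol=0, atol=1e-6))[0]
        if len(hits) == 0:
            raise KeyError(
                f"no snapshot at t={at_time}; available times: {times.tolist()}")
        return int(hits[0])

    def events(self) -> pd.DataFrame:
        frames = []
        for r, rep in enumerate(self.replicates):
            df = rep.events.copy()
            df.insert(0, "replicate", r)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def _events_frame(geom: EmbryoGeometry, ev_t, ev_kind, ev_lig, ev_pool, ev_tl,
                  n_ev: int) -> pd.DataFrame:
    pool_cell = geom.pool_cell
    cell_id = np.full(n_ev, -1, dtype=np.int64)
    d_edge = np.full(n_ev, np.nan)
    pools = ev_pool[:n_ev]
    valid = pools >= 0
    if valid.any() and len(pool_cell):
        cell_id[valid] = pool_cell[pools[valid]]
        d_lookup = np.array([
            geom.d_edge_of_cell(c.index) if c.tissue == "epiblast" else -1
            for c in geom.cells], dtype=float)
        d_edge[valid] = d_lookup[cell_id[valid]]
    return pd.DataFrame({
        "t": ev_t[:n_ev],
        "event": pd.Categorical.from_codes(
            ev_kind[:n_ev].astype(int), categories=["bind", "unbind", "cross"]),
        "ligand_id": ev_lig[:n_ev],
        "pool_id": pools,
        "cell_id": cell_id,
        "d_edge": d_edge,
        "T_L": ev_tl[:n_ev],
    })


def run(config: SimulationConfig,
        geometry: EmbryoGeometry | None = None,
        snapshot_times=None,
        initial_positions: np.ndarray | None = None,
        n_replicates: int | None = None) -> SimResult:
    """Run ``n_replicates`` independent replicates of a configuration.

    Replicate ``r`` uses seed ``config.seed + r``; identical (config, seed)
    pairs give bitwise-identical trajectories and event logs. Snapshots are
    taken at ``snapshot_times`` (default: every ``snapshot_interval``
    through ``duration``). ``geometry`` may be a prebuilt/custom geometry
    (e.g. an open box); ``initial_positions`` overrides secretion seeding.
    """
    geom = geometry if geometry is not None else build_geometry(config)
    arr = compile_geometry(geom)
    h = config.h
    n_steps = int(round(config.duration / h))
    if snapshot_times is None:
        snapshot_times = np.arange(config.snapshot_interval,
                                   config.duration + config.snapshot_interval / 2,
                                   config.snapshot_interval)
    snapshot_times = np.asarray(snapshot_times, dtype=float)
    snap_steps = np.round(snapshot_times / h).astype(np.int64)
    if np.any(snap_steps < 1) or np.any(snap_steps > n_steps):
        raise ValueError("snapshot times must lie in (0, duration]")
    if np.any(np.diff(snap_steps) <= 0):
        raise ValueError("snapshot times must be strictly increasing")

    variant = _VARIANT_CODES[config.turnover_variant]
    influx_rate = config.n_ligands / config.T_t if variant == 2 else 0.0
    n_extra = int(math.ceil(influx_rate * config.duration)) + 8 if variant == 2 else 0
    n_cap = config.n_ligands + n_extra

    episodes = config.n_ligands * (int(config.duration // config.T_t) + 2) + n_extra * 2
    ev_cap = 3 * episodes + n_cap + 64

    sigma = math.sqrt(config.c * config.D * h / config.dim)
    sec_apical = 1 if config.secretion_mode == "apical" else 0
    resec_uniform = 1 if (config.secretion_mode == "uniform_cavity"
                          or not geom.exe_cells()) else 0

    reps = n_replicates if n_replicates is not None else config.n_replicates
    out: list[Replicate] = []
    for r in range(reps):
        seed = config.seed + r
        rng = np.random.default_rng(seed)
        if initial_positions is not None:
            p0 = np.asarray(initial_positions, dtype=np.float64)
            if p0.shape[0] != config.n_ligands:
                raise ValueError("initial_positions must have n_ligands rows")
            pos0 = np.zeros((config.n_ligands, 3))
            pos0[:, :p0.shape[1]] = p0
            t_ent0 = np.full(config.n_ligands, -1.0)
            in_cav0 = (pos0[:, 1] >= geom.apical_y).astype(np.int8)
            origin0 = np.full(config.n_ligands, -1, dtype=np.int64)
        else:
            pos0, t_ent0, in_cav0, origin0 = seed_ligands(
                geom, config.secretion_mode, config.n_ligands, rng)

        pos = np.zeros((n_cap, 3), dtype=np.float64)
        pos[:config.n_ligands] = pos0
        status = np.full(n_cap, UNSPAWNED, dtype=np.int8)
        status[:config.n_ligands] = FREE
        bound_pool = np.full(n_cap, -1, dtype=np.int64)
        t_bound = np.full(n_cap, -1.0)
        t_entered = np.full(n_cap, -1.0)
        t_entered[:config.n_ligands] = t_ent0
        origin = np.full(n_cap, -1, dtype=np.int64)
        origin[:config.n_ligands] = origin0
        in_cav = np.zeros(n_cap, dtype=np.int8)
        in_cav[:config.n_ligands] = in_cav0

        n_pools = max(len(arr.pool_total), 1)
        pool_total = arr.pool_total if len(arr.pool_total) else np.ones(1, dtype=np.int64)
        pool_bound = np.zeros(n_pools, dtype=np.int64)

        n_snap = len(snap_steps)
        snap_pos = np.zeros((n_snap, n_cap, 3), dtype=np.float64)
        snap_status = np.zeros((n_snap, n_cap), dtype=np.int8)
        snap_pool = np.zeros((n_snap, n_pools), dtype=np.int64)
        snap_active = np.zeros(n_snap, dtype=np.int64)
        ev_t = np.zeros(ev_cap)
        ev_kind = np.zeros(ev_cap, dtype=np.int8)
        ev_lig = np.zeros(ev_cap, dtype=np.int64)
        ev_pool = np.zeros(ev_cap, dtype=np.int64)
        ev_tl = np.zeros(ev_cap)

        err, n_ev, bad = _kernel.run_kernel(
            geom.dim, n_steps, h, sigma, config.P_binding, config.T_t,
            variant, influx_rate,
            pos, status, bound_pool, t_bound, t_entered, origin,
            arr.surf_orient, arr.surf_c, arr.surf_lo1, arr.surf_hi1,
            arr.surf_lo2, arr.surf_hi2, arr.surf_kind, arr.surf_pool,
            arr.surf_xlo, arr.surf_xhi, arr.surf_ylo, arr.surf_yhi,
            arr.surf_zlo, arr.surf_zhi,
            arr.bucket_ptr, arr.bucket_idx, arr.bucket_w, arr.n_buckets,
            pool_bound, pool_total,
            arr.x_min, arr.x_max, arr.y_top, arr.basal_y, arr.apical_y,
            arr.z_period, arr.qz_lo, arr.qz_hi,
            arr.sec_x_lo, arr.sec_x_hi, arr.sec_z_lo, arr.sec_z_hi,
            sec_apical, resec_uniform, arr.exe_cells, arr.width,
            snap_steps,
            snap_pos, snap_status, snap_pool, snap_active,
            ev_t, ev_kind, ev_lig, ev_pool, ev_tl,
            rng)
        if err == _kernel.ERR_BOUNCE:
            raise BounceCapError(
                f"replicate {r}: bounce cap exceeded for ligand {bad}")
        if err == _kernel.ERR_CONSERVATION:
            raise AssertionError(
                f"replicate {r}: ligand/receptor conservation violated in-engine")
        if err == _kernel.ERR_EVENT_OVERFLOW:
            raise RuntimeError(f"replicate {r}: event log capacity exceeded")

        out.append(Replicate(
            seed=seed, times=snapshot_times.copy(),
            positions=snap_pos, status=snap_status,
            pool_bound=snap_pool, n_active=snap_active,
            events=_events_frame(geom, ev_t, ev_kind, ev_lig, ev_pool,
                                 ev_tl, n_ev)))
    return SimResult(config=config, geometry=geom, replicates=out)
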