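"""Numba integration kernel for the Brownian transport engine.

All geometry is flattened into parallel arrays of axis-aligned surfaces
(plane normal axis, plane coordinate, tangent extents, kind, receptor-pool
id). Ligand displacements are traced exactly: the step segment is tested
against every candidate surface (bucketed along x), the earliest hit is
resolved (binding trial on membranes, specular reflection otherwise,
periodic wrap on the open z faces), and the remaining displacement
continues until exhausted. Positions are nudged ``EPS`` off a surface after
every reflection so that subsequent steps never start exactly on a plane.

Status codes: 0 free, 1 bound, 2 retired (decreasing variant),
3 unspawned slot (increasing variant). Event kinds: 0 bind, 1 unbind
(turnover release), 2 first entry into the interstitial slab (y below the
cell-band floor) of a free episode - transit through the channel mouth or
a lateral gap alone does not start the capture clock.
"""

import numpy as np
from numba import njit

FREE, BOUND, RETIRED, UNSPAWNED = 0, 1, 2, 3
EV_BIND, EV_UNBIND, EV_CROSS = 0, 1, 2
EPS = 1e-6           # off-surface placement after reflection/binding
MAX_BOUNCES = 32     # hard cap on collisions resolved within one step

ERR_OK = 0
ERR_BOUNCE = 1
ERR_EVENT_OVERFLOW = 2
ERR_CONSERVATION = 3


@njit(cache=True)
def advance_ligand(px, py, pz, dx, dy, dz, dim,
                   surfs, buckets, pool_bound, pool_total, p_binding,
                   bounds, rng):
    """Move one free ligand by (dx, dy, dz) with collisions.

    Returns (outcome, x, y, z, pool): outcome 0 = still free, 1 = bound to
    ``pool``, -1 = bounce cap exceeded.
    """
    (surf_orient, surf_c, surf_lo1, surf_hi1, surf_lo2, surf_hi2,
     surf_kind, surf_pool, surf_xlo, surf_xhi, surf_ylo, surf_yhi,
     surf_zlo, surf_zhi) = surfs
    bucket_ptr, bucket_idx, bucket_w, n_buckets = buckets
    x_min, x_max, y_top, basal_y, apical_y, z_period, qz_lo, qz_hi = bounds
    for _ in range(MAX_BOUNCES):
        if abs(dx) + abs(dy) + abs(dz) < 1e-15:
            return 0, px, py, pz, -1
        nx = px + dx
        ny = py + dy
        nz = pz + dz
        lox = px if px < nx else nx
        hix = nx if px < nx else px
        loy = py if py < ny else ny
        hiy = ny if py < ny else py
        loz = pz if pz < nz else nz
        hiz = nz if pz < nz else pz
        # fast paths: the whole sub-step stays strictly inside an interior
        # band that contains no surfaces (cavity or interstitial space)
        if loz > qz_lo and hiz < qz_hi and lox > x_min and hix < x_max:
            if loy > apical_y and hiy < y_top:
                return 0, nx, ny, nz, -1
            if basal_y > 0.0 and loy > 0.0 and hiy < basal_y:
                return 0, nx, ny, nz, -1

        best_t = 2.0
        best_s = -1
        # periodic z faces act as an always-present pseudo-surface
        if z_period > 0.0:
            if dz < 0.0 and nz < 0.0:
                tt = (0.0 - pz) / dz
                if 0.0 < tt < best_t:
                    best_t = tt
                    best_s = -2
            elif dz > 0.0 and nz > z_period:
                tt = (z_period - pz) / dz
                if 0.0 < tt < best_t:
                    best_t = tt
                    best_s = -2

        b0 = int(lox / bucket_w)
        b1 = int(hix / bucket_w)
        if b0 < 0:
            b0 = 0
        if b1 > n_buckets - 1:
            b1 = n_buckets - 1
        if b0 > b1:
            b0, b1 = b1, b0
        for b in range(b0, b1 + 1):
            for k in range(bucket_ptr[b], bucket_ptr[b + 1]):
                s = bucket_idx[k]
                # bounding-box rejection before any division
                if surf_xlo[s] > hix or surf_xhi[s] < lox:
                    continue
                if surf_ylo[s] > hiy or surf_yhi[s] < loy:
                    continue
                if dim == 3 and (surf_zlo[s] > hiz or surf_zhi[s] < loz):
                    continue
                a = surf_orient[s]
                if a == 0:
                    da = dx
                    pa = px
                elif a == 1:
                    da = dy
                    pa = py
                else:
                    da = dz
                    pa = pz
                if da == 0.0:
                    continue
                tt = (surf_c[s] - pa) / da
                if tt <= 0.0 or tt > 1.0 or tt >= best_t:
                    continue
                hx = px + tt * dx
                hy = py + tt * dy
                hz = pz + tt * dz
                if a == 0:
                    u1 = hy
                    u2 = hz
                elif a == 1:
                    u1 = hx
                    u2 = hz
                else:
                    u1 = hx
                    u2 = hy
                if u1 < surf_lo1[s] or u1 >= surf_hi1[s]:
                    continue
                if dim == 3 and (u2 < surf_lo2[s] or u2 >= surf_hi2[s]):
                    continue
                best_t = tt
                best_s = s

        if best_s == -1:
            return 0, nx, ny, nz, -1

        rem = 1.0 - best_t
        hx = px + best_t * dx
        hy = py + best_t * dy
        hz = pz + best_t * dz
        if best_s == -2:
            # wrap across the periodic anterior-posterior boundary
            px = hx
            py = hy
            pz = 0.0 if dz > 0.0 else z_period
            dx *= rem
            dy *= rem
            dz *= rem
            continue

        s = best_s
        a = surf_orient[s]
        if surf_kind[s] == 1:
            pid = surf_pool[s]
            tot = pool_total[pid]
            pb = p_binding * (tot - pool_bound[pid]) / tot
            if pb > 0.0 and rng.random() < pb:
                # bound at the contact point, nudged off the membrane
                if a == 0:
                    hx = surf_c[s] - EPS if dx > 0.0 else surf_c[s] + EPS
                elif a == 1:
                    hy = surf_c[s] - EPS if dy > 0.0 else surf_c[s] + EPS
                else:
                    hz = surf_c[s] - EPS if dz > 0.0 else surf_c[s] + EPS
                return 1, hx, hy, hz, pid
        # specular reflection (failed binding trials reflect and continue)
        dx *= rem
        dy *= rem
        dz *= rem
        if a == 0:
            px = surf_c[s] - EPS if dx > 0.0 else surf_c[s] + EPS
            py = hy
            pz = hz
            dx = -dx
        elif a == 1:
            py = surf_c[s] - EPS if dy > 0.0 else surf_c[s] + EPS
            px = hx
            pz = hz
            dy = -dy
        else:
            pz = surf_c[s] - EPS if dz > 0.0 else surf_c[s] + EPS
            px = hx
            py = hy
            dz = -dz
    return -1, px, py, pz, -1


@njit(cache=True)
def _seed_slot(origin, dim, sec_x_lo, sec_x_hi, sec_z_lo, sec_z_hi,
               sec_apical, resecrete_uniform,
               width, apical_y, basal_y, y_top, z_period, rng):
    """Draw a fresh position for a (re-)secreted ligand.

    Returns (x, y, z, in_cavity, entered_interstitial). Draw order:
    x, then z (3D), then y when uniform in the cavity.
    """
    if origin >= 0 and resecrete_uniform == 0:
        x = sec_x_lo[origin] + (sec_x_hi[origin] - sec_x_lo[origin]) * rng.random()
        z = 0.0
        if dim == 3:
            z = sec_z_lo[origin] + (sec_z_hi[origin] - sec_z_lo[origin]) * rng.random()
        if sec_apical == 1:
            return x, apical_y + EPS, z, 1, 0
        return x, basal_y - EPS, z, 0, 1
    # uniform over the cavity (no originating secreting cell)
    x = EPS + (width - 2.0 * EPS) * rng.random()
    z = 0.0
    if dim == 3:
        z = z_period * rng.random()
    y = apical_y + EPS + (y_top - apical_y - 2.0 * EPS) * rng.random()
    return x, y, z, 1, 0


@njit(cache=True)
def run_kernel(dim, n_steps, h, sigma, p_binding, t_turnover,
               variant, influx_rate,
               pos, status, bound_pool, t_bound, t_entered, origin_cell,
               surf_orient, surf_c, surf_lo1, surf_hi1, surf_lo2, surf_hi2,
               surf_kind, surf_pool,
               surf_xlo, surf_xhi, surf_ylo, surf_yhi, surf_zlo, surf_zhi,
               bucket_ptr, bucket_idx, bucket_w, n_buckets,
               pool_bound, pool_total,
               x_min, x_max, y_top, basal_y, apical_y,
               z_period, qz_lo, qz_hi,
               sec_x_lo, sec_x_hi, sec_z_lo, sec_z_hi, sec_apical,
               resecrete_uniform, exe_cells, width,
               snap_steps,
               snap_pos, snap_status, snap_pool_bound, snap_active,
               ev_t, ev_kind, ev_lig, ev_pool, ev_tl,
               rng):
    """Integrate all ligands for ``n_steps`` steps of size ``h``.

    Returns (error_code, n_events, offending_ligand). The ligand-count law
    of the turnover variant and the ligand/pool bound-count identity are
    checked after every step.
    """
    surfs = (surf_orient, surf_c, surf_lo1, surf_hi1, surf_lo2, surf_hi2,
             surf_kind, surf_pool, surf_xlo, surf_xhi, surf_ylo, surf_yhi,
             surf_zlo, surf_zhi)
    buckets = (bucket_ptr, bucket_idx, bucket_w, n_buckets)
    bounds = (x_min, x_max, y_top, basal_y, apical_y, z_period, qz_lo, qz_hi)
    n_cap = pos.shape[0]
    n_pools = pool_bound.shape[0]
    ev_cap = ev_t.shape[0]
    ev_n = 0
    overflow = 0
    snap_ptr = 0
    n_snaps = snap_steps.shape[0]
    influx_acc = 0.0
    # unspawned capacity slots sit contiguously at the end of the arrays
    next_spawn = n_cap
    for i in range(n_cap):
        if status[i] == UNSPAWNED:
            next_spawn = i
            break

    n_active = 0
    n_bound = 0
    for i in range(n_cap):
        if status[i] == FREE:
            n_active += 1
        elif status[i] == BOUND:
            n_active += 1
            n_bound += 1
    n0_active = n_active
    prev_active = n_active

    for step in range(n_steps):
        t = step * h

        # ---- turnover: pairs dissolve exactly T_t after binding ----
        for i in range(n_cap):
            if status[i] == BOUND and t - t_bound[i] >= t_turnover:
                pid = bound_pool[i]
                pool_bound[pid] -= 1
                n_bound -= 1
                if ev_n < ev_cap:
                    ev_t[ev_n] = t
                    ev_kind[ev_n] = EV_UNBIND
                    ev_lig[ev_n] = i
                    ev_pool[ev_n] = pid
                    ev_tl[ev_n] = np.nan
                    ev_n += 1
                else:
                    overflow = 1
                bound_pool[i] = -1
                t_bound[i] = -1.0
                if variant == 1:  # decreasing: the ligand is cleared
                    status[i] = RETIRED
                    n_active -= 1
                else:             # re-secretion by the originating cell
                    x, y, z, cav, ent = _seed_slot(
                        origin_cell[i], dim, sec_x_lo, sec_x_hi, sec_z_lo,
                        sec_z_hi, sec_apical, resecrete_uniform,
                        width, apical_y, basal_y, y_top, z_period, rng)
                    pos[i, 0] = x
                    pos[i, 1] = y
                    pos[i, 2] = z
                    status[i] = FREE
                    t_entered[i] = t if ent == 1 else -1.0

        # ---- constant-rate influx of fresh ligands (increasing variant) ----
        if variant == 2:
            influx_acc += influx_rate * h
            while influx_acc >= 1.0 and next_spawn < n_cap:
                influx_acc -= 1.0
                j = next_spawn
                next_spawn += 1
                origin = -1
                if exe_cells.shape[0] > 0:
                    origin = exe_cells[rng.integers(0, exe_cells.shape[0])]
                origin_cell[j] = origin
                x, y, z, cav, ent = _seed_slot(
                    origin, dim, sec_x_lo, sec_x_hi, sec_z_lo, sec_z_hi,
                    sec_apical, resecrete_uniform,
                    width, apical_y, basal_y, y_top, z_period, rng)
                pos[j, 0] = x
                pos[j, 1] = y
                pos[j, 2] = z
                status[j] = FREE
                t_entered[j] = t if ent == 1 else -1.0
                n_active += 1

        # ---- Brownian moves with collision resolution ----
        for i in range(n_cap):
            if status[i] != FREE:
                continue
            dx = sigma * rng.standard_normal()
            dy = sigma * rng.standard_normal()
            dz = sigma * rng.standard_normal() if dim == 3 else 0.0
            # fast path hoisted here: step fully inside the cavity or
            # interstitial interior, away from every surface
            px = pos[i, 0]
            py = pos[i, 1]
            pz = pos[i, 2]
            nx = px + dx
            ny = py + dy
            nz = pz + dz
            lox = px if px < nx else nx
            hix = nx if px < nx else px
            loy = py if py < ny else ny
            hiy = ny if py < ny else py
            loz = pz if pz < nz else nz
            hiz = nz if pz < nz else pz
            if loz > qz_lo and hiz < qz_hi and lox > x_min and hix < x_max:
                # analytic specular reflection at the interstitial floor:
                # inside the band the only reachable surface below basal_y
                # is y = 0, and y is linear along the step segment
                if basal_y > 0.0 and ny < 0.0 and py < basal_y and \
                        0.0 < -ny < basal_y:
                    pos[i, 0] = nx
                    pos[i, 1] = -ny
                    pos[i, 2] = nz
                    if t_entered[i] < 0.0:
                        t_entered[i] = t + h
                        if ev_n < ev_cap:
                            ev_t[ev_n] = t + h
                            ev_kind[ev_n] = EV_CROSS
                            ev_lig[ev_n] = i
                            ev_pool[ev_n] = -1
                            ev_tl[ev_n] = np.nan
                            ev_n += 1
                        else:
                            overflow = 1
                    continue
                # analytic reflection at the cavity ceiling, same reasoning
                if ny > y_top and loy > apical_y and \
                        apical_y < 2.0 * y_top - ny < y_top:
                    pos[i, 0] = nx
                    pos[i, 1] = 2.0 * y_top - ny
                    pos[i, 2] = nz
                    continue
                if (loy > apical_y and hiy < y_top) or \
                   (basal_y > 0.0 and loy > 0.0 and hiy < basal_y):
                    pos[i, 0] = nx
                    pos[i, 1] = ny
                    pos[i, 2] = nz
                    if t_entered[i] < 0.0 and ny < basal_y:
                        t_entered[i] = t + h
                        if ev_n < ev_cap:
                            ev_t[ev_n] = t + h
                            ev_kind[ev_n] = EV_CROSS
                            ev_lig[ev_n] = i
                            ev_pool[ev_n] = -1
                            ev_tl[ev_n] = np.nan
                            ev_n += 1
                        else:
                            overflow = 1
                    continue
            outcome, px, py, pz, pid = advance_ligand(
                px, py, pz, dx, dy, dz, dim,
                surfs, buckets, pool_bound, pool_total, p_binding,
                bounds, rng)
            if outcome < 0:
                return ERR_BOUNCE, ev_n, i
            pos[i, 0] = px
            pos[i, 1] = py
            pos[i, 2] = pz
            if outcome == 1:
                status[i] = BOUND
                bound_pool[i] = pid
                t_bound[i] = t
                pool_bound[pid] += 1
                n_bound += 1
                if ev_n < ev_cap:
                    ev_t[ev_n] = t
                    ev_kind[ev_n] = EV_BIND
                    ev_lig[ev_n] = i
                    ev_pool[ev_n] = pid
                    ev_tl[ev_n] = t - t_entered[i] if t_entered[i] >= 0.0 else np.nan
                    ev_n += 1
                else:
                    overflow = 1
            else:
                if t_entered[i] < 0.0 and py < basal_y:
                    t_entered[i] = t + h
                    if ev_n < ev_cap:
                        ev_t[ev_n] = t + h
                        ev_kind[ev_n] = EV_CROSS
                        ev_lig[ev_n] = i
                        ev_pool[ev_n] = -1
                        ev_tl[ev_n] = np.nan
                        ev_n += 1
                    else:
                        overflow = 1

        # ---- per-step conservation checks ----
        sb = 0
        for p in range(n_pools):
            sb += pool_bound[p]
        if sb != n_bound:
            return ERR_CONSERVATION, ev_n, -1
        if variant == 0 and n_active != n0_active:
            return ERR_CONSERVATION, ev_n, -1
        if variant == 1 and n_active > prev_active:
            return ERR_CONSERVATION, ev_n, -1
        if variant == 2 and n_active < prev_active:
            return ERR_CONSERVATION, ev_n, -1
        prev_active = n_active

        # ---- snapshot ----
        if snap_ptr < n_snaps and step + 1 == snap_steps[snap_ptr]:
            nb = 0
            for i in range(n_cap):
                if status[i] == BOUND:
                    nb += 1
            if nb != sb:
                return ERR_CONSERVATION, ev_n, -1
            for i in range(n_cap):
                snap_pos[snap_ptr, i, 0] = pos[i, 0]
                snap_pos[snap_ptr, i, 1] = pos[i, 1]
                snap_pos[snap_ptr, i, 2] = pos[i, 2]
                snap_status[snap_ptr, i] = status[i]
            for p in range(n_pools):
                snap_pool_bound[snap_ptr, p] = pool_bound[p]
            snap_active[snap_ptr] = n_active
            snap_ptr += 1

    if overflow == 1:
        return ERR_EVENT_OVERFLOW, ev_n, -1
    return ERR_OK, ev_n, -1
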