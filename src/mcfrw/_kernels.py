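"""Numba-compiled computational kernels.

Everything performance-critical lives here: oriented-box and cylinder
occupancy tests, the spatial-hash-guided segment collision test, the
blocked-move random-walk inner loop, Monte-Carlo volume sampling and the
lattice-perturbation Metropolis-style loop.

Conventions
-----------
* Lengths in nm, time in s.  The fibril axis is z (the L direction);
  x is W and y is T.
* Platelet rotations are stored as 3x3 matrices mapping the platelet's
  local frame (W, T, L half-extents) to the world frame.
* Collagen is an implicit infinite hexagonal lattice of z-parallel
  cylinders; sites outside the envelope are harmless because every point
  outside the envelope is blocked anyway.
* The legacy ``np.random`` generator inside ``@njit`` reproduces
  ``np.random.RandomState`` bit-for-bit, which the pure-Python walker
  engine relies on for cross-engine determinism checks.
"""

import numpy as np
from numba import njit

# walker termination codes
STATUS_REACHED = 0
STATUS_TRUNCATED = 1
STATUS_TRAPPED = 2
STATUS_NO_START = 3

_SQRT3_2 = np.sqrt(3.0) / 2.0


# ---------------------------------------------------------------------------
# primitive geometry tests
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _point_in_obb(px, py, pz, cx, cy, cz, hx, hy, hz, R):
    dx = px - cx
    dy = py - cy
    dz = pz - cz
    # local coordinates q = R^T d
    qx = R[0, 0] * dx + R[1, 0] * dy + R[2, 0] * dz
    if abs(qx) > hx:
        return False
    qy = R[0, 1] * dx + R[1, 1] * dy + R[2, 1] * dz
    if abs(qy) > hy:
        return False
    qz = R[0, 2] * dx + R[1, 2] * dy + R[2, 2] * dz
    return abs(qz) <= hz


@njit(cache=True, inline="always")
def _segment_hits_obb(p0x, p0y, p0z, p1x, p1y, p1z,
                      cx, cy, cz, hx, hy, hz, R):
    """Slab test of the segment p0->p1 against an oriented box."""
    dx = p0x - cx
    dy = p0y - cy
    dz = p0z - cz
    q0x = R[0, 0] * dx + R[1, 0] * dy + R[2, 0] * dz
    q0y = R[0, 1] * dx + R[1, 1] * dy + R[2, 1] * dz
    q0z = R[0, 2] * dx + R[1, 2] * dy + R[2, 2] * dz
    dx = p1x - cx
    dy = p1y - cy
    dz = p1z - cz
    q1x = R[0, 0] * dx + R[1, 0] * dy + R[2, 0] * dz
    q1y = R[0, 1] * dx + R[1, 1] * dy + R[2, 1] * dz
    q1z = R[0, 2] * dx + R[1, 2] * dy + R[2, 2] * dz

    tmin = 0.0
    tmax = 1.0

    # x slab
    d = q1x - q0x
    if abs(d) < 1e-30:
        if q0x < -hx or q0x > hx:
            return False
    else:
        t1 = (-hx - q0x) / d
        t2 = (hx - q0x) / d
        if t1 > t2:
            t1, t2 = t2, t1
        if t1 > tmin:
            tmin = t1
        if t2 < tmax:
            tmax = t2
        if tmin > tmax:
            return False
    # y slab
    d = q1y - q0y
    if abs(d) < 1e-30:
        if q0y < -hy or q0y > hy:
            return False
    else:
        t1 = (-hy - q0y) / d
        t2 = (hy - q0y) / d
        if t1 > t2:
            t1, t2 = t2, t1
        if t1 > tmin:
            tmin = t1
        if t2 < tmax:
            tmax = t2
        if tmin > tmax:
            return False
    # z slab
    d = q1z - q0z
    if abs(d) < 1e-30:
        if q0z < -hz or q0z > hz:
            return False
    else:
        t1 = (-hz - q0z) / d
        t2 = (hz - q0z) / d
        if t1 > t2:
            t1, t2 = t2, t1
        if t1 > tmin:
            tmin = t1
        if t2 < tmax:
            tmax = t2
        if tmin > tmax:
            return False
    return True


@njit(cache=True, inline="always")
def _segdist2_2d(px, py, ax, ay, bx, by):
    """Squared distance from point (px,py) to 2D segment a->b."""
    abx = bx - ax
    aby = by - ay
    apx = px - ax
    apy = py - ay
    denom = abx * abx + aby * aby
    if denom < 1e-30:
        return apx * apx + apy * apy
    t = (apx * abx + apy * aby) / denom
    if t < 0.0:
        t = 0.0
    elif t > 1.0:
        t = 1.0
    ex = apx - t * abx
    ey = apy - t * aby
    return ex * ex + ey * ey


@njit(cache=True, inline="always")
def _segment_hits_collagen(p0x, p0y, p1x, p1y, a, r):
    """Does the (x,y) projection of the segment come within r of a hex site?

    Hex sites: x = a*(i + j/2), y = a*(sqrt(3)/2)*j for integer i, j.
    """
    row = a * _SQRT3_2
    ylo = min(p0y, p1y) - r
    yhi = max(p0y, p1y) + r
    xlo = min(p0x, p1x) - r
    xhi = max(p0x, p1x) + r
    r2 = r * r
    jlo = int(np.floor(ylo / row))
    jhi = int(np.ceil(yhi / row))
    for j in range(jlo, jhi + 1):
        cy = row * j
        ilo = int(np.floor(xlo / a - 0.5 * j))
        ihi = int(np.ceil(xhi / a - 0.5 * j))
        for i in range(ilo, ihi + 1):
            cx = a * (i + 0.5 * j)
            if _segdist2_2d(cx, cy, p0x, p0y, p1x, p1y) <= r2:
                return True
    return False


@njit(cache=True, inline="always")
def _point_in_collagen(px, py, a, r):
    return _segment_hits_collagen(px, py, px, py, a, r)


# ---------------------------------------------------------------------------
# spatial-index-guided platelet queries
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _cell_of(v, o, cell, n):
    i = int(np.floor((v - o) / cell))
    if i < 0:
        i = 0
    elif i >= n:
        i = n - 1
    return i


@njit(cache=True)
def _point_in_platelets(px, py, pz, centers, half, rot,
                        gox, goy, goz, cell, nx, ny, nz, cstart, citems):
    if centers.shape[0] == 0:
        return False
    if (px < gox or py < goy or pz < goz
            or px > gox + cell * nx or py > goy + cell * ny
            or pz > goz + cell * nz):
        return False
    ix = _cell_of(px, gox, cell, nx)
    iy = _cell_of(py, goy, cell, ny)
    iz = _cell_of(pz, goz, cell, nz)
    c = (ix * ny + iy) * nz + iz
    for k in range(cstart[c], cstart[c + 1]):
        p = citems[k]
        if _point_in_obb(px, py, pz,
                         centers[p, 0], centers[p, 1], centers[p, 2],
                         half[p, 0], half[p, 1], half[p, 2], rot[p]):
            return True
    return False


@njit(cache=True)
def _segment_hits_platelets(p0x, p0y, p0z, p1x, p1y, p1z,
                            centers, half, rot,
                            gox, goy, goz, cell, nx, ny, nz, cstart, citems):
    if centers.shape[0] == 0:
        return False
    ix0 = _cell_of(min(p0x, p1x), gox, cell, nx)
    ix1 = _cell_of(max(p0x, p1x), gox, cell, nx)
    iy0 = _cell_of(min(p0y, p1y), goy, cell, ny)
    iy1 = _cell_of(max(p0y, p1y), goy, cell, ny)
    iz0 = _cell_of(min(p0z, p1z), goz, cell, nz)
    iz1 = _cell_of(max(p0z, p1z), goz, cell, nz)
    for ix in range(ix0, ix1 + 1):
        for iy in range(iy0, iy1 + 1):
            for iz in range(iz0, iz1 + 1):
                c = (ix * ny + iy) * nz + iz
                for k in range(cstart[c], cstart[c + 1]):
                    p = citems[k]
                    if _segment_hits_obb(
                            p0x, p0y, p0z, p1x, p1y, p1z,
                            centers[p, 0], centers[p, 1], centers[p, 2],
                            half[p, 0], half[p, 1], half[p, 2], rot[p]):
                        return True
    return False


# ---------------------------------------------------------------------------
# full occupancy tests (envelope + collagen + platelets)
# ---------------------------------------------------------------------------

@njit(cache=True)
def point_blocked(px, py, pz, centers, half, rot,
                  gox, goy, goz, cell, nx, ny, nz, cstart, citems,
                  col_on, col_a, col_r, env_r, env_len, ztop_open):
    if px * px + py * py > env_r * env_r:
        return True
    if pz < 0.0:
        return True
    if not ztop_open and pz > env_len:
        return True
    if col_on and _point_in_collagen(px, py, col_a, col_r):
        return True
    return _point_in_platelets(px, py, pz, centers, half, rot,
                               gox, goy, goz, cell, nx, ny, nz,
                               cstart, citems)


@njit(cache=True)
def segment_blocked(p0x, p0y, p0z, p1x, p1y, p1z, centers, half, rot,
                    gox, goy, goz, cell, nx, ny, nz, cstart, citems,
                    col_on, col_a, col_r, env_r, env_len, ztop_open):
    # envelope is convex: endpoint checks suffice for it
    if p0x * p0x + p0y * p0y > env_r * env_r:
        return True
    if p1x * p1x + p1y * p1y > env_r * env_r:
        return True
    if p0z < 0.0 or p1z < 0.0:
        return True
    if not ztop_open and (p0z > env_len or p1z > env_len):
        return True
    if col_on and _segment_hits_collagen(p0x, p0y, p1x, p1y, col_a, col_r):
        return True
    return _segment_hits_platelets(p0x, p0y, p0z, p1x, p1y, p1z,
                                   centers, half, rot,
                                   gox, goy, goz, cell, nx, ny, nz,
                                   cstart, citems)


# ---------------------------------------------------------------------------
# random walk
# ---------------------------------------------------------------------------

@njit(cache=True)
def walk(seed, sx, sy, sz, start_given, sigma_nm, stride, stop_L,
         max_steps, max_consec, resample,
         centers, half, rot, gox, goy, goz, cell, nx, ny, nz,
         cstart, citems, col_on, col_a, col_r, env_r, env_len,
         rec):
    """Simulate one blocked-move Gaussian walk.

    Returns (n_recorded, n_steps, n_rejections, status).  ``rec`` is a
    preallocated (max_records, 3) buffer; positions are recorded every
    ``stride`` time steps plus the final position.

    ``resample`` selects the zero-time rejection policy (redraw within the
    same time step); the default policy is one proposal per time step with
    the particle staying put on rejection.
    """
    np.random.seed(seed)
    if start_given:
        x, y, z = sx, sy, sz
    else:
        ok = False
        for _ in range(1000000):
            u = np.random.random()
            th = 2.0 * np.pi * np.random.random()
            rad = env_r * np.sqrt(u)
            x = rad * np.cos(th)
            y = rad * np.sin(th)
            z = 0.0
            if not point_blocked(x, y, z, centers, half, rot,
                                 gox, goy, goz, cell, nx, ny, nz,
                                 cstart, citems, col_on, col_a, col_r,
                                 env_r, env_len, True):
                ok = True
                break
        if not ok:
            return 0, 0, 0, STATUS_NO_START

    rec[0, 0] = x
    rec[0, 1] = y
    rec[0, 2] = z
    n_rec = 1
    if z >= stop_L:
        return n_rec, 0, 0, STATUS_REACHED
    steps = 0
    n_rej = 0
    consec = 0
    status = STATUS_TRUNCATED
    last_rec_step = 0

    while steps < max_steps:
        px = x + sigma_nm * np.random.standard_normal()
        py = y + sigma_nm * np.random.standard_normal()
        pz = z + sigma_nm * np.random.standard_normal()
        hit = segment_blocked(x, y, z, px, py, pz, centers, half, rot,
                              gox, goy, goz, cell, nx, ny, nz,
                              cstart, citems, col_on, col_a, col_r,
                              env_r, env_len, True)
        if hit:
            n_rej += 1
            consec += 1
            if consec > max_consec:
                status = STATUS_TRAPPED
                break
            if resample:
                continue  # zero-time redraw: no step elapses
        else:
            x, y, z = px, py, pz
            consec = 0
        steps += 1
        if steps % stride == 0:
            rec[n_rec, 0] = x
            rec[n_rec, 1] = y
            rec[n_rec, 2] = z
            n_rec += 1
            last_rec_step = steps
        if z >= stop_L:
            status = STATUS_REACHED
            break

    if last_rec_step != steps:
        rec[n_rec, 0] = x
        rec[n_rec, 1] = y
        rec[n_rec, 2] = z
        n_rec += 1
    return n_rec, steps, n_rej, status


# ---------------------------------------------------------------------------
# Monte-Carlo mineral volume fraction
# ---------------------------------------------------------------------------

@njit(cache=True)
def mineral_fraction_count(seed, n_samples, centers, half, rot,
                           gox, goy, goz, cell, nx, ny, nz, cstart, citems,
                           env_r, env_len):
    """Count uniform envelope samples falling inside any platelet."""
    np.random.seed(seed)
    hits = 0
    for _ in range(n_samples):
        rad = env_r * np.sqrt(np.random.random())
        th = 2.0 * np.pi * np.random.random()
        x = rad * np.cos(th)
        y = rad * np.sin(th)
        z = env_len * np.random.random()
        if _point_in_platelets(x, y, z, centers, half, rot,
                               gox, goy, goz, cell, nx, ny, nz,
                               cstart, citems):
            hits += 1
    return hits


# ---------------------------------------------------------------------------
# oriented-box overlap (separating axis theorem) and perturbation loop
# ---------------------------------------------------------------------------

@njit(cache=True)
def obb_overlap(ca, ha, Ra, cb, hb, Rb):
    """Gottschalk 15-axis separating-axis test for two oriented boxes."""
    eps = 1e-9
    C = np.empty((3, 3))
    A = np.empty((3, 3))
    for i in range(3):
        for j in range(3):
            s = 0.0
            for k in range(3):
                s += Ra[k, i] * Rb[k, j]
            C[i, j] = s
            A[i, j] = abs(s) + eps
    # translation in A's frame
    tx = cb[0] - ca[0]
    ty = cb[1] - ca[1]
    tz = cb[2] - ca[2]
    t = np.empty(3)
    t[0] = Ra[0, 0] * tx + Ra[1, 0] * ty + Ra[2, 0] * tz
    t[1] = Ra[0, 1] * tx + Ra[1, 1] * ty + Ra[2, 1] * tz
    t[2] = Ra[0, 2] * tx + Ra[1, 2] * ty + Ra[2, 2] * tz
    # A's axes
    for i in range(3):
        ra = ha[i]
        rb = hb[0] * A[i, 0] + hb[1] * A[i, 1] + hb[2] * A[i, 2]
        if abs(t[i]) > ra + rb:
            return False
    # B's axes
    for j in range(3):
        ra = ha[0] * A[0, j] + ha[1] * A[1, j] + ha[2] * A[2, j]
        rb = hb[j]
        if abs(t[0] * C[0, j] + t[1] * C[1, j] + t[2] * C[2, j]) > ra + rb:
            return False
    # cross products A_i x B_j
    for i in range(3):
        i1 = (i + 1) % 3
        i2 = (i + 2) % 3
        for j in range(3):
            j1 = (j + 1) % 3
            j2 = (j + 2) % 3
            ra = ha[i1] * A[i2, j] + ha[i2] * A[i1, j]
            rb = hb[j1] * A[i, j2] + hb[j2] * A[i, j1]
            lhs = abs(t[i2] * C[i1, j] - t[i1] * C[i2, j])
            if lhs > ra + rb:
                return False
    return True


@njit(cache=True, inline="always")
def _world_extents(hx, hy, hz, R, out):
    for a in range(3):
        out[a] = abs(R[a, 0]) * hx + abs(R[a, 1]) * hy + abs(R[a, 2]) * hz


@njit(cache=True, inline="always")
def _protrusion(cx, cy, cz, hx, hy, hz, R, env_r, env_len):
    """Worst-case envelope protrusion of a box: (radial, below 0, above L)."""
    rad = 0.0
    zlo = cz
    zhi = cz
    for sx in (-1.0, 1.0):
        for sy in (-1.0, 1.0):
            for sz in (-1.0, 1.0):
                ox = R[0, 0] * sx * hx + R[0, 1] * sy * hy + R[0, 2] * sz * hz
                oy = R[1, 0] * sx * hx + R[1, 1] * sy * hy + R[1, 2] * sz * hz
                oz = R[2, 0] * sx * hx + R[2, 1] * sy * hy + R[2, 2] * sz * hz
                r = np.sqrt((cx + ox) ** 2 + (cy + oy) ** 2)
                if r > rad:
                    rad = r
                if cz + oz < zlo:
                    zlo = cz + oz
                if cz + oz > zhi:
                    zhi = cz + oz
    return rad - env_r, -zlo, zhi - env_len


@njit(cache=True)
def perturb_loop(seed, n_moves, max_trans, max_rot, cos_max_incl, max_offset,
                 centers, half, rot, ext, orig_centers,
                 nbr_start, nbr_items, env_r, env_len,
                 exc_r0, exc_lo0, exc_hi0):
    """Random single-platelet trial moves with rejection.

    A move is rejected if it would exceed the cumulative displacement cap,
    tilt the platelet's long axis beyond the inclination bound, push the
    platelet out of the envelope beyond its as-built protrusion, or create
    a platelet-platelet overlap (axis-aligned-bound prune, then a full
    separating-axis test).  ``centers``, ``rot`` and the cached world
    axis-aligned half-extents ``ext`` are updated in place.
    """
    np.random.seed(seed)
    P = centers.shape[0]
    if P == 0:
        return 0
    Rnew = np.empty((3, 3))
    dR = np.empty((3, 3))
    cnew = np.empty(3)
    enew = np.empty(3)
    max_off2 = max_offset * max_offset
    accepted = 0

    for _ in range(n_moves):
        p = np.random.randint(0, P)
        cnew[0] = centers[p, 0] + (2.0 * np.random.random() - 1.0) * max_trans
        cnew[1] = centers[p, 1] + (2.0 * np.random.random() - 1.0) * max_trans
        cnew[2] = centers[p, 2] + (2.0 * np.random.random() - 1.0) * max_trans
        # random rotation axis (uniform on the sphere) and small angle
        az = 2.0 * np.random.random() - 1.0
        aphi = 2.0 * np.pi * np.random.random()
        ang = (2.0 * np.random.random() - 1.0) * max_rot
        dx = cnew[0] - orig_centers[p, 0]
        dy = cnew[1] - orig_centers[p, 1]
        dz = cnew[2] - orig_centers[p, 2]
        if dx * dx + dy * dy + dz * dz > max_off2:
            continue
        s = np.sqrt(max(0.0, 1.0 - az * az))
        ux = s * np.cos(aphi)
        uy = s * np.sin(aphi)
        uz = az
        ca = np.cos(ang)
        sa = np.sin(ang)
        oc = 1.0 - ca
        dR[0, 0] = ca + ux * ux * oc
        dR[0, 1] = ux * uy * oc - uz * sa
        dR[0, 2] = ux * uz * oc + uy * sa
        dR[1, 0] = uy * ux * oc + uz * sa
        dR[1, 1] = ca + uy * uy * oc
        dR[1, 2] = uy * uz * oc - ux * sa
        dR[2, 0] = uz * ux * oc - uy * sa
        dR[2, 1] = uz * uy * oc + ux * sa
        dR[2, 2] = ca + uz * uz * oc
        for i in range(3):
            for j in range(3):
                s2 = 0.0
                for k in range(3):
                    s2 += dR[i, k] * rot[p, k, j]
                Rnew[i, j] = s2
        # inclination of the long (local z) axis w.r.t. global z
        if abs(Rnew[2, 2]) < cos_max_incl:
            continue
        er, elo, ehi = _protrusion(cnew[0], cnew[1], cnew[2],
                                   half[p, 0], half[p, 1], half[p, 2],
                                   Rnew, env_r, env_len)
        if er > exc_r0[p] or elo > exc_lo0[p] or ehi > exc_hi0[p]:
            continue
        _world_extents(half[p, 0], half[p, 1], half[p, 2], Rnew, enew)
        ok = True
        for k in range(nbr_start[p], nbr_start[p + 1]):
            q = nbr_items[k]
            if abs(cnew[1] - centers[q, 1]) > enew[1] + ext[q, 1]:
                continue
            if abs(cnew[2] - centers[q, 2]) > enew[2] + ext[q, 2]:
                continue
            if abs(cnew[0] - centers[q, 0]) > enew[0] + ext[q, 0]:
                continue
            if obb_overlap(cnew, half[p], Rnew, centers[q], half[q], rot[q]):
                ok = False
                break
        if not ok:
            continue
        centers[p, 0] = cnew[0]
        centers[p, 1] = cnew[1]
        centers[p, 2] = cnew[2]
        for i in range(3):
            ext[p, i] = enew[i]
            for j in range(3):
                rot[p, i, j] = Rnew[i, j]
        accepted += 1
    return accepted


# ---------------------------------------------------------------------------
# coarse-grained path length (tortuosity support)
# ---------------------------------------------------------------------------

@njit(cache=True)
def coarse_path_length(pos, resolution):
    """Effective path length after spatial coarse-graining.

    Anchors the path at its start and advances the anchor each time the
    walker first moves ``resolution`` away from it; the final position
    always terminates the path.  ``resolution = 0`` gives the raw sum of
    recorded segment lengths.
    """
    n = pos.shape[0]
    ax = pos[0, 0]
    ay = pos[0, 1]
    az = pos[0, 2]
    total = 0.0
    for i in range(1, n):
        dx = pos[i, 0] - ax
        dy = pos[i, 1] - ay
        dz = pos[i, 2] - az
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        if d >= resolution and d > 0.0:
            total += d
            ax = pos[i, 0]
            ay = pos[i, 1]
            az = pos[i, 2]
    # close the path at the final position
    dx = pos[n - 1, 0] - ax
    dy = pos[n - 1, 1] - ay
    dz = pos[n - 1, 2] - az
    total += np.sqrt(dx * dx + dy * dy + dz * dz)
    return total
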