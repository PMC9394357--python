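"""Numba kernels: neighbour search, DPD forces, integrator inner loop, and
the slab-resolved virial used by the stress module.

Performance layout: inside the integrator the bead arrays are kept sorted by
spatial cell, which makes the pair traversal cache-local; a Verlet pair list
with a safety skin is rebuilt whenever any bead has moved more than half the
skin since the last build (a sufficient condition for list validity), and
bead order is scattered back to the caller's canonical order at chunk
boundaries.  The random force uses a counter-based generator keyed on
(seed, step, canonical pair id), so the draw for a pair is independent of
traversal order and bead numbering: the sorted cell-list path and the plain
all-pairs path produce identical forces, and zeta_ij == zeta_ji by
construction (random-force momentum conservation to machine precision).
"""

from __future__ import annotations

import numpy as np
from numba import njit

U64 = np.uint64
_M1 = U64(0x9E3779B97F4A7C15)
_M2 = U64(0xBF58476D1CE4E5B9)
_M3 = U64(0x94D049BB133111EB)
_TWO_PI = 6.283185307179586
_INV_2_53 = 1.0 / 9007199254740992.0


@njit(cache=True, inline="always")
def _mix64(z):
    z = U64(z + _M1)
    z = U64(U64(z ^ U64(z >> U64(30))) * _M2)
    z = U64(U64(z ^ U64(z >> U64(27))) * _M3)
    return U64(z ^ U64(z >> U64(31)))


@njit(cache=True, inline="always")
def _step_hash(seed, step):
    return _mix64(U64(seed) ^ _mix64(U64(step)))


@njit(cache=True, inline="always")
def _pair_key(i, j):
    lo = i if i < j else j
    hi = j if i < j else i
    return U64(U64(U64(lo) << U64(32)) | U64(hi))


@njit(cache=True, inline="always")
def _norm_icdf(u):
    """Inverse normal CDF (Beasley-Springer-Moro), |error| < 1e-8."""
    q = u - 0.5
    if abs(q) <= 0.42:
        r = q * q
        num = q * (
            ((-25.44106049637 * r + 41.39119773534) * r - 18.61500062529) * r
            + 2.50662823884
        )
        den = (
            ((3.13082909833 * r - 21.06224101826) * r + 23.08336743743) * r
            - 8.47351093090
        ) * r + 1.0
        return num / den
    r = 1.0 - u if q > 0.0 else u
    s = np.log(-np.log(r))
    t = 0.3374754822726147 + s * (
        0.9761690190917186
        + s * (
            0.1607979714918209
            + s * (
                0.0276438810333863
                + s * (
                    0.0038405729373609
                    + s * (
                        0.0003951896511919
                        + s * (
                            0.0000321767881768
                            + s * (0.0000002888167364 + s * 0.0000003960315187)
                        )
                    )
                )
            )
        )
    )
    return t if q > 0.0 else -t


@njit(cache=True, inline="always")
def _pair_gauss(hstep, key):
    """Standard-normal zeta for one pair at one step (counter-based)."""
    h = _mix64(hstep ^ key)
    u = (np.float64(h >> U64(11)) + 0.5) * _INV_2_53
    return _norm_icdf(u)


@njit(cache=True, inline="always")
def _rand_unit(hstep, key):
    """Deterministic pseudo-random unit vector for overlapping pairs."""
    h1 = _mix64(U64(hstep ^ key) ^ U64(0x5A5A5A5A))
    h2 = _mix64(h1)
    z = 2.0 * (np.float64(h1 >> U64(11)) + 0.5) * _INV_2_53 - 1.0
    phi = _TWO_PI * (np.float64(h2 >> U64(11)) + 0.5) * _INV_2_53
    s = np.sqrt(max(1.0 - z * z, 0.0))
    return s * np.cos(phi), s * np.sin(phi), z


@njit(cache=True, inline="always")
def _min_image(d, L):
    return d - L * np.rint(d / L)


# half-space neighbour offsets (13) for Newton's-third-law cell traversal
_HALF_OFFSETS = np.array(
    [
        (0, 0, 1),
        (0, 1, -1),
        (0, 1, 0),
        (0, 1, 1),
        (1, -1, -1),
        (1, -1, 0),
        (1, -1, 1),
        (1, 0, -1),
        (1, 0, 0),
        (1, 0, 1),
        (1, 1, -1),
        (1, 1, 0),
        (1, 1, 1),
    ],
    dtype=np.int64,
)


@njit(cache=True)
def _cell_sort(pos, box, cell_edge):
    """Counting sort of beads into cells; returns (order, cell_start, ncx, ncy, ncz).

    ``order[t]`` is the bead index occupying sorted slot t; beads of cell c
    are slots cell_start[c]..cell_start[c+1].
    """
    n = pos.shape[0]
    ncx = max(int(box[0] / cell_edge), 1)
    ncy = max(int(box[1] / cell_edge), 1)
    ncz = max(int(box[2] / cell_edge), 1)
    ncell = ncx * ncy * ncz
    cidx = np.empty(n, dtype=np.int32)
    start = np.zeros(ncell + 1, dtype=np.int32)
    for i in range(n):
        ix = int(pos[i, 0] / box[0] * ncx) % ncx
        iy = int(pos[i, 1] / box[1] * ncy) % ncy
        iz = int(pos[i, 2] / box[2] * ncz) % ncz
        c = (ix * ncy + iy) * ncz + iz
        cidx[i] = c
        start[c + 1] += 1
    for c in range(ncell):
        start[c + 1] += start[c]
    order = np.empty(n, dtype=np.int32)
    fill = start[:-1].copy()
    for i in range(n):
        c = cidx[i]
        order[fill[c]] = i
        fill[c] += 1
    return order, start, ncx, ncy, ncz


@njit(cache=True, fastmath=True)
def _build_pair_list(
    pos, box, rlist, spec, gid, amat, pair_i, pair_j, pair_a, pair_key
):
    """Verlet pair list on cell-sorted arrays (pos already sorted).

    Emits all pairs with r < rlist with their repulsion parameter and the
    canonical RNG key.  The inner candidate scan is two-phase (distances into
    a flat buffer, then emission) to keep the hot loop branch-light.
    Returns the pair count, or -1 on capacity overflow.  Requires >= 3 cells
    per axis.
    """
    n = pos.shape[0]
    ncx = max(int(box[0] / rlist), 1)
    ncy = max(int(box[1] / rlist), 1)
    ncz = max(int(box[2] / rlist), 1)
    ncell = ncx * ncy * ncz
    # beads already sorted: recover cell boundaries by scanning
    start = np.zeros(ncell + 1, dtype=np.int32)
    for i in range(n):
        ix = int(pos[i, 0] / box[0] * ncx) % ncx
        iy = int(pos[i, 1] / box[1] * ncy) % ncy
        iz = int(pos[i, 2] / box[2] * ncz) % ncz
        c = (ix * ncy + iy) * ncz + iz
        start[c + 1] += 1
    for c in range(ncell):
        start[c + 1] += start[c]
    rl2 = rlist * rlist
    cap = pair_i.shape[0]
    npair = 0
    invx = 1.0 / box[0]
    invy = 1.0 / box[1]
    invz = 1.0 / box[2]
    buf = np.empty(4096)
    for cx in range(ncx):
        for cy in range(ncy):
            for cz in range(ncz):
                c = (cx * ncy + cy) * ncz + cz
                a0 = start[c]
                a1 = start[c + 1]
                for koff in range(14):
                    if koff == 13:
                        b0 = a0
                        b1 = a1
                        self_cell = True
                    else:
                        ox = (cx + _HALF_OFFSETS[koff, 0]) % ncx
                        oy = (cy + _HALF_OFFSETS[koff, 1]) % ncy
                        oz = (cz + _HALF_OFFSETS[koff, 2]) % ncz
                        c2 = (ox * ncy + oy) * ncz + oz
                        b0 = start[c2]
                        b1 = start[c2 + 1]
                        self_cell = False
                    for i in range(a0, a1):
                        xi = pos[i, 0]
                        yi = pos[i, 1]
                        zi = pos[i, 2]
                        j0 = i + 1 if self_cell else b0
                        while j0 < b1:
                            m = min(b1 - j0, 4096)
                            for t in range(m):
                                j = j0 + t
                                dx = xi - pos[j, 0]
                                dy = yi - pos[j, 1]
                                dz = zi - pos[j, 2]
                                dx -= box[0] * np.rint(dx * invx)
                                dy -= box[1] * np.rint(dy * invy)
                                dz -= box[2] * np.rint(dz * invz)
                                buf[t] = dx * dx + dy * dy + dz * dz
                            for t in range(m):
                                if buf[t] < rl2:
                                    if npair >= cap:
                                        return -1
                                    j = j0 + t
                                    pair_i[npair] = i
                                    pair_j[npair] = j
                                    pair_a[npair] = amat[spec[i], spec[j]]
                                    pair_key[npair] = _pair_key(gid[i], gid[j])
                                    npair += 1
                            j0 += m
    return npair


@njit(cache=True, fastmath=True)
def _pair_forces_list(
    pos, vel, gamma, sigma, inv_sqrt_dt, box, rc, forces,
    hstep, npair, pair_i, pair_j, pair_a, pair_key, use_thermostat,
):
    """C (+ D + R) forces over a prebuilt pair list; returns (e_pair, overlaps).

    The per-component force is a single scalar coefficient on the raw
    separation vector (conservative a w / r, dissipative
    -gamma w^2 (r.v)/r^2, random sigma w zeta dt^-0.5 / r), avoiding the
    explicit unit vector.
    """
    e = 0.0
    n_ov = 0
    rc2 = rc * rc
    inv_rc = 1.0 / rc
    sig_dt = sigma * inv_sqrt_dt
    invx = 1.0 / box[0]
    invy = 1.0 / box[1]
    invz = 1.0 / box[2]
    for p in range(npair):
        i = pair_i[p]
        j = pair_j[p]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box[0] * np.rint(dx * invx)
        dy -= box[1] * np.rint(dy * invy)
        dz -= box[2] * np.rint(dz * invz)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc2:
            continue
        a = pair_a[p]
        if r2 < 1e-24:
            # overlap is legal for the soft potential; direction is undefined,
            # take the r->0 magnitude along a deterministic random direction
            ex, ey, ez = _rand_unit(hstep, pair_key[p])
            n_ov += 1
            fmag = a
            if use_thermostat:
                zeta = _pair_gauss(hstep, pair_key[p])
                fmag += sig_dt * zeta
            fx = fmag * ex
            fy = fmag * ey
            fz = fmag * ez
            e += 0.5 * a * rc
        else:
            inv_r = 1.0 / np.sqrt(r2)
            r = r2 * inv_r
            w = 1.0 - r * inv_rc
            wr = w * inv_r
            fs = a * wr
            if use_thermostat:
                rv = (
                    dx * (vel[i, 0] - vel[j, 0])
                    + dy * (vel[i, 1] - vel[j, 1])
                    + dz * (vel[i, 2] - vel[j, 2])
                )
                zeta = _pair_gauss(hstep, pair_key[p])
                fs += -gamma * wr * wr * rv + sig_dt * zeta * wr
            fx = fs * dx
            fy = fs * dy
            fz = fs * dz
            e += 0.5 * a * rc * w * w
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
    return e, n_ov


@njit(cache=True)
def pair_forces_allpairs(
    pos, vel, species, amat, gamma, sigma, inv_sqrt_dt,
    box, rc, forces, seed, step, use_thermostat,
):
    """O(N^2) traversal on canonical arrays (small boxes, oracle checks)."""
    n = pos.shape[0]
    hstep = _step_hash(seed, step)
    e = 0.0
    n_ov = 0
    rc2 = rc * rc
    for i in range(n):
        for j in range(i + 1, n):
            dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
            dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
            dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= rc2:
                continue
            a = amat[species[i], species[j]]
            key = _pair_key(i, j)
            if r2 < 1e-24:
                ex, ey, ez = _rand_unit(hstep, key)
                r = 0.0
                n_ov += 1
            else:
                inv_r = 1.0 / np.sqrt(r2)
                r = r2 * inv_r
                ex = dx * inv_r
                ey = dy * inv_r
                ez = dz * inv_r
            w = 1.0 - r / rc
            fmag = a * w
            if use_thermostat:
                dvx = vel[i, 0] - vel[j, 0]
                dvy = vel[i, 1] - vel[j, 1]
                dvz = vel[i, 2] - vel[j, 2]
                rv = ex * dvx + ey * dvy + ez * dvz
                zeta = _pair_gauss(hstep, key)
                fmag += -gamma * w * w * rv + sigma * w * zeta * inv_sqrt_dt
            fx = fmag * ex
            fy = fmag * ey
            fz = fmag * ez
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[j, 0] -= fx
            forces[j, 1] -= fy
            forces[j, 2] -= fz
            e += 0.5 * a * rc * w * w
    return e, n_ov


@njit(cache=True)
def bond_forces(pos, bonds, ks, rs, box, forces):
    """Harmonic DPD bonds F = ks (1 - r/rs) r_hat; returns bond energy."""
    e = 0.0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
        dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
        dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            # zero-length bond: direction undefined, magnitude capped at zero
            e += 0.5 * ks * rs
            continue
        s = 1.0 - r / rs
        fmag = ks * s / r
        fx = fmag * dx
        fy = fmag * dy
        fz = fmag * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
        e += 0.5 * ks * rs * s * s
    return e


@njit(cache=True, inline="always")
def _angle_triple(pos, i, j, k, k_theta, theta0, box):
    """Bending forces for the triple (i, j, k); j is the middle bead.

    theta is the angle between u = ri - rj and v = rk - rj (pi for a
    straight chain).  Returns (Fi, Fk, energy); Fj = -(Fi + Fk).
    """
    ux = _min_image(pos[i, 0] - pos[j, 0], box[0])
    uy = _min_image(pos[i, 1] - pos[j, 1], box[1])
    uz = _min_image(pos[i, 2] - pos[j, 2], box[2])
    vx = _min_image(pos[k, 0] - pos[j, 0], box[0])
    vy = _min_image(pos[k, 1] - pos[j, 1], box[1])
    vz = _min_image(pos[k, 2] - pos[j, 2], box[2])
    ru = np.sqrt(ux * ux + uy * uy + uz * uz)
    rv = np.sqrt(vx * vx + vy * vy + vz * vz)
    if ru < 1e-12 or rv < 1e-12:
        return 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0
    c = (ux * vx + uy * vy + uz * vz) / (ru * rv)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    theta = np.arccos(c)
    s = np.sqrt(1.0 - c * c)
    e = k_theta * (theta - theta0) * (theta - theta0)
    if s < 1e-8:
        # collinear: gradient direction ill-defined; magnitude -> 0 for theta0 = pi
        return 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, e
    coef = 2.0 * k_theta * (theta - theta0) / s
    fix = coef * (vx / rv - c * ux / ru) / ru
    fiy = coef * (vy / rv - c * uy / ru) / ru
    fiz = coef * (vz / rv - c * uz / ru) / ru
    fkx = coef * (ux / ru - c * vx / rv) / rv
    fky = coef * (uy / ru - c * vy / rv) / rv
    fkz = coef * (uz / ru - c * vz / rv) / rv
    return fix, fiy, fiz, fkx, fky, fkz, e


@njit(cache=True)
def angle_forces(pos, angles, k_theta, theta0, box, forces):
    """Bending forces over all angle triples; returns angle energy."""
    e_tot = 0.0
    for a in range(angles.shape[0]):
        i = angles[a, 0]
        j = angles[a, 1]
        k = angles[a, 2]
        fix, fiy, fiz, fkx, fky, fkz, e = _angle_triple(
            pos, i, j, k, k_theta, theta0, box
        )
        forces[i, 0] += fix
        forces[i, 1] += fiy
        forces[i, 2] += fiz
        forces[k, 0] += fkx
        forces[k, 1] += fky
        forces[k, 2] += fkz
        forces[j, 0] -= fix + fkx
        forces[j, 1] -= fiy + fky
        forces[j, 2] -= fiz + fkz
        e_tot += e
    return e_tot


@njit(cache=True)
def compute_forces(
    pos, vel, species, bonds, angles, amat, gamma, sigma, dt,
    ks, rs, k_theta, theta0, box, rc, seed, step,
    use_thermostat, use_cells,
):
    """One-shot total force evaluation on canonical arrays.

    Returns (forces, e_pair, e_bond, e_angle, overlaps).  ``use_cells``
    selects the sorted cell-list path (boxes >= 3 rc per axis); physics and
    random draws are identical either way.
    """
    n = pos.shape[0]
    forces = np.zeros((n, 3))
    inv_sqrt_dt = 1.0 / np.sqrt(dt)
    hstep = _step_hash(seed, step)
    if use_cells:
        order, _start, _a, _b, _c = _cell_sort(pos, box, rc)
        pos_s = pos[order.astype(np.int64)]
        vel_s = vel[order.astype(np.int64)]
        spec_s = species[order.astype(np.int64)]
        gid = order.astype(np.int64)
        cap = max(int(n * 18), 1024)
        npair = -1
        while npair < 0:
            pair_i = np.empty(cap, dtype=np.int32)
            pair_j = np.empty(cap, dtype=np.int32)
            pair_a = np.empty(cap)
            pair_key = np.empty(cap, dtype=np.uint64)
            npair = _build_pair_list(
                pos_s, box, rc, spec_s, gid, amat, pair_i, pair_j, pair_a, pair_key
            )
            cap *= 2
        frc_s = np.zeros((n, 3))
        e_pair, n_ov = _pair_forces_list(
            pos_s, vel_s, gamma, sigma, inv_sqrt_dt, box, rc, frc_s,
            hstep, npair, pair_i, pair_j, pair_a, pair_key, use_thermostat,
        )
        for t in range(n):
            forces[gid[t], 0] = frc_s[t, 0]
            forces[gid[t], 1] = frc_s[t, 1]
            forces[gid[t], 2] = frc_s[t, 2]
    else:
        e_pair, n_ov = pair_forces_allpairs(
            pos, vel, species, amat, gamma, sigma, inv_sqrt_dt,
            box, rc, forces, seed, step, use_thermostat,
        )
    e_bond = bond_forces(pos, bonds, ks, rs, box, forces) if bonds.shape[0] else 0.0
    e_angle = (
        angle_forces(pos, angles, k_theta, theta0, box, forces)
        if angles.shape[0]
        else 0.0
    )
    return forces, e_pair, e_bond, e_angle, n_ov


@njit(cache=True)
def run_chunk(
    pos, vel, forces, species, bonds, angles, amat, gamma, sigma,
    dt, lam, ks, rs, k_theta, theta0, box, rc, skin, seed, step0, n_steps,
    energy_stride, e_step, e_kin, e_pair, e_bond, e_angle,
    use_cells,
):
    """Advance n_steps of the modified velocity-Verlet scheme in place.

    Per step: drift positions with the old forces, predict velocities with
    factor lambda, recompute forces (fresh random draws, dissipative term on
    the predicted velocities), correct velocities with the mean of old and
    new forces.  Energies are recorded every ``energy_stride`` steps into the
    e_* arrays (filled from index 0); returns (n_recorded, n_overlaps).
    """
    n = pos.shape[0]
    inv_sqrt_dt = 1.0 / np.sqrt(dt)
    rlist = rc + skin
    half_skin2 = 0.25 * skin * skin
    n_rec = 0
    n_ov_tot = 0
    if use_cells:
        # sorted working copies; gid maps sorted slot -> canonical index
        gid = np.arange(n, dtype=np.int64)
        pos_s = pos.copy()
        vel_s = vel.copy()
        frc_s = forces.copy()
        spec_s = species.copy()
        bonds_s = bonds.copy()
        angles_s = angles.copy()
        inv = np.empty(n, dtype=np.int64)
        pos_ref = np.empty((n, 3))
        cap = max(int(n * 9.0 * rlist * rlist * rlist), 4096)
        pair_i = np.empty(cap, dtype=np.int32)
        pair_j = np.empty(cap, dtype=np.int32)
        pair_a = np.empty(cap)
        pair_key = np.empty(cap, dtype=np.uint64)
        npair = -2  # force rebuild on entry
        tmp3 = np.empty((n, 3))
        tmp1 = np.empty(n, dtype=np.int8)
        tmpg = np.empty(n, dtype=np.int64)
        for s in range(n_steps):
            step = step0 + s + 1
            for i in range(n):
                for d in range(3):
                    x = pos_s[i, d] + dt * vel_s[i, d] + 0.5 * dt * dt * frc_s[i, d]
                    L = box[d]
                    x -= L * np.floor(x / L)
                    pos_s[i, d] = x
            # neighbour-list validity: any displacement beyond half the skin
            rebuild = npair < 0
            if not rebuild:
                for i in range(n):
                    ddx = _min_image(pos_s[i, 0] - pos_ref[i, 0], box[0])
                    ddy = _min_image(pos_s[i, 1] - pos_ref[i, 1], box[1])
                    ddz = _min_image(pos_s[i, 2] - pos_ref[i, 2], box[2])
                    if ddx * ddx + ddy * ddy + ddz * ddz > half_skin2:
                        rebuild = True
                        break
            if rebuild:
                order, _st, _a, _b, _c = _cell_sort(pos_s, box, rlist)
                for t in range(n):
                    o = order[t]
                    tmp3[t, 0] = pos_s[o, 0]
                    tmp3[t, 1] = pos_s[o, 1]
                    tmp3[t, 2] = pos_s[o, 2]
                pos_s[:, :] = tmp3
                for t in range(n):
                    o = order[t]
                    tmp3[t, 0] = vel_s[o, 0]
                    tmp3[t, 1] = vel_s[o, 1]
                    tmp3[t, 2] = vel_s[o, 2]
                vel_s[:, :] = tmp3
                for t in range(n):
                    o = order[t]
                    tmp3[t, 0] = frc_s[o, 0]
                    tmp3[t, 1] = frc_s[o, 1]
                    tmp3[t, 2] = frc_s[o, 2]
                frc_s[:, :] = tmp3
                for t in range(n):
                    o = order[t]
                    tmp1[t] = spec_s[o]
                    tmpg[t] = gid[o]
                spec_s[:] = tmp1
                gid[:] = tmpg
                for t in range(n):
                    inv[gid[t]] = t
                for b in range(bonds.shape[0]):
                    bonds_s[b, 0] = inv[bonds[b, 0]]
                    bonds_s[b, 1] = inv[bonds[b, 1]]
                for a in range(angles.shape[0]):
                    angles_s[a, 0] = inv[angles[a, 0]]
                    angles_s[a, 1] = inv[angles[a, 1]]
                    angles_s[a, 2] = inv[angles[a, 2]]
                npair = _build_pair_list(
                    pos_s, box, rlist, spec_s, gid, amat,
                    pair_i, pair_j, pair_a, pair_key,
                )
                while npair < 0:
                    cap *= 2
                    pair_i = np.empty(cap, dtype=np.int32)
                    pair_j = np.empty(cap, dtype=np.int32)
                    pair_a = np.empty(cap)
                    pair_key = np.empty(cap, dtype=np.uint64)
                    npair = _build_pair_list(
                        pos_s, box, rlist, spec_s, gid, amat,
                        pair_i, pair_j, pair_a, pair_key,
                    )
                pos_ref[:, :] = pos_s
            # predicted velocities for the dissipative force
            for i in range(n):
                for d in range(3):
                    tmp3[i, d] = vel_s[i, d] + lam * dt * frc_s[i, d]
            fnew = np.zeros((n, 3))
            hstep = _step_hash(seed, step)
            ep, nov = _pair_forces_list(
                pos_s, tmp3, gamma, sigma, inv_sqrt_dt, box, rc, fnew,
                hstep, npair, pair_i, pair_j, pair_a, pair_key, True,
            )
            eb = bond_forces(pos_s, bonds_s, ks, rs, box, fnew)
            ea = angle_forces(pos_s, angles_s, k_theta, theta0, box, fnew)
            n_ov_tot += nov
            for i in range(n):
                for d in range(3):
                    vel_s[i, d] += 0.5 * dt * (frc_s[i, d] + fnew[i, d])
                    frc_s[i, d] = fnew[i, d]
            if step % energy_stride == 0 and n_rec < e_step.shape[0]:
                ke = 0.0
                for i in range(n):
                    ke += (
                        vel_s[i, 0] * vel_s[i, 0]
                        + vel_s[i, 1] * vel_s[i, 1]
                        + vel_s[i, 2] * vel_s[i, 2]
                    )
                e_step[n_rec] = step
                e_kin[n_rec] = 0.5 * ke
                e_pair[n_rec] = ep
                e_bond[n_rec] = eb
                e_angle[n_rec] = ea
                n_rec += 1
        # scatter back to canonical order
        for t in range(n):
            g = gid[t]
            pos[g, 0] = pos_s[t, 0]
            pos[g, 1] = pos_s[t, 1]
            pos[g, 2] = pos_s[t, 2]
            vel[g, 0] = vel_s[t, 0]
            vel[g, 1] = vel_s[t, 1]
            vel[g, 2] = vel_s[t, 2]
            forces[g, 0] = frc_s[t, 0]
            forces[g, 1] = frc_s[t, 1]
            forces[g, 2] = frc_s[t, 2]
        return n_rec, n_ov_tot
    # small-box path: plain all-pairs every step, canonical order
    for s in range(n_steps):
        step = step0 + s + 1
        for i in range(n):
            for d in range(3):
                x = pos[i, d] + dt * vel[i, d] + 0.5 * dt * dt * forces[i, d]
                L = box[d]
                x -= L * np.floor(x / L)
                pos[i, d] = x
        vtilde = np.empty((n, 3))
        for i in range(n):
            for d in range(3):
                vtilde[i, d] = vel[i, d] + lam * dt * forces[i, d]
        fnew, ep, eb, ea, nov = compute_forces(
            pos, vtilde, species, bonds, angles, amat, gamma, sigma, dt,
            ks, rs, k_theta, theta0, box, rc, seed, step, True, False,
        )
        n_ov_tot += nov
        for i in range(n):
            for d in range(3):
                vel[i, d] += 0.5 * dt * (forces[i, d] + fnew[i, d])
                forces[i, d] = fnew[i, d]
        if step % energy_stride == 0 and n_rec < e_step.shape[0]:
            ke = 0.0
            for i in range(n):
                ke += (
                    vel[i, 0] * vel[i, 0]
                    + vel[i, 1] * vel[i, 1]
                    + vel[i, 2] * vel[i, 2]
                )
            e_step[n_rec] = step
            e_kin[n_rec] = 0.5 * ke
            e_pair[n_rec] = ep
            e_bond[n_rec] = eb
            e_angle[n_rec] = ea
            n_rec += 1
    return n_rec, n_ov_tot


# ----------------------------------------------------------------------------
# Slab-resolved virial (Irving-Kirkwood straight-contour apportionment)


@njit(cache=True, inline="always")
def _apportion_segment(z0, dz, Lz, n_slabs, weights):
    """Length fractions of the segment z0 -> z0+dz inside each periodic z-slab."""
    for s in range(n_slabs):
        weights[s] = 0.0
    h = Lz / n_slabs
    if abs(dz) < 1e-12:
        s = int(z0 / h) % n_slabs
        weights[s] = 1.0
        return
    lo = z0 if dz > 0 else z0 + dz
    hi = z0 + dz if dz > 0 else z0
    total = hi - lo
    s_lo = int(np.floor(lo / h))
    s_hi = int(np.floor(hi / h))
    for s in range(s_lo, s_hi + 1):
        seg_lo = max(lo, s * h)
        seg_hi = min(hi, (s + 1) * h)
        if seg_hi > seg_lo:
            weights[s % n_slabs] += (seg_hi - seg_lo) / total


@njit(cache=True, inline="always")
def _pair_virial_slab(pos, i, j, fx, fy, fz, box, n_slabs, y_lo, y_hi, vir, wbuf):
    """Add F_ij^a r_ij^a of one interaction leg to the per-slab virial.

    The contribution is spread along the straight ij contour by the length
    fraction in each z-slab.  With a y-window active, inclusion is decided by
    the (periodic) midpoint y of the pair.
    """
    dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
    dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
    dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
    if y_hi > y_lo:
        ymid = pos[j, 1] + 0.5 * dy
        ymid -= box[1] * np.floor(ymid / box[1])
        if ymid < y_lo or ymid >= y_hi:
            return
    _apportion_segment(pos[j, 2], dz, box[2], n_slabs, wbuf)
    wxx = fx * dx
    wyy = fy * dy
    wzz = fz * dz
    for s in range(n_slabs):
        if wbuf[s] > 0.0:
            vir[s, 0] += wbuf[s] * wxx
            vir[s, 1] += wbuf[s] * wyy
            vir[s, 2] += wbuf[s] * wzz


@njit(cache=True, inline="always")
def _cons_pair_virial(pos, i, j, species, amat, box, rc, n_slabs, y_lo, y_hi, vir, wbuf):
    dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
    dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
    dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
    r2 = dx * dx + dy * dy + dz * dz
    if r2 >= rc * rc or r2 < 1e-24:
        return
    r = np.sqrt(r2)
    fmag = amat[species[i], species[j]] * (1.0 - r / rc) / r
    _pair_virial_slab(
        pos, i, j, fmag * dx, fmag * dy, fmag * dz,
        box, n_slabs, y_lo, y_hi, vir, wbuf,
    )


@njit(cache=True)
def stress_slabs(
    pos, vel, species, bonds, angles, amat, ks, rs, k_theta, theta0,
    box, rc, n_slabs, y_lo, y_hi, use_cells,
):
    """Per-z-slab kinetic + virial diagonal of the pressure tensor.

    Only conservative pair, bond and angle forces enter the virial (the
    thermostat's dissipative/random forces average to noise at equilibrium).
    Returns (kin, vir), each (n_slabs, 3); p_aa(slab) = (kin + vir) / V_slab.
    Pass y_hi <= y_lo to disable the y-window.
    """
    n = pos.shape[0]
    kin = np.zeros((n_slabs, 3))
    vir = np.zeros((n_slabs, 3))
    wbuf = np.empty(n_slabs)
    h = box[2] / n_slabs
    for i in range(n):
        if y_hi > y_lo and (pos[i, 1] < y_lo or pos[i, 1] >= y_hi):
            continue
        s = int(pos[i, 2] / h) % n_slabs
        kin[s, 0] += vel[i, 0] * vel[i, 0]
        kin[s, 1] += vel[i, 1] * vel[i, 1]
        kin[s, 2] += vel[i, 2] * vel[i, 2]
    if use_cells:
        order, start, ncx, ncy, ncz = _cell_sort(pos, box, rc)
        ord64 = order.astype(np.int64)
        pos_s = pos[ord64]
        spec_s = species[ord64]
        for cx in range(ncx):
            for cy in range(ncy):
                for cz in range(ncz):
                    c = (cx * ncy + cy) * ncz + cz
                    a0 = start[c]
                    a1 = start[c + 1]
                    for koff in range(14):
                        if koff == 13:
                            b0 = a0
                            b1 = a1
                            self_cell = True
                        else:
                            ox = (cx + _HALF_OFFSETS[koff, 0]) % ncx
                            oy = (cy + _HALF_OFFSETS[koff, 1]) % ncy
                            oz = (cz + _HALF_OFFSETS[koff, 2]) % ncz
                            c2 = (ox * ncy + oy) * ncz + oz
                            b0 = start[c2]
                            b1 = start[c2 + 1]
                            self_cell = False
                        for ii in range(a0, a1):
                            j0 = ii + 1 if self_cell else b0
                            for jj in range(j0, b1):
                                _cons_pair_virial(
                                    pos_s, ii, jj, spec_s, amat, box, rc,
                                    n_slabs, y_lo, y_hi, vir, wbuf,
                                )
    else:
        for i in range(n):
            for j in range(i + 1, n):
                _cons_pair_virial(
                    pos, i, j, species, amat, box, rc,
                    n_slabs, y_lo, y_hi, vir, wbuf,
                )
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = _min_image(pos[i, 0] - pos[j, 0], box[0])
        dy = _min_image(pos[i, 1] - pos[j, 1], box[1])
        dz = _min_image(pos[i, 2] - pos[j, 2], box[2])
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            continue
        fmag = ks * (1.0 - r / rs) / r
        _pair_virial_slab(
            pos, i, j, fmag * dx, fmag * dy, fmag * dz,
            box, n_slabs, y_lo, y_hi, vir, wbuf,
        )
    # angles: decompose the 3-body force into the two bond legs (i,j), (k,j)
    for a in range(angles.shape[0]):
        i = angles[a, 0]
        j = angles[a, 1]
        k = angles[a, 2]
        fix, fiy, fiz, fkx, fky, fkz, _e = _angle_triple(
            pos, i, j, k, k_theta, theta0, box
        )
        _pair_virial_slab(pos, i, j, fix, fiy, fiz, box, n_slabs, y_lo, y_hi, vir, wbuf)
        _pair_virial_slab(pos, k, j, fkx, fky, fkz, box, n_slabs, y_lo, y_hi, vir, wbuf)
    return kin, vir
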