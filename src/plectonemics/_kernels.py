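"""Numba kernels for the fixed-linking-number twistable wormlike-chain MC.

The chain is a string of beads with fixed bond length ``a``; twist is
implicit (energy from ΔLk − Wr), so the writhe Wr must be tracked exactly.
Writhe uses the exact pairwise solid-angle formula of Klenin & Langowski
evaluated over all non-adjacent segment pairs; Monte Carlo moves update Wr
incrementally by recomputing only the pair terms that involve a moved
segment (rigid-rotation invariance of the Gauss integral makes all other
terms cancel).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_EPS = 1e-12
_TWO_PI = 2.0 * math.pi
_HALF_PI = 0.5 * math.pi


@njit(cache=True, fastmath=True, inline="always")
def _atan01(r):
    """Polynomial atan on [0, 1]; max error 7e-9 (Chebyshev fit)."""
    t = r * r
    return r * (
        0.9999999055342192
        + t
        * (
            -0.33332657782866415
            + t
            * (
                0.19986536343211034
                + t
                * (
                    -0.14164325191245328
                    + t
                    * (
                        0.10507289385987574
                        + t
                        * (
                            -0.0724788744055006
                            + t
                            * (
                                0.03989881857707091
                                + t
                                * (
                                    -0.014458239194439094
                                    + t * 0.0024681309247283913
                                )
                            )
                        )
                    )
                )
            )
        )
    )


@njit(cache=True, fastmath=True, inline="always")
def _fast_atan2(y, x):
    """atan2 via the [0,1] polynomial; adequate for writhe pair terms."""
    ax = abs(x)
    ay = abs(y)
    if ax >= ay:
        if ax < _EPS:
            return 0.0
        ang = _atan01(ay / ax)
    else:
        ang = _HALF_PI - _atan01(ax / ay)
    if x < 0.0:
        ang = math.pi - ang
    if y < 0.0:
        return -ang
    return ang


@njit(cache=True, fastmath=True, inline="always")
def _pw(ax, ay, az, bx, by, bz, cx, cy, cz, dx, dy, dz):
    """Writhe contribution of one unordered pair of segments a→b, c→d.

    The signed solid angle of the Gauss-map quadrilateral spanned by the
    four endpoint directions, evaluated as two spherical triangles with the
    van Oosterom–Strackee formula; equivalent to the Klenin–Langowski
    pairwise result and exact for straight segments.
    """
    e13x = cx - ax
    e13y = cy - ay
    e13z = cz - az
    e14x = dx - ax
    e14y = dy - ay
    e14z = dz - az
    e23x = cx - bx
    e23y = cy - by
    e23z = cz - bz
    e24x = dx - bx
    e24y = dy - by
    e24z = dz - bz
    n13 = math.sqrt(e13x * e13x + e13y * e13y + e13z * e13z)
    n14 = math.sqrt(e14x * e14x + e14y * e14y + e14z * e14z)
    n23 = math.sqrt(e23x * e23x + e23y * e23y + e23z * e23z)
    n24 = math.sqrt(e24x * e24x + e24y * e24y + e24z * e24z)
    if n13 < _EPS or n14 < _EPS or n23 < _EPS or n24 < _EPS:
        return 0.0
    e13x /= n13
    e13y /= n13
    e13z /= n13
    e14x /= n14
    e14y /= n14
    e14z /= n14
    e23x /= n23
    e23y /= n23
    e23z /= n23
    e24x /= n24
    e24y /= n24
    e24z /= n24
    # triangle (e13, e14, e24)
    tp1 = (
        e13x * (e14y * e24z - e14z * e24y)
        + e13y * (e14z * e24x - e14x * e24z)
        + e13z * (e14x * e24y - e14y * e24x)
    )
    d1 = (
        1.0
        + (e13x * e14x + e13y * e14y + e13z * e14z)
        + (e14x * e24x + e14y * e24y + e14z * e24z)
        + (e24x * e13x + e24y * e13y + e24z * e13z)
    )
    # triangle (e13, e24, e23)
    tp2 = (
        e13x * (e24y * e23z - e24z * e23y)
        + e13y * (e24z * e23x - e24x * e23z)
        + e13z * (e24x * e23y - e24y * e23x)
    )
    d2 = (
        1.0
        + (e13x * e24x + e13y * e24y + e13z * e24z)
        + (e24x * e23x + e24y * e23y + e24z * e23z)
        + (e23x * e13x + e23y * e13y + e23z * e13z)
    )
    # Ω_triangle = 2·atan2(·); pair term is −(Ω1 + Ω2)/2π
    return -(_fast_atan2(tp1, d1) + _fast_atan2(tp2, d2)) / math.pi


@njit(cache=True, fastmath=True, inline="always")
def _seg_pair(pos, s, t):
    return _pw(
        pos[s, 0],
        pos[s, 1],
        pos[s, 2],
        pos[s + 1, 0],
        pos[s + 1, 1],
        pos[s + 1, 2],
        pos[t, 0],
        pos[t, 1],
        pos[t, 2],
        pos[t + 1, 0],
        pos[t + 1, 1],
        pos[t + 1, 2],
    )


@njit(cache=True, fastmath=True)
def total_writhe(pos):
    """Writhe of the open chain (double sum over non-adjacent segment pairs)."""
    ns = pos.shape[0] - 1
    w = 0.0
    for s in range(ns - 2):
        for t in range(s + 2, ns):
            w += _seg_pair(pos, s, t)
    return w


@njit(cache=True, fastmath=True)
def _cross_writhe(pos, s0, s1):
    """Sum of pair terms with exactly one segment inside the block [s0, s1)."""
    ns = pos.shape[0] - 1
    w = 0.0
    for s in range(s0, s1):
        for t in range(min(s - 1, s0)):
            w += _seg_pair(pos, t, s)
        for t in range(max(s + 2, s1), ns):
            w += _seg_pair(pos, s, t)
    return w


@njit(cache=True, fastmath=True)
def _boundary_intra_writhe(pos, s0, s1):
    """Intra-block pair terms that involve a deforming boundary segment."""
    w = 0.0
    for t in range(s0 + 2, s1):
        w += _seg_pair(pos, s0, t)
    for s in range(s0 + 1, s1 - 2):
        w += _seg_pair(pos, s, s1 - 1)
    return w


@njit(cache=True, fastmath=True)
def loop_writhe(pos, bi, bj):
    """Writhe of the subchain bi..bj closed by the straight chord bj→bi."""
    w = 0.0
    for s in range(bi, bj - 1):
        for t in range(s + 2, bj):
            w += _seg_pair(pos, s, t)
    for s in range(bi + 1, bj - 1):
        w += _pw(
            pos[s, 0],
            pos[s, 1],
            pos[s, 2],
            pos[s + 1, 0],
            pos[s + 1, 1],
            pos[s + 1, 2],
            pos[bj, 0],
            pos[bj, 1],
            pos[bj, 2],
            pos[bi, 0],
            pos[bi, 1],
            pos[bi, 2],
        )
    return w


@njit(cache=True, fastmath=True, inline="always")
def _joint_cos(pos, b):
    """Cosine of the bend angle at joint b (phantom ẑ tangents at the ends)."""
    nb = pos.shape[0]
    if b == 0:
        ux = 0.0
        uy = 0.0
        uz = 1.0
    else:
        ux = pos[b, 0] - pos[b - 1, 0]
        uy = pos[b, 1] - pos[b - 1, 1]
        uz = pos[b, 2] - pos[b - 1, 2]
        un = math.sqrt(ux * ux + uy * uy + uz * uz)
        ux /= un
        uy /= un
        uz /= un
    if b == nb - 1:
        vx = 0.0
        vy = 0.0
        vz = 1.0
    else:
        vx = pos[b + 1, 0] - pos[b, 0]
        vy = pos[b + 1, 1] - pos[b, 1]
        vz = pos[b + 1, 2] - pos[b, 2]
        vn = math.sqrt(vx * vx + vy * vy + vz * vz)
        vx /= vn
        vy /= vn
        vz /= vn
    return ux * vx + uy * vy + uz * vz


@njit(cache=True, fastmath=True)
def bending_energy_kT(pos, bend_persistence, a):
    """Total bending energy (A/a)·Σ(1 − cos θ) in k_BT, end clamps included."""
    nb = pos.shape[0]
    e = 0.0
    for b in range(nb):
        e += 1.0 - _joint_cos(pos, b)
    return bend_persistence / a * e


@njit(cache=True, fastmath=True)
def min_nonadjacent_distance(pos, ex_sep=1):
    """Minimum distance between beads with contour separation > ex_sep."""
    nb = pos.shape[0]
    best = 1e300
    for i in range(nb - 2):
        for j in range(i + 1 + ex_sep, nb):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 < best:
                best = d2
    return math.sqrt(best)


@njit(cache=True, fastmath=True, inline="always")
def _rotate_block(pos, newpos, b0, b1, px, py, pz, kx, ky, kz, angle):
    """Rodrigues rotation of beads [b0, b1) about axis k through point p."""
    c = math.cos(angle)
    s = math.sin(angle)
    for b in range(b0, b1):
        vx = pos[b, 0] - px
        vy = pos[b, 1] - py
        vz = pos[b, 2] - pz
        kv = kx * vx + ky * vy + kz * vz
        cxv = ky * vz - kz * vy
        cyv = kz * vx - kx * vz
        czv = kx * vy - ky * vx
        newpos[b, 0] = px + vx * c + cxv * s + kx * kv * (1.0 - c)
        newpos[b, 1] = py + vy * c + cyv * s + ky * kv * (1.0 - c)
        newpos[b, 2] = pz + vz * c + czv * s + kz * kv * (1.0 - c)


@njit(cache=True, fastmath=True)
def _ev_clash(pos, newpos, b0, b1, d2, ex_sep):
    """True if any bead in newpos[b0:b1) comes within √d2 of an outside
    bead at contour separation > ex_sep."""
    nb = pos.shape[0]
    for b in range(b0, b1):
        x = newpos[b, 0]
        y = newpos[b, 1]
        z = newpos[b, 2]
        for t in range(0, b0):
            if b - t > ex_sep:
                dx = x - pos[t, 0]
                dy = y - pos[t, 1]
                dz = z - pos[t, 2]
                if dx * dx + dy * dy + dz * dz < d2:
                    return True
        for t in range(b1, nb):
            if t - b > ex_sep:
                dx = x - pos[t, 0]
                dy = y - pos[t, 1]
                dz = z - pos[t, 2]
                if dx * dx + dy * dy + dz * dz < d2:
                    return True
    return False


@njit(cache=True, inline="always")
def _draw_move(
    nb, max_block, max_pivot, p_crank, p_cluster, bridged, c_lo, c_hi,
    theta_crank, theta_pivot,
):
    """Draw one move proposal: type, beads moved, segments moved, angle.

    The proposal density is independent of the chain state and symmetric
    under move reversal (the rotation angle is uniform on ±θ_max), which
    together with Metropolis acceptance gives detailed balance.
    Returns (mtype, i, j, k, b0, b1, s0, s1, rigid, angle).
    """
    ns = nb - 1
    u = np.random.random()
    if bridged and u < p_cluster and c_lo >= 2 and c_hi <= nb - 3:
        mtype = 2
        i = np.random.randint(0, c_lo - 1)
        j = np.random.randint(c_hi + 2, nb)
        k = -1
        b0 = i + 1
        b1 = j
        s0 = i
        s1 = j
        rigid = 0
        theta = theta_crank
        blk = j - i
    elif u < p_crank:
        mtype = 0
        blk = 2 + np.random.randint(0, max_block - 1)
        i = np.random.randint(0, nb - blk)
        j = i + blk
        k = -1
        b0 = i + 1
        b1 = j
        s0 = i
        s1 = j
        rigid = 0
        theta = theta_crank
    else:
        mtype = 1
        blk = 1 + np.random.randint(0, max_pivot)
        i = -1
        j = -1
        if np.random.random() < 0.5:
            k = nb - 1 - blk
            b0 = k + 1
            b1 = nb
            s0 = k
            s1 = ns
        else:
            k = blk
            b0 = 0
            b1 = k
            s0 = 0
            s1 = k
        rigid = 1
        theta = theta_pivot
    # larger blocks get proportionally smaller angles so that the
    # acceptance stays roughly uniform across block sizes
    if blk > 4:
        theta = theta * 2.0 / math.sqrt(blk)
    angle = (2.0 * np.random.random() - 1.0) * theta
    return mtype, i, j, k, b0, b1, s0, s1, rigid, angle


@njit(cache=True)
def sample_proposals(
    n, seed, nb, max_block, max_pivot, p_crank, p_cluster, bridged, c_lo, c_hi,
    theta_crank, theta_pivot,
):
    """Draw ``n`` proposals from the move generator (for statistics tests)."""
    np.random.seed(seed)
    mtypes = np.empty(n, np.int64)
    b0s = np.empty(n, np.int64)
    b1s = np.empty(n, np.int64)
    angles = np.empty(n)
    for idx in range(n):
        mtype, i, j, k, b0, b1, s0, s1, rigid, angle = _draw_move(
            nb, max_block, max_pivot, p_crank, p_cluster, bridged, c_lo, c_hi,
            theta_crank, theta_pivot,
        )
        mtypes[idx] = mtype
        b0s[idx] = b0
        b1s[idx] = b1
        angles[idx] = angle
    return mtypes, b0s, b1s, angles


@njit(cache=True)
def assign_states_hysteresis(x, levels, hysteresis):
    """Sticky nearest-level assignment of a filtered trace.

    The assignment switches to a different level only once the signal comes
    within ``hysteresis`` of that level, which suppresses spurious toggling
    when the signal sits between two levels.
    """
    n = x.size
    m = levels.size
    out = np.empty(n, np.int64)
    # start at the nearest level
    best = 0
    bd = abs(x[0] - levels[0])
    for k in range(1, m):
        d = abs(x[0] - levels[k])
        if d < bd:
            bd = d
            best = k
    cur = best
    for i in range(n):
        best = 0
        bd = abs(x[i] - levels[0])
        for k in range(1, m):
            d = abs(x[i] - levels[k])
            if d < bd:
                bd = d
                best = k
        if best != cur and bd < hysteresis:
            cur = best
        out[i] = cur
    return out


@njit(cache=True)
def run_mc(
    pos,
    delta_lk,
    a,
    bend_A,
    twist_C,
    kT,
    force,
    d_ex,
    n_steps,
    stride,
    snap_stride,
    seed,
    theta_crank,
    theta_pivot,
    max_block,
    max_pivot,
    p_crank,
    p_cluster,
    bridge_i,
    bridge_j,
    wr_sentinel,
    sub_step_rad,
):
    """Metropolis MC of the fixed-ΔLk chain; returns sampled observables.

    ``pos`` is modified in place and left at the final conformation. When
    ``bridge_i >= 0`` the beads bridge_i±1 and bridge_j±1 form a rigid
    cluster whose relative pose is preserved: ordinary moves must leave the
    cluster untouched, and dedicated large crankshaft moves rotate it
    rigidly together with the enclosed loop.
    """
    np.random.seed(seed)
    nb = pos.shape[0]
    ns = nb - 1
    L = ns * a
    kb_pref = bend_A / a
    kt_pref = 2.0 * math.pi**2 * twist_C / L
    beta_f = force / kT
    d2 = d_ex * d_ex
    # hard-core checks skip contour neighbours that can never clear d_ex
    ex_sep = max(1, int(d_ex / a + 1e-9))
    bridged = bridge_i >= 0
    c_lo = bridge_i - 1
    c_hi = bridge_j + 1

    wr = total_writhe(pos)
    n_samp = (n_steps + stride - 1) // stride
    z_s = np.empty(n_samp)
    wr_s = np.empty(n_samp)
    lwr_s = np.full(n_samp, np.nan)
    n_snap = (n_steps + snap_stride - 1) // snap_stride
    snaps = np.empty((n_snap, nb, 3))
    newpos = np.empty((nb, 3))
    prop = np.zeros(3, np.int64)
    acc = np.zeros(3, np.int64)

    for step in range(n_steps):
        # sampling happens every `stride` steps whatever the move outcome
        if step % stride == 0:
            idx = step // stride
            z_s[idx] = pos[nb - 1, 2] - pos[0, 2]
            wr_s[idx] = wr
            if bridged:
                lwr_s[idx] = loop_writhe(pos, bridge_i, bridge_j)
        if step % snap_stride == 0:
            snaps[step // snap_stride] = pos

        mtype, i, j, k, b0, b1, s0, s1, rigid, angle = _draw_move(
            nb, max_block, max_pivot, p_crank, p_cluster, bridged, c_lo, c_hi,
            theta_crank, theta_pivot,
        )
        prop[mtype] += 1

        if bridged and mtype != 2:
            # ordinary moves must not touch the bridge cluster
            if not (b1 <= c_lo or b0 > c_hi):
                continue

        if mtype == 1:
            # random axis through the pivot bead
            kx = np.random.normal()
            ky = np.random.normal()
            kz = np.random.normal()
            kn = math.sqrt(kx * kx + ky * ky + kz * kz)
            if kn < _EPS:
                continue
            kx /= kn
            ky /= kn
            kz /= kn
            px = pos[k, 0]
            py = pos[k, 1]
            pz = pos[k, 2]
        else:
            kx = pos[j, 0] - pos[i, 0]
            ky = pos[j, 1] - pos[i, 1]
            kz = pos[j, 2] - pos[i, 2]
            kn = math.sqrt(kx * kx + ky * ky + kz * kz)
            if kn < _EPS:
                continue
            kx /= kn
            ky /= kn
            kz /= kn
            px = pos[i, 0]
            py = pos[i, 1]
            pz = pos[i, 2]

        # excluded volume at the final angle first (cheap rejection) ...
        _rotate_block(pos, newpos, b0, b1, px, py, pz, kx, ky, kz, angle)
        if _ev_clash(pos, newpos, b0, b1, d2, ex_sep):
            continue
        # ... then along the swept rotation (topology guard)
        n_sub = int(abs(angle) / sub_step_rad) + 1
        clash = False
        for m in range(1, n_sub):
            _rotate_block(
                pos, newpos, b0, b1, px, py, pz, kx, ky, kz, angle * m / n_sub
            )
            if _ev_clash(pos, newpos, b0, b1, d2, ex_sep):
                clash = True
                break
        if clash:
            continue
        _rotate_block(pos, newpos, b0, b1, px, py, pz, kx, ky, kz, angle)

        # bending energy change at the affected joints
        if mtype == 1:
            if b0 == 0:
                ja = k
                jb = 0
            else:
                ja = k
                jb = nb - 1
        else:
            ja = i
            jb = j
        cos_a_old = _joint_cos(pos, ja)
        cos_b_old = _joint_cos(pos, jb)

        # writhe change: swap in the new block, recompute involved pair terms
        w_old = _cross_writhe(pos, s0, s1)
        if not rigid:
            w_old += _boundary_intra_writhe(pos, s0, s1)
        backup = pos[b0:b1].copy()
        pos[b0:b1] = newpos[b0:b1]
        w_new = _cross_writhe(pos, s0, s1)
        if not rigid:
            w_new += _boundary_intra_writhe(pos, s0, s1)
        dwr = w_new - w_old

        if abs(dwr) > wr_sentinel:
            pos[b0:b1] = backup  # strand-passage sentinel
            continue

        cos_a_new = _joint_cos(pos, ja)
        cos_b_new = _joint_cos(pos, jb)
        d_ebend = kb_pref * (cos_a_old - cos_a_new + cos_b_old - cos_b_new)

        tw_old = delta_lk - wr
        tw_new = tw_old - dwr
        d_etw = kt_pref * (tw_new * tw_new - tw_old * tw_old)

        dz = 0.0
        if mtype == 1:
            if b0 == 0:
                dz = -(pos[0, 2] - backup[0, 2])
            else:
                dz = pos[nb - 1, 2] - backup[b1 - 1 - b0, 2]

        d_e = d_ebend + d_etw - beta_f * dz
        if d_e <= 0.0 or np.random.random() < math.exp(-d_e):
            wr += dwr
            acc[mtype] += 1
        else:
            pos[b0:b1] = backup

    return z_s, wr_s, lwr_s, snaps, prop, acc, wr
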