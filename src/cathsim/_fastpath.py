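"""Compiled session kernel for the standard noisy path-following agent.

Mirrors, step for step, the semantics of ``session.run_session`` +
``session.step`` + ``agents.make_controller`` for the two agent modes
(guided tube fixture / free organ contacts), using a pre-drawn noise array
so the random stream matches the interpreted path.  Cross-path agreement is
asserted by the test suite; if numba is unavailable the package falls back
to the interpreted loop transparently.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - import guard
    from numba import njit

    NUMBA_OK = True
except Exception:  # pragma: no cover
    NUMBA_OK = False

    def njit(*args, **kwargs):  # type: ignore
        def deco(fn):
            return fn

        return deco if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _session_kernel(  # noqa: C901 - one hot loop, intentionally flat
    verts,          # (P, 3) agent path vertices
    cum,            # (P,) cumulative arclength
    lookahead,      # float
    sigma,          # float, angular noise sd
    noise,          # (max_steps, 4) standard normals (unused if sigma == 0)
    guided,         # bool: fixture mode (path is also the fixture)
    radius,         # float: tube radius (guided mode)
    correction,     # bool: position correction (guided mode)
    corr_threshold, # float
    cap_a, cap_d, cap_len2, cap_r,  # capsule/sphere organ arrays
    box_c, box_h,                   # box organ arrays
    start,          # (3,)
    dest,           # (3,)
    eps,            # completion epsilon
    dt,
    step_len,       # base_speed * multiplier * dt
    max_time,
    trace,          # bool: record the tip trajectory
):
    P = verts.shape[0]
    length = cum[P - 1]
    max_steps = noise.shape[0]
    ev_t = np.empty(max_steps)
    ev_pen = np.empty(max_steps)
    ev_seg = np.empty(max_steps, dtype=np.int64)
    ev_org = np.empty(max_steps, dtype=np.int64)
    ev_pos = np.empty((max_steps, 3))
    tips = np.empty((max_steps + 1, 3))
    n_ev = 0
    n_tr = 0

    tip = start.copy()
    if trace:
        tips[0] = tip
        n_tr = 1
    t = 0.0
    eps2 = eps * eps

    # initial containment
    if guided:
        dmin, _, _, _, _, _ = _project(tip, verts, cum)
        inside = dmin <= radius
    else:
        sd, _ = _organ_min(tip, cap_a, cap_d, cap_len2, cap_r, box_c, box_h)
        inside = sd >= 0.0

    completed = False
    k = 0
    while t < max_time - 0.5 * dt:
        dx = tip[0] - dest[0]
        dy = tip[1] - dest[1]
        dz = tip[2] - dest[2]
        if dx * dx + dy * dy + dz * dz <= eps2:
            completed = True
            break

        # --- controller ---
        _, s, _, _, _, _ = _project(tip, verts, cum)
        sl = s + lookahead
        if sl >= length:
            tx, ty, tz = verts[P - 1, 0], verts[P - 1, 1], verts[P - 1, 2]
        else:
            tx, ty, tz = _point_at(sl, verts, cum)
        ax = tx - tip[0]
        ay = ty - tip[1]
        az = tz - tip[2]
        n = np.sqrt(ax * ax + ay * ay + az * az)
        moved = n >= 1e-12
        if moved:
            ax /= n
            ay /= n
            az /= n
            if sigma > 0.0:
                angle = sigma * noise[k, 0]
                vx, vy, vz = noise[k, 1], noise[k, 2], noise[k, 3]
                dot = vx * ax + vy * ay + vz * az
                px = vx - dot * ax
                py = vy - dot * ay
                pz = vz - dot * az
                pn = np.sqrt(px * px + py * py + pz * pz)
                if pn >= 1e-12:
                    px /= pn
                    py /= pn
                    pz /= pn
                    ca = np.cos(angle)
                    sa = np.sin(angle)
                    cx = py * az - pz * ay
                    cy = pz * ax - px * az
                    cz = px * ay - py * ax
                    ax = ax * ca + cx * sa
                    ay = ay * ca + cy * sa
                    az = az * ca + cz * sa

        # --- step ---
        if moved:
            tip = tip + np.array([ax * step_len, ay * step_len, az * step_len])
        else:
            tip = tip.copy()
        t += dt
        k += 1

        if guided:
            d, _, seg, nx, ny, nz = _project(tip, verts, cum)
            inside_new = d <= radius
            if inside and not inside_new:
                ev_t[n_ev] = t
                ev_pen[n_ev] = d - radius
                ev_seg[n_ev] = seg
                ev_org[n_ev] = -1
                ev_pos[n_ev] = tip
                n_ev += 1
            inside = inside_new
            if correction and d > corr_threshold:
                tip = np.array([nx, ny, nz])
                inside = True
        else:
            sd, org = _organ_min(tip, cap_a, cap_d, cap_len2, cap_r, box_c, box_h)
            inside_new = sd >= 0.0
            if inside and not inside_new:
                ev_t[n_ev] = t
                ev_pen[n_ev] = -sd
                ev_seg[n_ev] = -1
                ev_org[n_ev] = org
                ev_pos[n_ev] = tip
                n_ev += 1
            inside = inside_new

        if trace:
            tips[n_tr] = tip
            n_tr += 1

    if completed:
        completion_time = t if t < max_time else max_time
    else:
        completion_time = max_time
    return (
        completed,
        completion_time,
        n_ev,
        ev_t[:n_ev],
        ev_pen[:n_ev],
        ev_seg[:n_ev],
        ev_org[:n_ev],
        ev_pos[:n_ev],
        tips[:n_tr],
    )


@njit(cache=True)
def _project(tip, verts, cum):
    """(distance, arclength, segment, nearest xyz) of tip on the polyline."""
    best_d2 = np.inf
    best_seg = 0
    best_t = 0.0
    for i in range(verts.shape[0] - 1):
        axx = verts[i, 0]
        ayy = verts[i, 1]
        azz = verts[i, 2]
        dxx = verts[i + 1, 0] - axx
        dyy = verts[i + 1, 1] - ayy
        dzz = verts[i + 1, 2] - azz
        len2 = dxx * dxx + dyy * dyy + dzz * dzz
        t = ((tip[0] - axx) * dxx + (tip[1] - ayy) * dyy + (tip[2] - azz) * dzz) / len2
        if t < 0.0:
            t = 0.0
        elif t > 1.0:
            t = 1.0
        px = axx + t * dxx - tip[0]
        py = ayy + t * dyy - tip[1]
        pz = azz + t * dzz - tip[2]
        d2 = px * px + py * py + pz * pz
        if d2 < best_d2:
            best_d2 = d2
            best_seg = i
            best_t = t
    i = best_seg
    seglen = cum[i + 1] - cum[i]
    s = cum[i] + best_t * seglen
    nx = verts[i, 0] + best_t * (verts[i + 1, 0] - verts[i, 0])
    ny = verts[i, 1] + best_t * (verts[i + 1, 1] - verts[i, 1])
    nz = verts[i, 2] + best_t * (verts[i + 1, 2] - verts[i, 2])
    return np.sqrt(best_d2), s, i, nx, ny, nz


@njit(cache=True)
def _point_at(s, verts, cum):
    P = verts.shape[0]
    if s <= 0.0:
        return verts[0, 0], verts[0, 1], verts[0, 2]
    if s >= cum[P - 1]:
        return verts[P - 1, 0], verts[P - 1, 1], verts[P - 1, 2]
    i = 0
    for j in range(1, P):
        if cum[j] > s:
            i = j - 1
            break
    t = (s - cum[i]) / (cum[i + 1] - cum[i])
    return (
        verts[i, 0] + t * (verts[i + 1, 0] - verts[i, 0]),
        verts[i, 1] + t * (verts[i + 1, 1] - verts[i, 1]),
        verts[i, 2] + t * (verts[i + 1, 2] - verts[i, 2]),
    )


@njit(cache=True)
def _organ_min(tip, cap_a, cap_d, cap_len2, cap_r, box_c, box_h):
    """Minimum signed organ distance and flat organ block index."""
    best = np.inf
    best_i = 0
    for i in range(cap_a.shape[0]):
        rx = tip[0] - cap_a[i, 0]
        ry = tip[1] - cap_a[i, 1]
        rz = tip[2] - cap_a[i, 2]
        t = (rx * cap_d[i, 0] + ry * cap_d[i, 1] + rz * cap_d[i, 2]) / cap_len2[i]
        if t < 0.0:
            t = 0.0
        elif t > 1.0:
            t = 1.0
        qx = rx - t * cap_d[i, 0]
        qy = ry - t * cap_d[i, 1]
        qz = rz - t * cap_d[i, 2]
        d = np.sqrt(qx * qx + qy * qy + qz * qz) - cap_r[i]
        if d < best:
            best = d
            best_i = i
    ncap = cap_a.shape[0]
    for i in range(box_c.shape[0]):
        qx = abs(tip[0] - box_c[i, 0]) - box_h[i, 0]
        qy = abs(tip[1] - box_c[i, 1]) - box_h[i, 1]
        qz = abs(tip[2] - box_c[i, 2]) - box_h[i, 2]
        ox = qx if qx > 0.0 else 0.0
        oy = qy if qy > 0.0 else 0.0
        oz = qz if qz > 0.0 else 0.0
        mx = qx
        if qy > mx:
            mx = qy
        if qz > mx:
            mx = qz
        if mx > 0.0:
            mx = 0.0
        d = np.sqrt(ox * ox + oy * oy + oz * oz) + mx
        if d < best:
            best = d
            best_i = ncap + i
    return best, best_i
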