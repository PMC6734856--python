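"""Independent brute-force oracles shared by the unit and acceptance tests.

Everything here is deliberately simple and slow: dense sampling, plain
loops, textbook definitional formulas.  Nothing imports the implementation
paths it is used to check (beyond the data types under test).
"""

import numpy as np


# ---------------------------------------------------------------------------
# dense surface sampling for signed-distance oracles


def fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def surface_samples(organ, spacing: float) -> np.ndarray:
    """Quasi-uniform samples of the primitive surface at ~`spacing` mm."""
    prm = organ.parameters
    if organ.shape == "sphere":
        r = prm["radius_mm"]
        n = max(int(4 * np.pi * r**2 / spacing**2), 100)
        return np.asarray(prm["center_mm"]) + r * fibonacci_sphere(n)
    if organ.shape == "capsule":
        a = np.asarray(prm["p0_mm"], dtype=float)
        b = np.asarray(prm["p1_mm"], dtype=float)
        r = prm["radius_mm"]
        axis = b - a
        L = np.linalg.norm(axis)
        n_cap = max(int(4 * np.pi * r**2 / spacing**2), 100)
        if L == 0:
            return a + r * fibonacci_sphere(n_cap)
        u = axis / L
        # end caps are hemispheres: the inward-facing halves of the end
        # spheres lie inside the capsule and are not surface
        dirs = fibonacci_sphere(n_cap)
        caps_a = a + r * dirs[dirs @ u <= 0.0]
        caps_b = b + r * dirs[dirs @ u >= 0.0]
        w = np.array([1.0, 0.0, 0.0])
        if abs(u @ w) > 0.9:
            w = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(u, w)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(u, e1)
        nz = max(int(L / spacing), 2)
        nt = max(int(2 * np.pi * r / spacing), 8)
        t = np.linspace(0.0, 1.0, nz)
        ang = np.linspace(0.0, 2 * np.pi, nt, endpoint=False)
        T, A = np.meshgrid(t, ang, indexing="ij")
        side = (
            a[None, None, :]
            + T[..., None] * axis[None, None, :]
            + r * (np.cos(A)[..., None] * e1 + np.sin(A)[..., None] * e2)
        ).reshape(-1, 3)
        return np.vstack([side, caps_a, caps_b])
    if organ.shape == "box":
        c = np.asarray(prm["center_mm"], dtype=float)
        h = np.asarray(prm["half_extents_mm"], dtype=float)
        faces = []
        for axis in range(3):
            u, v = [i for i in range(3) if i != axis]
            nu = max(int(2 * h[u] / spacing), 2)
            nv = max(int(2 * h[v] / spacing), 2)
            gu = np.linspace(-h[u], h[u], nu)
            gv = np.linspace(-h[v], h[v], nv)
            U, V = np.meshgrid(gu, gv, indexing="ij")
            for sign in (-1.0, 1.0):
                f = np.zeros((nu * nv, 3))
                f[:, u] = U.ravel()
                f[:, v] = V.ravel()
                f[:, axis] = sign * h[axis]
                faces.append(c + f)
        return np.vstack(faces)
    raise ValueError(f"unsupported shape {organ.shape!r}")


def nearest_sample_distance(points: np.ndarray, samples: np.ndarray) -> np.ndarray:
    """Unsigned distance of each point to the nearest surface sample.

    Chunked over the sample cloud so million-point clouds stay in cache-
    friendly blocks.
    """
    points = np.atleast_2d(points)
    best = np.full(len(points), np.inf)
    for lo in range(0, len(samples), 200_000):
        block = samples[lo:lo + 200_000]
        d2 = (
            ((points**2).sum(axis=1))[:, None]
            - 2.0 * points @ block.T
            + (block**2).sum(axis=1)[None, :]
        )
        best = np.minimum(best, d2.min(axis=1))
    return np.sqrt(np.maximum(best, 0.0))


def polyline_samples(centerline: np.ndarray, spacing: float) -> np.ndarray:
    """Dense resampling of a polyline at ~`spacing` mm."""
    pts = [centerline[:1]]
    for a, b in zip(centerline[:-1], centerline[1:]):
        ln = np.linalg.norm(b - a)
        n = max(int(np.ceil(ln / spacing)), 1)
        t = np.linspace(0.0, 1.0, n + 1)[1:]
        pts.append(a + t[:, None] * (b - a))
    return np.vstack(pts)


# ---------------------------------------------------------------------------
# collision-count reference state machine


def count_excursions(inside_sequence) -> int:
    """Number of inside -> outside transitions in a sampled containment log."""
    count = 0
    prev = None
    for inside in inside_sequence:
        if prev is not None and prev and not inside:
            count += 1
        prev = inside
    return count


# ---------------------------------------------------------------------------
# definitional mixed-design RM-ANOVA (plain loops)


def definitional_rm_anova(data: np.ndarray) -> dict:
    """Textbook SS formulas for a balanced (g, n, m) layout, via raw loops."""
    g, n, m = data.shape
    N = g * n
    grand = data.sum() / data.size

    ss_total = 0.0
    for i in range(g):
        for j in range(n):
            for k in range(m):
                ss_total += (data[i, j, k] - grand) ** 2

    ss_group = 0.0
    for i in range(g):
        mean_i = data[i].sum() / (n * m)
        ss_group += n * m * (mean_i - grand) ** 2

    ss_between_subj = 0.0
    for i in range(g):
        for j in range(n):
            mean_ij = data[i, j].sum() / m
            ss_between_subj += m * (mean_ij - grand) ** 2
    ss_subj_within = ss_between_subj - ss_group

    ss_rep = 0.0
    for k in range(m):
        mean_k = data[:, :, k].sum() / N
        ss_rep += N * (mean_k - grand) ** 2

    ss_inter = 0.0
    for i in range(g):
        mean_i = data[i].sum() / (n * m)
        for k in range(m):
            mean_ik = data[i, :, k].sum() / n
            mean_k = data[:, :, k].sum() / N
            ss_inter += n * (mean_ik - mean_i - mean_k + grand) ** 2

    ss_error = ss_total - ss_group - ss_subj_within - ss_rep - ss_inter
    df = {
        "group": g - 1,
        "subjects_within_groups": N - g,
        "repetition": m - 1,
        "group:repetition": (g - 1) * (m - 1),
        "within_error": (N - g) * (m - 1),
    }
    ms_subj = ss_subj_within / df["subjects_within_groups"]
    ms_error = ss_error / df["within_error"]
    return {
        "ss": {
            "group": ss_group,
            "subjects_within_groups": ss_subj_within,
            "repetition": ss_rep,
            "group:repetition": ss_inter,
            "within_error": ss_error,
            "total": ss_total,
        },
        "df": df,
        "F": {
            "group": (ss_group / df["group"]) / ms_subj,
            "repetition": (ss_rep / df["repetition"]) / ms_error,
            "group:repetition": (ss_inter / df["group:repetition"]) / ms_error,
        },
    }
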