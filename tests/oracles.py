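"""Independent reference implementations used only to check the package.

These deliberately avoid the package's own vectorized code paths: the
objective is summed term by term with explicitly constructed matrices, the
assignment optimum is found by exhaustive enumeration, and the best axis by
a dense unit-sphere grid search plus derivative-free refinement.
"""

import itertools

import numpy as np
from scipy.optimize import minimize


def reference_rotation(axis, angle, improper=False):
    """Rodrigues rotation assembled from the component formula."""
    v = np.asarray(axis, float)
    v = v / np.linalg.norm(v)
    c, s = np.cos(angle), np.sin(angle)
    mat = np.empty((3, 3))
    for a in range(3):
        for b in range(3):
            mat[a, b] = (1 - c) * v[a] * v[b] + (c if a == b else 0.0)
    mat += s * np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    if improper:
        refl = np.eye(3) - 2.0 * np.outer(v, v)
        mat = refl @ mat
    return mat


def reference_objective(q, group, perm, axis):
    """Term-by-term Σ_i Σ_k |T^i q_k − q_{π^i(k)}|² over the group order."""
    q = np.asarray(q, float)
    perm = np.asarray(perm, int)
    total = 0.0
    pi_i = np.arange(len(q))
    for i in range(1, group.order + 1):
        pi_i = perm[pi_i]
        angle = 2 * np.pi * i / group.n
        t_i = reference_rotation(axis, angle, group.improper and i % 2 == 1)
        for k in range(len(q)):
            d = t_i @ q[k] - q[pi_i[k]]
            total += float(d @ d)
    return total


def reference_csm(q, group, perm, axis):
    """S(G) from the reference objective and the centered normalization."""
    q = np.asarray(q, float)
    qc = q - q.mean(axis=0)
    m = reference_objective(qc, group, perm, axis) / (2.0 * group.order)
    norm = float(np.sum(qc * qc))
    return 100.0 * m / norm


def grid_search_axis(q, group, perm, step_deg=2.0):
    """Dense hemisphere grid + Nelder-Mead refinement; returns (axis, value)."""
    q = np.asarray(q, float)
    q = q - q.mean(axis=0)
    theta = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    phi = np.deg2rad(np.arange(0.0, 360.0, step_deg))
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    dirs = np.stack(
        [np.sin(tt) * np.cos(pp), np.sin(tt) * np.sin(pp), np.cos(tt)], axis=-1
    ).reshape(-1, 3)

    # vectorized objective over all grid directions
    perm = np.asarray(perm, int)
    vals = np.zeros(len(dirs))
    pi_i = np.arange(len(q))
    for i in range(1, group.order + 1):
        pi_i = perm[pi_i]
        angle = 2 * np.pi * i / group.n
        c, s = np.cos(angle), np.sin(angle)
        target = q[pi_i]
        # Rodrigues applied per direction: R x = c x + s (v×x) + (1−c)(v·x)v
        vx = np.cross(dirs[:, None, :], q[None, :, :])
        vdotx = dirs @ q.T
        rx = c * q[None] + s * vx + (1 - c) * vdotx[:, :, None] * dirs[:, None, :]
        if group.improper and i % 2 == 1:
            axial = np.einsum("gk,ga->gka", np.einsum("gka,ga->gk", rx, dirs), dirs)
            rx = rx - 2.0 * axial
        diff = rx - target[None]
        vals += np.einsum("gka,gka->g", diff, diff)
    best = dirs[int(np.argmin(vals))]

    res = minimize(
        lambda v: reference_objective(q, group, perm, v / np.linalg.norm(v)),
        best,
        method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 4000},
    )
    axis = res.x / np.linalg.norm(res.x)
    return axis, float(res.fun)


def brute_force_assignment(cost):
    """Exhaustive minimum of Σ_i cost[i, μ(i)] over all permutations."""
    cost = np.asarray(cost, float)
    k = cost.shape[0]
    best_mu, best_val = None, np.inf
    rows = np.arange(k)
    for mu in itertools.permutations(range(k)):
        val = float(cost[rows, list(mu)].sum())
        if val < best_val - 1e-15:
            best_val, best_mu = val, mu
    return np.array(best_mu), best_val
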