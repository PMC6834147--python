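"""Independent reference computations used only by the test suite.

These deliberately take the slow, direct route — full matrix recomputation,
generic optimization, brute-force scans — so they share no code path with
the package implementation they check.
"""

import numpy as np
from scipy.optimize import minimize

from ellipsomol import Sphere, enclosing_sphere, vdm
from ellipsomol.hierarchy import NodeLevel


def naive_cluster_merges(molecule):
    """O(n^3) two-phase average-linkage agglomeration, recomputed each step.

    Dissimilarity between clusters is the mean pair volume metric over all
    leaf-atom pairs, recomputed from scratch at every step (no
    Lance-Williams shortcut).  Returns the merge sequence as a list of
    frozensets of atom indices.
    """
    spheres = [Sphere(a.position, a.radius) for a in molecule.atoms]
    n = len(spheres)
    pair_vdm = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                pair_vdm[i, j] = vdm(spheres[i], spheres[j])

    residue_of = molecule.residue_index_of()
    clusters = {i: frozenset([i]) for i in range(n)}
    next_id = n
    merges = []

    def dissim(a, b):
        return float(np.mean([pair_vdm[i, j] for i in clusters[a] for j in clusters[b]]))

    def same_residue_pair(a, b):
        res = {residue_of[i] for i in clusters[a] | clusters[b]}
        return len(res) == 1

    while len(clusters) > 1:
        ids = sorted(clusters)
        candidates = [(a, b) for ai, a in enumerate(ids) for b in ids[ai + 1:]
                      if same_residue_pair(a, b)]
        if not candidates:  # all residues closed: phase 2
            candidates = [(a, b) for ai, a in enumerate(ids) for b in ids[ai + 1:]]
        best = min(candidates, key=lambda ab: (dissim(*ab), min(ab), max(ab)))
        a, b = best
        merges.append(clusters[a] | clusters[b])
        clusters[next_id] = clusters.pop(a) | clusters.pop(b)
        next_id += 1
    return merges


def mvee_volume_by_convex_opt(points):
    """MVEE volume from a generic convex solver on the D-optimal dual.

    Maximizes log det of the weighted lifted scatter over the probability
    simplex with SLSQP, then converts the optimal weights to the enclosing
    ellipsoid (rescaled so every point is inside).
    """
    P = np.asarray(points, dtype=float)
    n, d = P.shape
    Q = np.column_stack([P, np.ones(n)])

    def neg_logdet(u):
        X = Q.T @ (Q * u[:, None])
        sign, ld = np.linalg.slogdet(X)
        return np.inf if sign <= 0 else -ld

    res = minimize(
        neg_logdet,
        np.full(n, 1.0 / n),
        method="SLSQP",
        bounds=[(0.0, 1.0)] * n,
        constraints=[{"type": "eq", "fun": lambda u: u.sum() - 1.0}],
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    u = np.clip(res.x, 0.0, None)
    u /= u.sum()
    c = P.T @ u
    scatter = P.T @ (P * u[:, None]) - np.outer(c, c)
    A = np.linalg.inv(scatter) / d
    dev = P - c
    q = np.einsum("ij,jk,ik->i", dev, A, dev)
    A = A / q.max()
    evals = np.linalg.eigvalsh(A)
    semi = 1.0 / np.sqrt(evals)
    return (4.0 / 3.0) * np.pi * float(np.prod(semi))


def min_sphere_radius_multistart(spheres, n_starts=32, seed=0):
    """Reference minimal enclosing-sphere radius via multi-start Nelder-Mead."""
    centers = np.array([s.center for s in spheres])
    radii = np.array([s.radius for s in spheres])

    def objective(c):
        return float(np.max(np.linalg.norm(centers - c, axis=1) + radii))

    rng = np.random.default_rng(seed)
    spread = centers.max(axis=0) - centers.min(axis=0) + 1.0
    best = np.inf
    starts = [centers.mean(axis=0)] + [
        centers.mean(axis=0) + rng.normal(scale=spread / 4) for _ in range(n_starts - 1)
    ]
    for c0 in starts:
        res = minimize(objective, c0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
        best = min(best, objective(res.x))
    return best


def brute_force_depth(geometry, camera):
    """Per-pixel nearest-hit depth over all glyphs by scalar ray casting."""
    from ellipsomol import generate_ray, ray_ellipsoid_intersect, ray_sphere_intersect

    depth = np.full((camera.height, camera.width), np.inf)
    for py in range(camera.height):
        for px in range(camera.width):
            ray = generate_ray(camera, px, py)
            for _, kind, shape, _ in geometry:
                hit = (ray_sphere_intersect(ray, shape) if kind == "sphere"
                       else ray_ellipsoid_intersect(ray, shape))
                if hit is not None and hit.t < depth[py, px]:
                    depth[py, px] = hit.t
    return depth
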