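"""Minimum-volume enclosing ellipsoids and minimal enclosing spheres.

Every internal cluster node gets two bounds: the exact minimal sphere
enclosing its member atom spheres (the conventional representation), and a
minimum-volume enclosing ellipsoid (MVEE) that is typically much tighter.
MVEEs are fitted to surface samples: residue-interior and residue nodes
sample every member atom sphere, higher nodes sample their two children's
MVEEs, so inflation does not re-accumulate from raw atoms at every level.

The MVEE solver is the Khachiyan barycentric-coordinate ascent in its
(1+ε)-approximation form: it maximises the determinant of the weighted
scatter of the lift (p, 1), which is the dual of the minimum-volume
ellipsoid problem.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .hierarchy import ClusterTree, NodeLevel, Sphere

__all__ = [
    "Ellipsoid",
    "SamplingConfig",
    "DegenerateInputError",
    "sample_sphere_surface",
    "sample_ellipsoid_surface",
    "mvee",
    "min_enclosing_sphere",
    "annotate_tree",
]

_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


class DegenerateInputError(ValueError):
    """Point set is not affinely full-dimensional (rank < 3)."""


@dataclass(frozen=True)
class Ellipsoid:
    """Ellipsoid as center, orthonormal axis frame, and semi-axis lengths.

    Columns of ``axes`` are the principal directions; ``semi_axes`` are
    sorted descending.  The equivalent quadric is
    (x−c)ᵀ A (x−c) = 1 with A = V diag(λ⁻²) Vᵀ.
    """

    center: np.ndarray  # (3,), Å
    axes: np.ndarray  # (3, 3), orthonormal columns
    semi_axes: np.ndarray  # (3,), Å, descending

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        object.__setattr__(self, "axes", np.asarray(self.axes, dtype=float))
        object.__setattr__(self, "semi_axes", np.asarray(self.semi_axes, dtype=float))
        if not np.allclose(self.axes.T @ self.axes, np.eye(3), atol=1e-8):
            raise ValueError("ellipsoid axes must be orthonormal")
        if np.any(self.semi_axes <= 0) or np.any(np.diff(self.semi_axes) > 1e-12):
            raise ValueError("semi-axes must be positive and sorted descending")

    @classmethod
    def from_sphere(cls, s: Sphere) -> "Ellipsoid":
        r = max(s.radius, 1e-6)
        return cls(center=s.center, axes=np.eye(3), semi_axes=np.full(3, r))

    @classmethod
    def from_quadric(cls, center: np.ndarray, A: np.ndarray) -> "Ellipsoid":
        """Build from the positive-definite quadric matrix A.

        Eigenvalues of A are the reciprocal squared semi-axes.
        """
        evals, evecs = np.linalg.eigh(A)
        if np.any(evals <= 0):
            raise ValueError("quadric matrix must be positive definite")
        semi = 1.0 / np.sqrt(evals)  # eigh ascending -> semi descending
        order = np.argsort(semi)[::-1]
        return cls(center=center, axes=evecs[:, order], semi_axes=semi[order])

    @property
    def quadric(self) -> np.ndarray:
        V, lam = self.axes, self.semi_axes
        return V @ np.diag(1.0 / lam**2) @ V.T

    @property
    def volume(self) -> float:
        return (4.0 / 3.0) * math.pi * float(np.prod(self.semi_axes))

    def contains(self, points: np.ndarray, inflate: float = 1.0, tol: float = 1e-9) -> np.ndarray:
        """Boolean mask: (p−c)ᵀA(p−c) ≤ inflate² (+tol)."""
        d = np.atleast_2d(points) - self.center
        q = np.einsum("ij,jk,ik->i", d, self.quadric, d)
        return q <= inflate**2 + tol


@dataclass(frozen=True)
class SamplingConfig:
    """Surface sampling and MVEE solver parameters."""

    points_per_surface: int = 32
    mvee_tolerance: float = 1e-3
    max_iterations: int = 10_000

    def __post_init__(self) -> None:
        if self.points_per_surface < 4:
            raise ValueError("need at least 4 sample points per surface")
        if self.mvee_tolerance <= 0 or self.max_iterations < 1:
            raise ValueError("mvee_tolerance and max_iterations must be positive")


def sample_sphere_surface(s: Sphere, k: int) -> np.ndarray:
    """k deterministic Fibonacci-lattice points on the sphere surface."""
    if k < 4:
        raise ValueError("k must be >= 4")
    i = np.arange(k)
    z = 1.0 - 2.0 * (i + 0.5) / k
    rho = np.sqrt(np.maximum(0.0, 1.0 - z**2))
    theta = _GOLDEN_ANGLE * i
    unit = np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])
    return s.center + s.radius * unit


def sample_ellipsoid_surface(e: Ellipsoid, k: int) -> np.ndarray:
    """Map unit-sphere lattice samples u -> c + V diag(λ) u."""
    unit = sample_sphere_surface(Sphere(np.zeros(3), 1.0), k)
    return e.center + unit @ np.diag(e.semi_axes) @ e.axes.T


def mvee(points: np.ndarray, cfg: SamplingConfig = SamplingConfig()) -> Ellipsoid:
    """(1+ε)-approximate minimum-volume enclosing ellipsoid of a point set.

    Khachiyan's ascent on the dual weights, stopping once the maximum lifted
    leverage is within (1+ε)(d+1); the result is rescaled so every input
    point lies inside exactly, which keeps the (1+ε)³ volume guarantee.

    Raises :class:`DegenerateInputError` for rank-deficient inputs.
    """
    P = np.atleast_2d(np.asarray(points, dtype=float))
    n, d = P.shape
    if d != 3:
        raise ValueError("points must be 3-dimensional")
    if n < 4:
        raise DegenerateInputError("need at least 4 points for a 3-D MVEE")
    if np.linalg.matrix_rank(P - P.mean(axis=0), tol=1e-9) < 3:
        raise DegenerateInputError("point set is not affinely full-dimensional")

    Q = np.column_stack([P, np.ones(n)])  # lift to (p, 1)
    u = np.full(n, 1.0 / n)
    eps = cfg.mvee_tolerance
    target = (1.0 + eps) * (d + 1)
    for _ in range(cfg.max_iterations):
        X = Q.T @ (Q * u[:, None])
        w = np.einsum("ij,ij->i", Q @ np.linalg.inv(X), Q)  # lifted leverages
        j = int(np.argmax(w))
        kappa = w[j]
        if kappa <= target:
            break
        step = (kappa - d - 1.0) / ((d + 1.0) * (kappa - 1.0))
        u *= 1.0 - step
        u[j] += step

    c = P.T @ u
    scatter = P.T @ (P * u[:, None]) - np.outer(c, c)
    A = np.linalg.inv(scatter) / d
    # Rescale so the farthest point sits exactly on the surface.
    dev = P - c
    qmax = float(np.einsum("ij,jk,ik->i", dev, A, dev).max())
    A = A / qmax
    return Ellipsoid.from_quadric(c, A)


def min_enclosing_sphere(spheres: list[Sphere]) -> Sphere:
    """Exact minimal sphere enclosing a set of spheres.

    Minimises R(c) = max_i (‖c−ci‖ + ri), a convex function, via SLSQP on
    the epigraph form with a deterministic centroid start.
    """
    if not spheres:
        raise ValueError("need at least one sphere")
    if len(spheres) == 1:
        return spheres[0]
    centers = np.array([s.center for s in spheres])
    radii = np.array([s.radius for s in spheres])

    def reach(c: np.ndarray) -> np.ndarray:
        return np.linalg.norm(centers - c, axis=1) + radii

    c0 = centers.mean(axis=0)
    x0 = np.append(c0, reach(c0).max())
    res = minimize(
        lambda x: x[3],
        x0,
        jac=lambda x: np.array([0.0, 0.0, 0.0, 1.0]),
        constraints=[{
            "type": "ineq",
            "fun": lambda x: x[3] - reach(x[:3]),
        }],
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-14},
    )
    c = res.x[:3]
    return Sphere(center=c, radius=float(reach(c).max()))


def _node_min_sphere(node_atoms: frozenset[int], atom_spheres: list[Sphere]) -> Sphere:
    return min_enclosing_sphere([atom_spheres[i] for i in sorted(node_atoms)])


def _mvee_regularized(points: np.ndarray, cfg: SamplingConfig) -> Ellipsoid:
    try:
        return mvee(points, cfg)
    except DegenerateInputError:
        # Pad with tiny axis-aligned offsets around the centroid and retry.
        c = points.mean(axis=0)
        pad = c + 1e-6 * np.vstack([np.eye(3), -np.eye(3)])
        e = mvee(np.vstack([points, pad]), cfg)
        semi = np.maximum(e.semi_axes, 1e-6)
        return Ellipsoid(center=e.center, axes=e.axes, semi_axes=semi)


def annotate_tree(tree: ClusterTree, molecule, cfg: SamplingConfig = SamplingConfig()) -> ClusterTree:
    """Attach an exact minimal sphere and an MVEE to every tree node.

    Leaves carry their atom sphere as a degenerate equal-axis ellipsoid.
    Residue-interior and residue nodes fit the MVEE to surface samples of
    all member atom spheres; residue-link and molecule nodes fit it to
    surface samples of their children's MVEEs.  In-place; returns the tree.
    """
    k = cfg.points_per_surface
    atom_spheres = [Sphere(a.position, a.radius) for a in molecule.atoms]

    for node in sorted(tree.nodes.values(), key=lambda nd: nd.height):
        if node.is_leaf:
            node.bounding_sphere = atom_spheres[next(iter(node.atom_members))]
            node.mvee = Ellipsoid.from_sphere(node.bounding_sphere)
            continue
        node.bounding_sphere = _node_min_sphere(node.atom_members, atom_spheres)
        if node.level in (NodeLevel.RESIDUE_INTERIOR, NodeLevel.RESIDUE):
            samples = np.vstack([
                sample_sphere_surface(atom_spheres[i], k)
                for i in sorted(node.atom_members)
            ])
        else:  # RESIDUE_LINK / MOLECULE: previous level's MVEEs as input
            samples = np.vstack([
                sample_ellipsoid_surface(tree.node(ch).mvee, k)
                for ch in node.children
            ])
        node.mvee = _mvee_regularized(samples, cfg)
    return tree
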