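"""Residue-restricted hierarchical cluster tree with a volume metric.

The tree is built by adjusted agglomerative clustering: atoms belonging to
the same residue merge first, until every residue is one cluster; only then
do residue clusters merge with each other.  Dissimilarity between two atom
spheres is the volume of the smallest sphere enclosing both (the
volume-based distance metric, VDM); between clusters it is the unweighted
average of that quantity over all leaf-atom pairs (UPGMA), maintained
through Lance–Williams updates.  A molecule of n atoms always yields a
complete binary tree of exactly 2n−1 nodes.

Node levels, bottom-up: ATOM (leaves), RESIDUE_INTERIOR (partial residue),
RESIDUE (one whole residue), RESIDUE_LINK (several whole residues),
MOLECULE (the root).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

import numpy as np

if TYPE_CHECKING:
    from .bounding import Ellipsoid
    from .molecule_io import Molecule

__all__ = [
    "Sphere",
    "NodeLevel",
    "ClusterNode",
    "ClusterTree",
    "enclosing_sphere",
    "vdm",
    "build_cluster_tree",
    "subtree_height",
]


@dataclass(frozen=True)
class Sphere:
    center: np.ndarray  # (3,), Å
    radius: float  # Å, >= 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.radius < 0:
            raise ValueError("sphere radius must be non-negative")

    @property
    def volume(self) -> float:
        return (4.0 / 3.0) * math.pi * self.radius**3

    def contains_sphere(self, other: "Sphere", tol: float = 1e-9) -> bool:
        return float(np.linalg.norm(self.center - other.center)) + other.radius <= self.radius + tol


class NodeLevel(enum.Enum):
    ATOM = "atom"
    RESIDUE_INTERIOR = "residue_interior"
    RESIDUE = "residue"
    RESIDUE_LINK = "residue_link"
    MOLECULE = "molecule"


@dataclass
class ClusterNode:
    """One tree node: a leaf atom or the merge of exactly two children."""

    id: int
    level: NodeLevel
    children: Optional[tuple[int, int]]
    atom_members: frozenset[int]
    bounding_sphere: Sphere
    height: int  # longest path down to a leaf (D in the LOD predicate)
    residue_root: bool = False  # cluster == exactly one whole residue
    mvee: Optional["Ellipsoid"] = None  # filled by bounding.annotate_tree

    @property
    def is_leaf(self) -> bool:
        return self.children is None


@dataclass
class ClusterTree:
    nodes: dict[int, ClusterNode]
    root_id: int
    n_atoms: int

    @property
    def root(self) -> ClusterNode:
        return self.nodes[self.root_id]

    def node(self, node_id: int) -> ClusterNode:
        try:
            return self.nodes[node_id]
        except KeyError:
            raise KeyError(f"unknown cluster node id {node_id}") from None

    def leaves(self) -> list[ClusterNode]:
        return [n for n in self.nodes.values() if n.is_leaf]

    def internal_nodes(self) -> list[ClusterNode]:
        return [n for n in self.nodes.values() if not n.is_leaf]

    def level_counts(self) -> dict[NodeLevel, int]:
        counts: dict[NodeLevel, int] = {}
        for n in self.nodes.values():
            counts[n.level] = counts.get(n.level, 0) + 1
        return counts


def enclosing_sphere(a: Sphere, b: Sphere) -> Sphere:
    """Smallest sphere containing both input spheres.

    If one sphere contains the other, the larger is returned unchanged;
    otherwise the result spans both along the line of centers.
    """
    d = float(np.linalg.norm(b.center - a.center))
    if d + b.radius <= a.radius:
        return a
    if d + a.radius <= b.radius:
        return b
    # Radii grouped first: bit-exact symmetry in the arguments.
    radius = 0.5 * (d + (a.radius + b.radius))
    # Center sits on the segment, offset from a toward b.
    u = (b.center - a.center) / d
    center = a.center + (radius - a.radius) * u
    return Sphere(center=center, radius=radius)


def vdm(a: Sphere, b: Sphere) -> float:
    """Volume-based distance metric: volume (Å³) of the pair's enclosing sphere."""
    return enclosing_sphere(a, b).volume


def subtree_height(tree: ClusterTree, node_id: int) -> int:
    """Edges on the longest path from the node down to a leaf (0 for leaves)."""
    return tree.node(node_id).height


def _pairwise_vdm_matrix(spheres: list[Sphere]) -> np.ndarray:
    n = len(spheres)
    centers = np.array([s.center for s in spheres])
    radii = np.array([s.radius for s in spheres])
    d = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=2)
    # Enclosing radius: (d + ri + rj)/2, or the larger radius under containment.
    # The radii sum is grouped first so the matrix is bit-exactly symmetric
    # (the tie scan relies on exact equality of mirrored entries).
    r_enc = 0.5 * (d + (radii[:, None] + radii[None, :]))
    contain_i = d + radii[None, :] <= radii[:, None]  # j inside i
    contain_j = d + radii[:, None] <= radii[None, :]  # i inside j
    r_enc = np.where(contain_i, radii[:, None], r_enc)
    r_enc = np.where(contain_j, radii[None, :], r_enc)
    return (4.0 / 3.0) * math.pi * r_enc**3


def build_cluster_tree(molecule: "Molecule", linkage: str = "average") -> ClusterTree:
    """Build the residue-restricted complete binary cluster tree.

    Phase 1 merges only within-residue pairs until each residue is a single
    cluster; phase 2 merges residue clusters up to the root.  Ties on equal
    dissimilarity break toward the lexicographically smallest
    ``(min node id, max node id)`` pair, so trees are deterministic.
    """
    if linkage != "average":
        raise ValueError(f"unsupported linkage {linkage!r}; only 'average'")
    n = molecule.n_atoms
    if n == 0:
        raise ValueError("cannot cluster an empty molecule")

    atom_spheres = [Sphere(a.position, a.radius) for a in molecule.atoms]
    residue_of = molecule.residue_index_of()
    residue_sizes = np.bincount(residue_of, minlength=molecule.n_residues)

    nodes: dict[int, ClusterNode] = {}
    for i, s in enumerate(atom_spheres):
        nodes[i] = ClusterNode(
            id=i,
            level=NodeLevel.ATOM,
            children=None,
            atom_members=frozenset([i]),
            bounding_sphere=s,
            height=0,
            residue_root=bool(residue_sizes[residue_of[i]] == 1),
        )
    if n == 1:
        return ClusterTree(nodes=nodes, root_id=0, n_atoms=1)

    # Active-slot bookkeeping: slot i holds a live cluster; merges reuse the
    # lower slot.  D is the UPGMA dissimilarity matrix over slots.
    D = _pairwise_vdm_matrix(atom_spheres)
    np.fill_diagonal(D, np.inf)
    active = np.ones(n, dtype=bool)
    slot_node = np.arange(n)  # slot -> current node id
    slot_size = np.ones(n, dtype=int)
    slot_residue = residue_of.copy()  # phase 1 restriction; -1 in phase 2
    slot_sphere: list[Sphere] = list(atom_spheres)

    same_residue = slot_residue[:, None] == slot_residue[None, :]
    allowed = same_residue.copy()
    np.fill_diagonal(allowed, False)

    next_id = n
    n_phase1 = int(np.sum(residue_sizes - 1))  # merges needed to close residues

    for merge_idx in range(n - 1):
        phase1 = merge_idx < n_phase1
        if merge_idx == n_phase1:
            # Phase 2: every live cluster must now be a whole residue.
            live = np.where(active)[0]
            assert all(
                slot_size[s] == residue_sizes[slot_residue[s]] for s in live
            ), "phase 2 reached before all residues closed"
            allowed = np.ones((n, n), dtype=bool)
            np.fill_diagonal(allowed, False)
            allowed[~active, :] = False
            allowed[:, ~active] = False

        masked = np.where(allowed, D, np.inf)
        best = masked.min()
        assert np.isfinite(best), "no admissible merge pair"
        # Deterministic tie-break on node ids among exact minima.
        ii, jj = np.nonzero(masked == best)
        pairs = [(min(slot_node[a], slot_node[b]), max(slot_node[a], slot_node[b]), a, b)
                 for a, b in zip(ii, jj) if a < b]
        pairs.sort()
        _, _, si, sj = pairs[0]

        na, nb = nodes[slot_node[si]], nodes[slot_node[sj]]
        sphere = enclosing_sphere(slot_sphere[si], slot_sphere[sj])
        members = na.atom_members | nb.atom_members
        if phase1:
            res = slot_residue[si]
            whole = len(members) == residue_sizes[res]
            level = NodeLevel.RESIDUE if whole else NodeLevel.RESIDUE_INTERIOR
        else:
            level = NodeLevel.RESIDUE_LINK
        if merge_idx == n - 2:
            level = NodeLevel.MOLECULE
        node = ClusterNode(
            id=next_id,
            level=level,
            children=(na.id, nb.id),
            atom_members=frozenset(members),
            bounding_sphere=sphere,
            height=1 + max(na.height, nb.height),
            residue_root=phase1 and level in (NodeLevel.RESIDUE, NodeLevel.MOLECULE),
        )
        nodes[next_id] = node

        # Lance–Williams UPGMA update into slot si; retire slot sj.
        wi = slot_size[si] / (slot_size[si] + slot_size[sj])
        wj = 1.0 - wi
        newd = wi * D[si, :] + wj * D[sj, :]
        D[si, :] = newd
        D[:, si] = newd
        D[si, si] = np.inf
        active[sj] = False
        D[sj, :] = np.inf
        D[:, sj] = np.inf
        allowed[sj, :] = False
        allowed[:, sj] = False
        slot_node[si] = next_id
        slot_size[si] += slot_size[sj]
        slot_sphere[si] = sphere
        if phase1 and node.residue_root:
            # A closed residue takes no further part in phase 1.
            allowed[si, :] = False
            allowed[:, si] = False
        next_id += 1

    tree = ClusterTree(nodes=nodes, root_id=next_id - 1, n_atoms=n)
    assert len(tree.nodes) == 2 * n - 1
    return tree
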