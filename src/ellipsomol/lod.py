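"""Distance-dependent level-of-detail selection on the cluster tree.

A node C with subtree height D is abstract enough for a camera at distance
``dis`` from its center when

    D <= (dis - inival) / interval

where ``inival`` is the distance at which simplification begins and
``interval`` is the width of each detail band.  The display list is the
frontier of tree nodes found by evaluating this predicate top-down from the
root: a node that passes (or is a leaf) is emitted and its branch pruned,
otherwise both children are visited.  The emitted nodes always partition
the atom set, so no atom is drawn twice or dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .hierarchy import ClusterTree

__all__ = ["LODParams", "DisplayList", "lod_predicate", "select_display_list"]

GlyphKind = Literal["sphere", "ellipsoid"]


@dataclass(frozen=True)
class LODParams:
    """inival: distance (Å) where simplification starts; interval: band width (Å)."""

    inival: float = 100.0
    interval: float = 20.0

    def __post_init__(self) -> None:
        if self.interval <= 0:
            raise ValueError("interval must be positive")


@dataclass(frozen=True)
class DisplayList:
    """Frontier of tree nodes selected for one camera pose."""

    entries: tuple[tuple[int, GlyphKind], ...]

    def __len__(self) -> int:
        return len(self.entries)

    def node_ids(self) -> list[int]:
        return [nid for nid, _ in self.entries]


def lod_predicate(D: int, dis: float, params: LODParams) -> bool:
    """True when subtree height D is admissible at camera distance dis.

    The threshold (dis − inival)/interval is compared as a real number (it
    may be negative, in which case only leaves pass elsewhere).
    """
    return D <= (dis - params.inival) / params.interval


def select_display_list(
    tree: ClusterTree,
    camera_position: np.ndarray,
    params: LODParams,
    glyph_mode: Literal["sphere", "ellipsoid", "vdw"] = "ellipsoid",
) -> DisplayList:
    """Top-down traversal emitting the frontier of admissible nodes.

    Distance is measured per cluster to its own center — the MVEE center in
    ellipsoid mode, the minimal-sphere center in sphere mode — so one frame
    can mix detail bands across the molecule.  ``vdw`` mode bypasses the
    predicate and emits every atom.
    """
    cam = np.asarray(camera_position, dtype=float)
    entries: list[tuple[int, GlyphKind]] = []

    if glyph_mode == "vdw":
        for leaf in sorted(tree.leaves(), key=lambda nd: nd.id):
            entries.append((leaf.id, "sphere"))
        return DisplayList(entries=tuple(entries))
    if glyph_mode not in ("sphere", "ellipsoid"):
        raise ValueError(f"unknown glyph mode {glyph_mode!r}")

    def center_of(node) -> np.ndarray:
        if glyph_mode == "ellipsoid" and node.mvee is not None:
            return node.mvee.center
        return node.bounding_sphere.center

    # Explicit stack: depth-first, left child first, safe for deep trees.
    stack = [tree.root_id]
    while stack:
        node = tree.node(stack.pop())
        dis = float(np.linalg.norm(cam - center_of(node)))
        if node.is_leaf:
            entries.append((node.id, "sphere"))
        elif lod_predicate(node.height, dis, params):
            kind: GlyphKind = "ellipsoid" if glyph_mode == "ellipsoid" else "sphere"
            entries.append((node.id, kind))
        else:
            stack.extend(reversed(node.children))

    covered: set[int] = set()
    for nid, _ in entries:
        members = tree.node(nid).atom_members
        assert covered.isdisjoint(members), "display list double-covers atoms"
        covered |= members
    assert len(covered) == tree.n_atoms, "display list drops atoms"
    return DisplayList(entries=tuple(entries))
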