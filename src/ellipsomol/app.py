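"""Command-line pipeline: build / select / render / stats.

Trees are serialized as versioned JSON (human-inspectable, diff-friendly);
ellipsoids are stored as center + axes + semi-axes rather than the quadric
matrix so a reload does not re-run an eigendecomposition.  Render settings
come from a flat TOML config mirroring the Camera/LOD/RenderSettings
fields.  Log lines go to stderr with timestamps and levels.
"""

from __future__ import annotations

import argparse
import json
import logging
import sys
import tomllib
from pathlib import Path

import numpy as np

from . import __version__
from .bounding import Ellipsoid, SamplingConfig, annotate_tree
from .hierarchy import ClusterNode, ClusterTree, NodeLevel, Sphere, build_cluster_tree
from .lod import DisplayList, LODParams, select_display_list
from .molecule_io import (
    Atom,
    InputError,
    Molecule,
    generate_synthetic_molecule,
    read_pdb,
)
from .render import (
    LEVEL_PALETTE,
    Camera,
    RenderSettings,
    composite,
    render_frame,
    write_image,
)

log = logging.getLogger("ellipsomol")

FORMAT_VERSION = 1


# --------------------------------------------------------------------------
# Tree serialization
# --------------------------------------------------------------------------

def _sphere_to_json(s: Sphere) -> dict:
    return {"center": s.center.tolist(), "radius": s.radius}


def _ellipsoid_to_json(e: Ellipsoid | None) -> dict | None:
    if e is None:
        return None
    return {
        "center": e.center.tolist(),
        "axes": e.axes.tolist(),
        "semi_axes": e.semi_axes.tolist(),
    }


def serialize_tree(tree: ClusterTree, molecule: Molecule) -> dict:
    return {
        "format_version": FORMAT_VERSION,
        "molecule": {
            "atoms": [
                {
                    "index": a.index,
                    "element": a.element,
                    "position": a.position.tolist(),
                    "radius": a.radius,
                    "residue_key": a.residue_key,
                    "residue_name": a.residue_name,
                }
                for a in molecule.atoms
            ],
            "residues": [[key, list(members)] for key, members in molecule.residues],
        },
        "tree": {
            "root_id": tree.root_id,
            "n_atoms": tree.n_atoms,
            "nodes": [
                {
                    "id": n.id,
                    "level": n.level.value,
                    "children": list(n.children) if n.children else None,
                    "atom_members": sorted(n.atom_members),
                    "height": n.height,
                    "residue_root": n.residue_root,
                    "sphere": _sphere_to_json(n.bounding_sphere),
                    "ellipsoid": _ellipsoid_to_json(n.mvee),
                }
                for n in sorted(tree.nodes.values(), key=lambda nd: nd.id)
            ],
        },
    }


def deserialize_tree(doc: dict) -> tuple[ClusterTree, Molecule]:
    if doc.get("format_version") != FORMAT_VERSION:
        raise InputError(f"unsupported tree format version {doc.get('format_version')}")
    atoms = tuple(
        Atom(
            index=a["index"],
            element=a["element"],
            position=np.array(a["position"]),
            radius=a["radius"],
            residue_key=a["residue_key"],
            residue_name=a["residue_name"],
        )
        for a in doc["molecule"]["atoms"]
    )
    residues = tuple((key, tuple(members)) for key, members in doc["molecule"]["residues"])
    molecule = Molecule(atoms=atoms, residues=residues)

    nodes: dict[int, ClusterNode] = {}
    for nd in doc["tree"]["nodes"]:
        ell = nd["ellipsoid"]
        nodes[nd["id"]] = ClusterNode(
            id=nd["id"],
            level=NodeLevel(nd["level"]),
            children=tuple(nd["children"]) if nd["children"] else None,
            atom_members=frozenset(nd["atom_members"]),
            bounding_sphere=Sphere(np.array(nd["sphere"]["center"]), nd["sphere"]["radius"]),
            height=nd["height"],
            residue_root=nd["residue_root"],
            mvee=Ellipsoid(
                center=np.array(ell["center"]),
                axes=np.array(ell["axes"]),
                semi_axes=np.array(ell["semi_axes"]),
            ) if ell else None,
        )
    tree = ClusterTree(nodes=nodes, root_id=doc["tree"]["root_id"],
                       n_atoms=doc["tree"]["n_atoms"])
    return tree, molecule


def save_tree(tree: ClusterTree, molecule: Molecule, path: str | Path) -> None:
    Path(path).write_text(json.dumps(serialize_tree(tree, molecule), indent=1))


def load_tree(path: str | Path) -> tuple[ClusterTree, Molecule]:
    path = Path(path)
    if not path.is_file():
        raise InputError(f"tree file not found: {path}")
    return deserialize_tree(json.loads(path.read_text()))


# --------------------------------------------------------------------------
# Display-list text export and glyph geometry
# --------------------------------------------------------------------------

def display_list_text(dl: DisplayList, tree: ClusterTree) -> str:
    """One line per entry: id, kind, center, then geometry parameters."""
    lines = []
    for nid, kind in dl.entries:
        node = tree.node(nid)
        if kind == "sphere" and node.is_leaf:
            c, geom = node.bounding_sphere.center, [node.bounding_sphere.radius]
        elif kind == "sphere":
            c, geom = node.bounding_sphere.center, [node.bounding_sphere.radius]
        else:
            e = node.mvee
            c = e.center
            geom = list(e.semi_axes) + [x for col in e.axes.T for x in col]
        fields = [str(nid), kind] + [f"{v:.9f}" for v in (*c, *geom)]
        lines.append(" ".join(fields))
    return "\n".join(lines) + "\n"


def glyph_geometry(dl: DisplayList, tree: ClusterTree,
                   color_by: str = "level") -> list[tuple[int, str, object, tuple]]:
    """Expand a display list into renderable (id, kind, shape, color) tuples."""
    geometry = []
    for nid, kind in dl.entries:
        node = tree.node(nid)
        if color_by == "residue":
            # Stable per-residue hue from the smallest member atom index.
            h = (min(node.atom_members) * 0.6180339887498949) % 1.0
            color = _hsv_to_rgb(h, 0.55, 0.9)
        else:
            color = LEVEL_PALETTE[node.level]
        shape = node.bounding_sphere if kind == "sphere" else node.mvee
        geometry.append((nid, kind, shape, color))
    return geometry


def _hsv_to_rgb(h: float, s: float, v: float) -> tuple[float, float, float]:
    i = int(h * 6.0) % 6
    f = h * 6.0 - int(h * 6.0)
    p, q, t = v * (1 - s), v * (1 - s * f), v * (1 - s * (1 - f))
    return [(v, t, p), (q, v, p), (p, v, t), (p, q, v), (t, p, v), (v, p, q)][i]


# --------------------------------------------------------------------------
# Config
# --------------------------------------------------------------------------

def load_render_config(path: str | Path) -> dict:
    """Flat TOML config -> validated Camera / LODParams / RenderSettings."""
    path = Path(path)
    if not path.is_file():
        raise InputError(f"config file not found: {path}")
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)

    camera = Camera(
        position=np.array(raw.get("camera_position", [0.0, 0.0, 100.0])),
        target=np.array(raw.get("camera_target", [0.0, 0.0, 0.0])),
        up=np.array(raw.get("camera_up", [0.0, 1.0, 0.0])),
        vertical_fov=float(raw.get("vertical_fov", 45.0)),
        width=int(raw.get("width", 512)),
        height=int(raw.get("height", 512)),
    )
    params = LODParams(
        inival=float(raw.get("inival", 100.0)),
        interval=float(raw.get("interval", 20.0)),
    )
    settings = RenderSettings(
        shading=raw.get("shading", "diffuse"),
        contours=bool(raw.get("contours", True)),
        ssao=bool(raw.get("ssao", True)),
        ssao_samples=int(raw.get("ssao_samples", 16)),
        ssao_radius=float(raw.get("ssao_radius", 3.0)),
        ssao_seed=int(raw.get("ssao_seed", 0)),
        silhouette_threshold=float(raw.get("silhouette_threshold", 1.0)),
        silhouette_depth_scale=float(raw.get("silhouette_depth_scale", 0.01)),
        background=tuple(raw.get("background", [1.0, 1.0, 1.0])),
    )
    return {
        "camera": camera,
        "lod": params,
        "settings": settings,
        "mode": raw.get("mode", "ellipsoid"),
        "color_by": raw.get("color_by", "level"),
    }


# --------------------------------------------------------------------------
# Subcommands
# --------------------------------------------------------------------------

def _cmd_build(args: argparse.Namespace) -> int:
    if args.synthetic:
        try:
            r, a, seed = (int(x) for x in args.synthetic.split(","))
        except ValueError:
            raise InputError("--synthetic expects R,A,SEED integers")
        molecule = generate_synthetic_molecule(r, a, seed)
        log.info("generated synthetic molecule: %d residues x %d atoms", r, a)
    else:
        molecule = read_pdb(args.pdb, include_hetero=args.include_hetero)
        log.info("read %s: %d atoms, %d residues", args.pdb,
                 molecule.n_atoms, molecule.n_residues)
    tree = build_cluster_tree(molecule)
    cfg = SamplingConfig(points_per_surface=args.samples,
                         mvee_tolerance=args.mvee_tol)
    annotate_tree(tree, molecule, cfg)
    save_tree(tree, molecule, args.out)
    log.info("wrote tree with %d nodes to %s", len(tree.nodes), args.out)
    return 0


def _cmd_select(args: argparse.Namespace) -> int:
    tree, _ = load_tree(args.tree)
    cam = np.array([float(x) for x in args.camera.split(",")])
    params = LODParams(inival=args.inival, interval=args.interval)
    dl = select_display_list(tree, cam, params, glyph_mode=args.mode)
    text = display_list_text(dl, tree)
    if args.out:
        Path(args.out).write_text(text)
    else:
        sys.stdout.write(text)
    log.info("display list: %d entries", len(dl))
    return 0


def _cmd_render(args: argparse.Namespace) -> int:
    tree, _ = load_tree(args.tree)
    cfg = load_render_config(args.config)
    dl = select_display_list(tree, cfg["camera"].position, cfg["lod"],
                             glyph_mode=cfg["mode"])
    geometry = glyph_geometry(dl, tree, color_by=cfg["color_by"])
    fb = render_frame(geometry, cfg["camera"], cfg["settings"])
    rgb = composite(fb, cfg["camera"], cfg["settings"])
    write_image(rgb, args.out)
    log.info("rendered %d glyphs to %s (%dx%d)", len(dl), args.out,
             cfg["camera"].width, cfg["camera"].height)
    return 0


def _cmd_stats(args: argparse.Namespace) -> int:
    tree, molecule = load_tree(args.tree)
    counts = tree.level_counts()
    print(f"atoms: {tree.n_atoms}")
    print(f"nodes: {len(tree.nodes)}")
    for level in NodeLevel:
        print(f"  {level.value}: {counts.get(level, 0)}")
    internal = tree.internal_nodes()
    sphere_vol = sum(n.bounding_sphere.volume for n in internal)
    mvee_vol = sum(n.mvee.volume for n in internal if n.mvee is not None)
    print(f"total internal-node sphere volume: {sphere_vol:.3f} A^3")
    print(f"total internal-node ellipsoid volume: {mvee_vol:.3f} A^3")
    if sphere_vol > 0:
        print(f"ellipsoid/sphere volume ratio: {mvee_vol / sphere_vol:.4f}")
    return 0


def build_parser() -> argparse.ArgumentParser:
    parser = argparse.ArgumentParser(
        prog="ellipsomol",
        description="Ellipsoidal level-of-detail abstraction of molecular surfaces",
    )
    parser.add_argument("--version", action="version", version=__version__)
    parser.add_argument("-v", "--verbose", action="store_true")
    sub = parser.add_subparsers(dest="command", required=True)

    p = sub.add_parser("build", help="cluster a molecule and bound every node")
    src = p.add_mutually_exclusive_group(required=True)
    src.add_argument("--pdb", help="input PDB file")
    src.add_argument("--synthetic", metavar="R,A,SEED",
                     help="generate R residues of A atoms with the given seed")
    p.add_argument("--include-hetero", action="store_true")
    p.add_argument("--samples", type=int, default=32,
                   help="surface sample points per atom/ellipsoid")
    p.add_argument("--mvee-tol", type=float, default=1e-3)
    p.add_argument("--out", required=True, help="output tree JSON")
    p.set_defaults(func=_cmd_build)

    p = sub.add_parser("select", help="compute a display list for a camera pose")
    p.add_argument("--tree", required=True)
    p.add_argument("--camera", required=True, metavar="X,Y,Z")
    p.add_argument("--inival", type=float, default=100.0)
    p.add_argument("--interval", type=float, default=20.0)
    p.add_argument("--mode", choices=["sphere", "ellipsoid", "vdw"],
                   default="ellipsoid")
    p.add_argument("--out")
    p.set_defaults(func=_cmd_select)

    p = sub.add_parser("render", help="render a tree with a TOML config")
    p.add_argument("--tree", required=True)
    p.add_argument("--config", required=True)
    p.add_argument("--out", required=True)
    p.set_defaults(func=_cmd_render)

    p = sub.add_parser("stats", help="node counts and bound-volume totals")
    p.add_argument("--tree", required=True)
    p.set_defaults(func=_cmd_stats)
    return parser


def main(argv: list[str] | None = None) -> int:
    args = build_parser().parse_args(argv)
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if args.verbose else logging.INFO,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )
    try:
        return args.func(args)
    except InputError as exc:
        log.error("%s", exc)
        return 1
    except FileNotFoundError as exc:
        log.error("%s", exc)
        return 1


if __name__ == "__main__":
    sys.exit(main())
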