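"""Molecule model, PDB input, vdW radii, and synthetic test molecules.

The abstraction pipeline operates on a flat list of atom spheres grouped
into residues.  Coordinates stay in the PDB frame (ångström, no centering)
so that camera distances used by the level-of-detail predicate are in Å.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Molecule",
    "RadiiTable",
    "BONDI_RADII",
    "InputError",
    "EmptyInputError",
    "read_pdb",
    "assign_vdw_radii",
    "generate_synthetic_molecule",
    "write_pdb",
]


class InputError(ValueError):
    """Raised for unreadable or malformed input."""


class EmptyInputError(InputError):
    """Raised when a structure file yields zero accepted atoms."""


#: Bondi van der Waals radii (Å) for the elements common in proteins.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
}

DEFAULT_RADIUS = 1.50


@dataclass(frozen=True)
class RadiiTable:
    """Element symbol -> vdW radius (Å) with a fallback for unknowns."""

    radii: Mapping[str, float] = field(default_factory=lambda: dict(BONDI_RADII))
    default_radius: float = DEFAULT_RADIUS

    def __post_init__(self) -> None:
        if self.default_radius <= 0 or any(r <= 0 for r in self.radii.values()):
            raise InputError("all vdW radii must be positive")

    def lookup(self, element: str) -> float:
        r = self.radii.get(element.capitalize())
        if r is None:
            log.debug("unknown element %r, using default radius %.2f Å", element, self.default_radius)
            return self.default_radius
        return r


@dataclass(frozen=True)
class Atom:
    """One atom sphere: position in Å, vdW radius, and residue membership."""

    index: int
    element: str
    position: np.ndarray  # shape (3,), Å
    radius: float
    residue_key: str  # "chain:resSeq:iCode"
    residue_name: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if self.position.shape != (3,):
            raise InputError("atom position must be a 3-vector")
        if self.radius <= 0:
            raise InputError("atom radius must be positive")


@dataclass(frozen=True)
class Molecule:
    """An ordered atom list plus the residue partition over atom indices.

    ``residues`` preserves file order; each entry is ``(residue_key,
    atom_indices)`` and the groups partition ``range(n_atoms)``.
    """

    atoms: tuple[Atom, ...]
    residues: tuple[tuple[str, tuple[int, ...]], ...]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for _, members in self.residues:
            if not members:
                raise InputError("empty residue group")
            if seen.intersection(members):
                raise InputError("residue groups overlap")
            seen.update(members)
        if seen != set(range(len(self.atoms))):
            raise InputError("residue groups do not cover the atom set")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def positions(self) -> np.ndarray:
        """(n, 3) coordinate array in file order."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)

    def residue_index_of(self) -> np.ndarray:
        """Per-atom index into ``residues``."""
        out = np.empty(self.n_atoms, dtype=int)
        for ri, (_, members) in enumerate(self.residues):
            out[list(members)] = ri
        return out


def _group_residues(atoms: Sequence[Atom]) -> tuple[tuple[str, tuple[int, ...]], ...]:
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for a in atoms:
        if a.residue_key not in groups:
            order.append(a.residue_key)
            groups[a.residue_key] = []
        groups[a.residue_key].append(a.index)
    return tuple((key, tuple(groups[key])) for key in order)


def read_pdb(path: str | Path, include_hetero: bool = False,
             table: RadiiTable | None = None) -> Molecule:
    """Read a PDB file into a :class:`Molecule`.

    Model 1 only.  Alternate locations other than blank or "A" are dropped,
    waters (HOH) are always skipped, and HETATM records are skipped unless
    ``include_hetero`` is set.  Radii come from ``table`` (Bondi by default).
    """
    import gemmi

    path = Path(path)
    if not path.is_file():
        raise InputError(f"cannot read PDB file: {path}")
    try:
        structure = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise InputError(f"failed to parse {path}: {exc}") from exc

    if table is None:
        table = RadiiTable()
    if len(structure) == 0:
        raise EmptyInputError(f"no models in {path}")
    model = structure[0]

    atoms: list[Atom] = []
    for chain in model:
        for residue in chain:
            if residue.name == "HOH":
                continue
            is_het = residue.het_flag == "H"
            if is_het and not include_hetero:
                continue
            icode = residue.seqid.icode.strip()
            key = f"{chain.name}:{residue.seqid.num}:{icode}"
            for atom in residue:
                if atom.altloc not in ("", "\0", "A"):
                    continue
                element = atom.element.name
                if element in ("", "X"):
                    element = _element_from_name(atom.name)
                atoms.append(Atom(
                    index=len(atoms),
                    element=element,
                    position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    radius=table.lookup(element),
                    residue_key=key,
                    residue_name=residue.name,
                ))
    if not atoms:
        raise EmptyInputError(f"no accepted atoms in {path} (include_hetero={include_hetero})")
    return Molecule(atoms=tuple(atoms), residues=_group_residues(atoms))


def _element_from_name(name: str) -> str:
    """Legacy fallback: infer the element from the atom-name field."""
    stripped = name.strip()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return "C"


def assign_vdw_radii(molecule: Molecule, table: RadiiTable) -> Molecule:
    """Return a copy of ``molecule`` with radii looked up by element.

    Unknown elements fall back to the table default.  Idempotent.
    """
    atoms = tuple(replace(a, radius=table.lookup(a.element)) for a in molecule.atoms)
    return Molecule(atoms=atoms, residues=molecule.residues)


# Elements cycled through the synthetic chain; roughly protein-like mix.
_SYNTH_ELEMENTS = ("C", "C", "N", "O", "C", "S")


def generate_synthetic_molecule(n_residues: int, atoms_per_residue: int,
                                seed: int) -> Molecule:
    """Generate a protein-like chain of residue blobs along a helix.

    Residue centers follow a smooth helical curve with ~6 Å spacing, larger
    than the ~1.1 Å intra-residue spread, so residues form spatially
    coherent blobs the clustering can recover.  Radii are drawn uniformly
    from the realistic vdW range 1.2–1.8 Å.  Deterministic per seed.
    """
    if n_residues < 1 or atoms_per_residue < 1:
        raise InputError("n_residues and atoms_per_residue must be >= 1")
    rng = np.random.default_rng(seed)

    # Helix: rise 3 Å per residue, radius 8 Å, ~6 Å arc spacing.
    t = np.arange(n_residues) * 0.7
    centers = np.column_stack([8.0 * np.cos(t), 8.0 * np.sin(t), 3.0 * t])

    atoms: list[Atom] = []
    for ri in range(n_residues):
        offsets = rng.normal(scale=1.1, size=(atoms_per_residue, 3))
        offsets -= offsets.mean(axis=0) if atoms_per_residue > 1 else 0.0
        radii = rng.uniform(1.2, 1.8, size=atoms_per_residue)
        for ai in range(atoms_per_residue):
            atoms.append(Atom(
                index=len(atoms),
                element=_SYNTH_ELEMENTS[ai % len(_SYNTH_ELEMENTS)],
                position=centers[ri] + offsets[ai],
                radius=float(radii[ai]),
                residue_key=f"A:{ri + 1}:",
                residue_name="GLY",
            ))
    return Molecule(atoms=tuple(atoms), residues=_group_residues(atoms))


def write_pdb(molecule: Molecule, path: str | Path) -> None:
    """Export the molecule as a minimal fixed-column PDB file."""
    lines = []
    for a in molecule.atoms:
        chain, resseq, icode = (a.residue_key.split(":") + [""])[:3]
        name = (a.element + str(a.index % 10))[:4]
        x, y, z = a.position
        lines.append(
            f"ATOM  {a.index + 1:5d} {name:<4s} {a.residue_name:<3s} "
            f"{chain[:1] or 'A'}{int(resseq):4d}{(icode or ' ')[:1]}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{a.element:>2s}  "
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
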