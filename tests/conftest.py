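import numpy as np
import pytest
from hypothesis import settings

import ellipsomol as em

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")


def _pdb_atom(serial, name, resname, chain, resseq, xyz, element, altloc=" ",
              record="ATOM"):
    x, y, z = xyz
    return (
        f"{record:<6s}{serial:5d} {name:<4s}{altloc}{resname:<3s} {chain}"
        f"{resseq:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
        f"          {element:>2s}  "
    )


@pytest.fixture
def two_residue_pdb(tmp_path):
    """Minimal 2-residue PDB with altLocs, a water, and a ligand HETATM."""
    lines = [
        _pdb_atom(1, "N", "ALA", "A", 1, (0.0, 0.0, 0.0), "N"),
        _pdb_atom(2, "CA", "ALA", "A", 1, (1.5, 0.0, 0.0), "C"),
        _pdb_atom(3, "CB", "ALA", "A", 1, (2.2, 1.2, 0.0), "C", altloc="A"),
        _pdb_atom(4, "CB", "ALA", "A", 1, (2.3, 1.3, 0.1), "C", altloc="B"),
        _pdb_atom(5, "N", "GLY", "A", 2, (3.8, 0.0, 0.0), "N"),
        _pdb_atom(6, "CA", "GLY", "A", 2, (5.3, 0.0, 0.0), "C"),
        _pdb_atom(7, "O", "HOH", "A", 101, (9.0, 9.0, 9.0), "O", record="HETATM"),
        _pdb_atom(8, "ZN", "ZN", "A", 102, (7.0, 7.0, 7.0), "ZN", record="HETATM"),
        "END",
    ]
    path = tmp_path / "mini.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture(scope="session")
def molecule_6x5():
    return em.generate_synthetic_molecule(6, 5, seed=1)


@pytest.fixture(scope="session")
def tree_6x5(molecule_6x5):
    return em.build_cluster_tree(molecule_6x5)


@pytest.fixture(scope="session")
def annotated_6x5(molecule_6x5):
    tree = em.build_cluster_tree(molecule_6x5)
    return em.annotate_tree(tree, molecule_6x5), molecule_6x5


@pytest.fixture(scope="session")
def unit_sphere_scene():
    """Unit sphere at the origin viewed down +z from 10 Å, 65x65 frame."""
    sphere = em.Sphere(np.zeros(3), 1.0)
    camera = em.Camera(position=np.array([0.0, 0.0, 10.0]),
                       target=np.zeros(3), width=65, height=65,
                       vertical_fov=30.0)
    return sphere, camera
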