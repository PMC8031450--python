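"""Shared fixtures: small hand-written structure files and random pockets.

All fixture structures are generated programmatically at test time; nothing
binary is stored in the repository.
"""

from __future__ import annotations

import numpy as np
import pytest

from pocketgcn.structure_io import AtomRecord, PocketComplex


PROPANE_MOL2 = """@<TRIPOS>MOLECULE
propane
11 10 0 0 0
SMALL
NO_CHARGES
@<TRIPOS>ATOM
      1 C1     0.0000   0.0000   0.0000 C.3    1 LIG1   0.0000
      2 C2     1.5260   0.0000   0.0000 C.3    1 LIG1   0.0000
      3 C3     2.0610   1.4420   0.0000 C.3    1 LIG1   0.0000
      4 H1    -0.3900  -0.5150   0.8900 H      1 LIG1   0.0000
      5 H2    -0.3900  -0.5150  -0.8900 H      1 LIG1   0.0000
      6 H3    -0.3900   1.0250   0.0000 H      1 LIG1   0.0000
      7 H4     1.9000  -0.5300   0.8850 H      1 LIG1   0.0000
      8 H5     1.9000  -0.5300  -0.8850 H      1 LIG1   0.0000
      9 H6     1.6900   1.9700   0.8900 H      1 LIG1   0.0000
     10 H7     1.6900   1.9700  -0.8900 H      1 LIG1   0.0000
     11 H8     3.1550   1.4680   0.0000 H      1 LIG1   0.0000
@<TRIPOS>BOND
     1    1    2 1
     2    2    3 1
     3    1    4 1
     4    1    5 1
     5    1    6 1
     6    2    7 1
     7    2    8 1
     8    3    9 1
     9    3   10 1
    10    3   11 1
"""


@pytest.fixture
def propane_mol2(tmp_path):
    path = tmp_path / "propane.mol2"
    path.write_text(PROPANE_MOL2)
    return str(path)


@pytest.fixture
def chlorobenzene_sdf(tmp_path):
    """Chlorobenzene with 3D coordinates, built through the backend."""
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = Chem.AddHs(Chem.MolFromSmiles("c1ccccc1Cl"))
    AllChem.EmbedMolecule(mol, randomSeed=7)
    path = tmp_path / "chlorobenzene.sdf"
    writer = Chem.SDWriter(str(path))
    writer.write(mol)
    writer.close()
    return str(path)


def make_pdb_line(serial, name, resname, resseq, x, y, z, element, altloc=" ", record="ATOM  "):
    return (
        f"{record}{serial:5d} {name:<4s}{altloc}{resname:<3s} A{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}\n"
    )


@pytest.fixture
def small_protein_pdb(tmp_path):
    """5 heavy atoms + 3 hydrogens + 1 water (should load as 5 atoms)."""
    lines = [
        make_pdb_line(1, "N", "GLY", 1, 0.0, 0.0, 0.0, "N"),
        make_pdb_line(2, "CA", "GLY", 1, 1.45, 0.0, 0.0, "C"),
        make_pdb_line(3, "C", "GLY", 1, 2.0, 1.4, 0.0, "C"),
        make_pdb_line(4, "O", "GLY", 1, 3.2, 1.5, 0.0, "O"),
        make_pdb_line(5, "H", "GLY", 1, -0.5, 0.8, 0.0, "H"),
        make_pdb_line(6, "HA", "GLY", 1, 1.8, -0.9, 0.5, "H"),
        make_pdb_line(7, "HB", "GLY", 1, 1.6, 2.3, 0.0, "H"),
        make_pdb_line(8, "SD", "MET", 2, 5.0, 5.0, 5.0, "S"),
        make_pdb_line(9, "O", "HOH", 3, 8.0, 8.0, 8.0, "O", record="HETATM"),
    ]
    path = tmp_path / "prot.pdb"
    path.write_text("".join(lines) + "END\n")
    return str(path)


@pytest.fixture
def altloc_pdb(tmp_path):
    """One atom with altloc A and B plus a normal atom (loads as 2 atoms)."""
    lines = [
        make_pdb_line(1, "CA", "ALA", 1, 0.0, 0.0, 0.0, "C", altloc="A"),
        make_pdb_line(2, "CA", "ALA", 1, 0.3, 0.0, 0.0, "C", altloc="B"),
        make_pdb_line(3, "CB", "ALA", 1, 1.5, 0.0, 0.0, "C"),
    ]
    path = tmp_path / "altloc.pdb"
    path.write_text("".join(lines) + "END\n")
    return str(path)


def random_pocket(rng: np.random.Generator, n_ligand=None, n_protein=None, spread=6.0) -> PocketComplex:
    """Random geometric pocket (no backend molecule; adjacency-level tests)."""
    n_ligand = n_ligand or int(rng.integers(3, 10))
    n_protein = n_protein or int(rng.integers(5, 30))
    lig = rng.uniform(-3, 3, size=(n_ligand, 3))
    prot = rng.uniform(-spread, spread, size=(n_protein, 3))
    lig_atoms = [
        AtomRecord(element="C", coords=tuple(c), molecule="ligand", source_index=i)
        for i, c in enumerate(lig)
    ]
    prot_atoms = [
        AtomRecord(element="C", coords=tuple(c), molecule="protein", source_index=i)
        for i, c in enumerate(prot)
    ]
    return PocketComplex(ligand_atoms=lig_atoms, protein_atoms=prot_atoms, cutoff=8.0, id="rand")


def random_graph(rng: np.random.Generator, n_nodes: int, n_bins: int, max_nodes: int = 40):
    """Random padded PocketGraph with symmetric zero-diagonal binary bins."""
    from pocketgcn.featurizer import PocketGraph, N_FEATURES

    A = np.zeros((n_bins, max_nodes, max_nodes))
    for k in range(n_bins):
        M = (rng.random((n_nodes, n_nodes)) < 0.25).astype(float)
        M = np.triu(M, 1)
        A[k, :n_nodes, :n_nodes] = M + M.T
    X = np.zeros((max_nodes, N_FEATURES))
    X[:n_nodes] = rng.normal(size=(n_nodes, N_FEATURES))
    return PocketGraph(features=X, adjacency=A, n_nodes=n_nodes,
                       label=float(rng.normal(7, 2)), id=f"g{n_nodes}")
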