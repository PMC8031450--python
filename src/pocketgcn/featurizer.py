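"""Pocket featurization: per-atom descriptors and distance-binned adjacency.

Each heavy atom is described by 13 numbers: a 9-class element one-hot
(B, C, N, O, P, S, Se, Halogen, Metal), a hybridization integer, the count of
attached heavy atoms, the count of attached hetero-atoms, and the Gasteiger
partial charge. Pairwise structure is encoded as ``n_bins`` binary adjacency
matrices: entry (i, j) of the k-th matrix is 1 iff the interatomic distance
falls in the interval (4(k-1)/n, 4k/n] Å, subject to a 4 Å limit for
inter-molecular (protein-ligand) pairs and a 2 Å limit for intra-molecular
pairs. Feature matrix and adjacency matrices are zero-padded to a fixed
200-node size; pockets with more than 200 nodes are rejected.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import h5py
import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from scipy.spatial.distance import pdist, squareform

from .structure_io import AtomRecord, MolecularStructure, PocketComplex

logger = logging.getLogger(__name__)

N_FEATURES = 13
MAX_NODES = 200
VALID_N_BINS = (1, 2, 4, 8)
INTER_LIMIT = 4.0  # Å, protein-ligand pairs
INTRA_LIMIT = 2.0  # Å, within-molecule pairs

ONE_HOT_CLASSES = ("B", "C", "N", "O", "P", "S", "Se", "Halogen", "Metal")
HALOGENS = frozenset({"F", "Cl", "Br", "I", "At"})
METALS = frozenset(
    {
        "Li", "Na", "K", "Rb", "Cs",
        "Mg", "Ca", "Sr", "Ba",
        "Mn", "Fe", "Co", "Ni", "Cu", "Zn", "Cd", "Hg", "Mo",
        "Al",
    }
)

_HYBRIDIZATION_MAP = {
    Chem.HybridizationType.SP: 1,
    Chem.HybridizationType.SP2: 2,
    Chem.HybridizationType.SP3: 3,
}


class GraphTooLargeError(ValueError):
    """Pocket exceeds the fixed node budget; carries the complex id."""

    def __init__(self, id: str, n_nodes: int, max_nodes: int):
        super().__init__(f"complex {id}: {n_nodes} nodes exceeds cap of {max_nodes}")
        self.id = id
        self.n_nodes = n_nodes


@dataclass
class AtomFeatures:
    one_hot: np.ndarray  # length 9, binary
    hybridization: int
    heavy_valence: int
    hetero_valence: int
    partial_charge: float

    def to_vector(self) -> np.ndarray:
        v = np.empty(N_FEATURES, dtype=np.float64)
        v[:9] = self.one_hot
        v[9] = self.hybridization
        v[10] = self.heavy_valence
        v[11] = self.hetero_valence
        v[12] = self.partial_charge
        return v


@dataclass
class AdjacencyBins:
    """``n_bins`` symmetric binary matrices over the pocket's node ordering.

    Bins partition admissible pair distances: a pair appears in at most one
    matrix, and never on the diagonal.
    """

    n_bins: int
    matrices: list[np.ndarray]

    def union(self) -> np.ndarray:
        out = np.zeros_like(self.matrices[0])
        for m in self.matrices:
            out = np.logical_or(out, m).astype(out.dtype)
        return out


@dataclass
class PocketGraph:
    """Fixed-size graph tensor for one complex: zero-padded features and
    per-bin adjacency, true node count, affinity label (pKd/pKi), id."""

    features: np.ndarray  # (max_nodes, 13)
    adjacency: np.ndarray  # (n_bins, max_nodes, max_nodes), binary
    n_nodes: int
    label: float
    id: str

    @property
    def n_bins(self) -> int:
        return self.adjacency.shape[0]


# ---------------------------------------------------------------------------
# Per-atom descriptors


def _one_hot(element: str) -> np.ndarray:
    v = np.zeros(9, dtype=np.float64)
    if element in HALOGENS:
        v[ONE_HOT_CLASSES.index("Halogen")] = 1.0
    elif element in METALS:
        v[ONE_HOT_CLASSES.index("Metal")] = 1.0
    elif element in ONE_HOT_CLASSES:
        v[ONE_HOT_CLASSES.index(element)] = 1.0
    # otherwise all-zero: element outside the nine classes
    return v


def _gasteiger_charges(mol: Chem.Mol) -> np.ndarray:
    """Per-atom Gasteiger charges, cached on the molecule; non-finite → 0."""
    if not mol.HasProp("_pocketgcn_charges"):
        AllChem.ComputeGasteigerCharges(mol, throwOnParamFailure=False)
        charges = []
        n_bad = 0
        for atom in mol.GetAtoms():
            q = atom.GetDoubleProp("_GasteigerCharge") if atom.HasProp("_GasteigerCharge") else 0.0
            if not math.isfinite(q):
                n_bad += 1
                q = 0.0
            charges.append(q)
        if n_bad:
            logger.warning("%d of %d partial charges non-finite; replaced by 0", n_bad, len(charges))
        mol.SetProp("_pocketgcn_charges", json.dumps(charges))
    return np.asarray(json.loads(mol.GetProp("_pocketgcn_charges")))


def atom_features(atom: AtomRecord, context: MolecularStructure) -> AtomFeatures:
    """13-descriptor featurization of one heavy atom in its parent molecule.

    Hybridization is mapped SP→1, SP2→2, SP3→3 and anything else (ions,
    unset) to 0. Heavy valence counts non-hydrogen neighbours, hetero valence
    counts neighbours that are neither carbon nor hydrogen.
    """
    mol = context.rdkit_mol
    if mol is None:
        raise ValueError(f"structure {context.id} has no backend molecule for featurization")
    rd_atom = mol.GetAtomWithIdx(atom.source_index)
    neighbors = [n for n in rd_atom.GetNeighbors() if n.GetAtomicNum() != 1]
    charge = float(_gasteiger_charges(mol)[atom.source_index])
    return AtomFeatures(
        one_hot=_one_hot(atom.element),
        hybridization=_HYBRIDIZATION_MAP.get(rd_atom.GetHybridization(), 0),
        heavy_valence=len(neighbors),
        hetero_valence=sum(1 for n in neighbors if n.GetAtomicNum() not in (1, 6)),
        partial_charge=charge,
    )


def build_feature_matrix(pocket: PocketComplex) -> np.ndarray:
    """Unpadded N×13 matrix in canonical node order (ligand first, then
    protein, each in source-file order)."""
    if pocket.n_atoms == 0:
        raise ValueError("cannot featurize an empty pocket")
    rows = [atom_features(a, pocket.ligand_structure).to_vector() for a in pocket.ligand_atoms]
    rows += [atom_features(a, pocket.protein_structure).to_vector() for a in pocket.protein_atoms]
    return np.vstack(rows)


# ---------------------------------------------------------------------------
# Distance-binned adjacency


def build_adjacency_bins(pocket: PocketComplex, n_bins: int) -> AdjacencyBins:
    """Binned binary adjacency: pair (i, j) is set in bin k iff
    4(k−1)/n < d_ij ≤ 4k/n, with inter-molecular pairs admissible to 4 Å and
    intra-molecular pairs only to 2 Å. Boundaries are left-open/right-closed,
    so d = 4k/n exactly lands in bin k."""
    if n_bins not in VALID_N_BINS:
        raise ValueError(f"n_bins must be one of {VALID_N_BINS}, got {n_bins}")
    xyz = pocket.coords_array()
    n = len(xyz)
    d = squareform(pdist(xyz)) if n > 1 else np.zeros((1, 1))
    nl = len(pocket.ligand_atoms)
    is_lig = np.zeros(n, dtype=bool)
    is_lig[:nl] = True
    inter = is_lig[:, None] != is_lig[None, :]
    limit = np.where(inter, INTER_LIMIT, INTRA_LIMIT)
    admissible = (d <= limit) & ~np.eye(n, dtype=bool)
    width = INTER_LIMIT / n_bins
    matrices = []
    for k in range(1, n_bins + 1):
        in_bin = (d > width * (k - 1)) & (d <= width * k)
        matrices.append((in_bin & admissible).astype(np.float64))
    return AdjacencyBins(n_bins=n_bins, matrices=matrices)


def assemble_graph(
    features: np.ndarray,
    bins: AdjacencyBins,
    label: float,
    id: str,
    max_nodes: int = MAX_NODES,
) -> PocketGraph:
    """Zero-pad to the fixed node budget, or raise ``GraphTooLargeError``
    when the pocket exceeds it."""
    n = features.shape[0]
    if any(m.shape != (n, n) for m in bins.matrices):
        raise ValueError(f"complex {id}: features ({n} rows) and adjacency shapes disagree")
    if n > max_nodes:
        raise GraphTooLargeError(id, n, max_nodes)
    feat = np.zeros((max_nodes, N_FEATURES), dtype=np.float64)
    feat[:n] = features
    adj = np.zeros((bins.n_bins, max_nodes, max_nodes), dtype=np.float64)
    for k, m in enumerate(bins.matrices):
        adj[k, :n, :n] = m
    return PocketGraph(features=feat, adjacency=adj, n_nodes=n, label=float(label), id=id)


def featurize_complex(
    pocket: PocketComplex,
    n_bins: int,
    label: float,
    max_nodes: int = MAX_NODES,
) -> PocketGraph:
    """Full featurization of one pocket: feature matrix, binned adjacency,
    padding. Raises ``GraphTooLargeError`` past the node cap."""
    features = build_feature_matrix(pocket)
    bins = build_adjacency_bins(pocket, n_bins)
    return assemble_graph(features, bins, label, pocket.id, max_nodes=max_nodes)


# ---------------------------------------------------------------------------
# Graph-tensor cache (HDF5; unpadded per-complex groups)


def save_graphs(path: str, graphs: list[PocketGraph]) -> None:
    """Write graphs to an HDF5 cache, one group per complex id with datasets
    ``features`` (n×13), ``adjacency`` (n_bins×n×n, uint8) and attrs
    ``n_nodes``, ``label``. Stored unpadded; re-padded on load."""
    with h5py.File(path, "w") as fh:
        for g in graphs:
            n = g.n_nodes
            grp = fh.create_group(g.id)
            grp.create_dataset("features", data=g.features[:n].astype(np.float32))
            grp.create_dataset("adjacency", data=g.adjacency[:, :n, :n].astype(np.uint8))
            grp.attrs["n_nodes"] = n
            grp.attrs["label"] = g.label


def load_graphs(path: str, max_nodes: int = MAX_NODES, ids: list[str] | None = None) -> list[PocketGraph]:
    graphs = []
    with h5py.File(path, "r") as fh:
        keys = ids if ids is not None else sorted(fh.keys())
        for cid in keys:
            grp = fh[cid]
            n = int(grp.attrs["n_nodes"])
            feat = np.zeros((max_nodes, N_FEATURES))
            feat[:n] = grp["features"][...]
            raw = grp["adjacency"][...]
            adj = np.zeros((raw.shape[0], max_nodes, max_nodes))
            adj[:, :n, :n] = raw
            graphs.append(
                PocketGraph(features=feat, adjacency=adj, n_nodes=n, label=float(grp.attrs["label"]), id=cid)
            )
    return graphs
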