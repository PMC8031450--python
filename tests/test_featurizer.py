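"""featurizer: 13-descriptor atom features, binned adjacency, padding, cache."""

import numpy as np
import pytest

from pocketgcn.featurizer import (
    INTER_LIMIT,
    INTRA_LIMIT,
    MAX_NODES,
    N_FEATURES,
    ONE_HOT_CLASSES,
    AdjacencyBins,
    GraphTooLargeError,
    assemble_graph,
    atom_features,
    build_adjacency_bins,
    build_feature_matrix,
    featurize_complex,
    load_graphs,
    save_graphs,
)
from pocketgcn.structure_io import AtomRecord, PocketComplex, read_ligand, read_protein

from conftest import make_pdb_line, random_pocket, random_graph


# ---------------------------------------------------------------------------
# Atom features


def test_propane_central_carbon(propane_mol2):
    from rdkit.Chem import AllChem

    struct = read_ligand(propane_mol2)
    central = struct.atoms[1]  # C2 in file order
    f = atom_features(central, struct)
    assert f.one_hot.tolist() == [0, 1, 0, 0, 0, 0, 0, 0, 0]  # C slot
    assert f.heavy_valence == 2
    assert f.hetero_valence == 0
    assert f.hybridization == 3  # SP3
    # oracle: direct backend query on the same molecule
    mol = struct.rdkit_mol
    AllChem.ComputeGasteigerCharges(mol)
    expected = mol.GetAtomWithIdx(central.source_index).GetDoubleProp("_GasteigerCharge")
    assert f.partial_charge == pytest.approx(expected, abs=1e-9)


def test_chlorine_halogen_slot(chlorobenzene_sdf):
    struct = read_ligand(chlorobenzene_sdf)
    cl = next(a for a in struct.atoms if a.element == "Cl")
    f = atom_features(cl, struct)
    assert f.one_hot[ONE_HOT_CLASSES.index("Halogen")] == 1
    assert f.one_hot.sum() == 1


def test_zinc_metal_slot(tmp_path):
    path = tmp_path / "zn.pdb"
    path.write_text(
        make_pdb_line(1, "ZN", "ZN", 1, 0, 0, 0, "Zn", record="HETATM") + "END\n"
    )
    struct = read_protein(str(path))
    f = atom_features(struct.atoms[0], struct)
    assert f.one_hot[ONE_HOT_CLASSES.index("Metal")] == 1
    assert f.one_hot.sum() == 1
    assert f.heavy_valence == 0


def test_feature_vector_length_and_layout(propane_mol2):
    struct = read_ligand(propane_mol2)
    for atom in struct.atoms:
        v = atom_features(atom, struct).to_vector()
        assert v.shape == (N_FEATURES,)
        assert np.sum(v[:9] == 1) <= 1
        assert set(np.unique(v[:9])) <= {0.0, 1.0}


def test_feature_matrix_shape_and_order(propane_mol2, small_protein_pdb):
    ligand = read_ligand(propane_mol2)
    from pocketgcn.structure_io import select_pocket

    protein = read_protein(small_protein_pdb)
    pocket = select_pocket(protein, ligand, cutoff=10.0)
    M = build_feature_matrix(pocket)
    assert M.shape == (pocket.n_atoms, N_FEATURES)
    # row i equals the per-atom featurization of atom i (loop oracle)
    atoms = pocket.atoms
    contexts = [pocket.ligand_structure] * len(pocket.ligand_atoms) + [
        pocket.protein_structure
    ] * len(pocket.protein_atoms)
    for i, (a, ctx) in enumerate(zip(atoms, contexts)):
        np.testing.assert_allclose(M[i], atom_features(a, ctx).to_vector())


# ---------------------------------------------------------------------------
# Binned adjacency


def _pocket_from_coords(lig_coords, prot_coords):
    lig = [
        AtomRecord(element="C", coords=tuple(map(float, c)), molecule="ligand", source_index=i)
        for i, c in enumerate(lig_coords)
    ]
    prot = [
        AtomRecord(element="C", coords=tuple(map(float, c)), molecule="protein", source_index=i)
        for i, c in enumerate(prot_coords)
    ]
    return PocketComplex(ligand_atoms=lig, protein_atoms=prot, cutoff=8.0, id="t")


def test_inter_pair_3p5_in_fourth_bin_only():
    pocket = _pocket_from_coords([(0, 0, 0)], [(3.5, 0, 0)])
    bins = build_adjacency_bins(pocket, 4)
    assert [m[0, 1] for m in bins.matrices] == [0, 0, 0, 1]


def test_intra_protein_2p5_excluded_everywhere():
    pocket = _pocket_from_coords([(50, 50, 50)], [(0, 0, 0), (2.5, 0, 0)])
    bins = build_adjacency_bins(pocket, 4)
    for m in bins.matrices:
        assert m[1, 2] == 0 and m[2, 1] == 0


def test_intra_ligand_exactly_2_in_first_bin_n2():
    pocket = _pocket_from_coords([(0, 0, 0), (2.0, 0, 0)], [(50, 50, 50)])
    bins = build_adjacency_bins(pocket, 2)
    assert bins.matrices[0][0, 1] == 1  # left-open, right-closed: d=2 in (0,2]
    assert bins.matrices[1][0, 1] == 0


def test_pair_beyond_4A_zero_everywhere():
    pocket = _pocket_from_coords([(0, 0, 0)], [(4.2, 0, 0)])
    for n_bins in (1, 2, 4, 8):
        bins = build_adjacency_bins(pocket, n_bins)
        assert all(m[0, 1] == 0 for m in bins.matrices)


def test_invalid_n_bins():
    pocket = _pocket_from_coords([(0, 0, 0)], [(3.0, 0, 0)])
    with pytest.raises(ValueError):
        build_adjacency_bins(pocket, 3)


def _brute_force_bins(pocket, n_bins):
    """Independent double-loop oracle for the binned adjacency rule."""
    atoms = pocket.atoms
    n = len(atoms)
    mats = [np.zeros((n, n)) for _ in range(n_bins)]
    width = 4.0 / n_bins
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = float(np.linalg.norm(np.subtract(atoms[i].coords, atoms[j].coords)))
            limit = INTER_LIMIT if pocket.is_inter_pair(i, j) else INTRA_LIMIT
            if d > limit:
                continue
            for k in range(n_bins):
                if width * k < d <= width * (k + 1):
                    mats[k][i, j] = 1
    return mats


@pytest.mark.parametrize("n_bins", [1, 2, 4, 8])
def test_adjacency_matches_brute_force(n_bins):
    rng = np.random.default_rng(42 + n_bins)
    for _ in range(10):
        pocket = random_pocket(rng)
        bins = build_adjacency_bins(pocket, n_bins)
        oracle = _brute_force_bins(pocket, n_bins)
        for m, o in zip(bins.matrices, oracle):
            np.testing.assert_array_equal(m, o)


def test_adjacency_partition_symmetry_refinement():
    rng = np.random.default_rng(7)
    for _ in range(20):
        pocket = random_pocket(rng)
        per_n = {n: build_adjacency_bins(pocket, n) for n in (1, 2, 4, 8)}
        for bins in per_n.values():
            stack = np.stack(bins.matrices)
            # symmetry and zero diagonal
            for m in bins.matrices:
                np.testing.assert_array_equal(m, m.T)
                assert np.all(np.diag(m) == 0)
            # each pair in at most one bin
            assert stack.sum(axis=0).max() <= 1
        # refinement: unions agree across bin counts
        u1 = per_n[1].union()
        for n in (2, 4, 8):
            np.testing.assert_array_equal(per_n[n].union(), u1)


def test_n8_outer_bins_inter_only():
    rng = np.random.default_rng(11)
    for _ in range(10):
        pocket = random_pocket(rng)
        bins = build_adjacency_bins(pocket, 8)
        nl = len(pocket.ligand_atoms)
        n = pocket.n_atoms
        is_lig = np.zeros(n, dtype=bool)
        is_lig[:nl] = True
        intra = is_lig[:, None] == is_lig[None, :]
        for m in bins.matrices[4:]:  # bins covering (2, 4] Å
            assert np.all(m[intra] == 0)


# ---------------------------------------------------------------------------
# Assembly, padding, node cap


def _dummy_bins(n, n_bins=2):
    rng = np.random.default_rng(0)
    mats = []
    for _ in range(n_bins):
        m = np.triu((rng.random((n, n)) < 0.2).astype(float), 1)
        mats.append(m + m.T)
    return AdjacencyBins(n_bins=n_bins, matrices=mats)


def test_assemble_rejects_201_nodes():
    feats = np.ones((201, N_FEATURES))
    with pytest.raises(GraphTooLargeError) as exc:
        assemble_graph(feats, _dummy_bins(201), 5.0, "big")
    assert exc.value.id == "big"
    assert exc.value.n_nodes == 201


def test_assemble_accepts_200_nodes():
    feats = np.ones((200, N_FEATURES))
    g = assemble_graph(feats, _dummy_bins(200), 5.0, "edge")
    assert g.n_nodes == 200
    assert g.features.shape == (MAX_NODES, N_FEATURES)


def test_assemble_padding_is_zero():
    feats = np.ones((7, N_FEATURES))
    g = assemble_graph(feats, _dummy_bins(7), 5.0, "small")
    assert g.features.shape == (MAX_NODES, N_FEATURES)
    assert np.all(g.features[7:] == 0)
    assert np.all(g.adjacency[:, 7:, :] == 0)
    assert np.all(g.adjacency[:, :, 7:] == 0)


def test_assemble_dimension_mismatch():
    feats = np.ones((5, N_FEATURES))
    with pytest.raises(ValueError):
        assemble_graph(feats, _dummy_bins(6), 5.0, "bad")


def test_featurize_complex_end_to_end(propane_mol2, small_protein_pdb):
    from pocketgcn.structure_io import select_pocket

    ligand = read_ligand(propane_mol2)
    protein = read_protein(small_protein_pdb)
    pocket = select_pocket(protein, ligand, cutoff=10.0, id="cplx")
    g = featurize_complex(pocket, 2, 6.4)
    assert g.n_nodes == pocket.n_atoms
    assert g.n_bins == 2
    assert g.label == 6.4
    assert g.id == "cplx"


# ---------------------------------------------------------------------------
# HDF5 cache round trip


def test_save_load_round_trip(tmp_path):
    rng = np.random.default_rng(3)
    graphs = [random_graph(rng, n_nodes=int(rng.integers(3, 30)), n_bins=2, max_nodes=MAX_NODES)
              for _ in range(5)]
    for i, g in enumerate(graphs):
        g.id = f"c{i}"
    path = str(tmp_path / "cache.h5")
    save_graphs(path, graphs)
    loaded = load_graphs(path, ids=[g.id for g in graphs])
    for g, l in zip(graphs, loaded):
        assert l.id == g.id and l.n_nodes == g.n_nodes
        assert l.label == pytest.approx(g.label)
        np.testing.assert_allclose(l.features, g.features, atol=1e-6)  # float32 storage
        np.testing.assert_array_equal(l.adjacency, g.adjacency)


def test_load_subset_by_id(tmp_path):
    rng = np.random.default_rng(4)
    graphs = [random_graph(rng, n_nodes=5, n_bins=2, max_nodes=MAX_NODES) for _ in range(3)]
    for i, g in enumerate(graphs):
        g.id = f"c{i}"
    path = str(tmp_path / "cache.h5")
    save_graphs(path, graphs)
    loaded = load_graphs(path, ids=["c2"])
    assert len(loaded) == 1 and loaded[0].id == "c2"
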