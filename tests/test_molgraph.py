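import numpy as np
import pytest
from rdkit import Chem

from atomflow.molgraph import (MaskedStateError, MoleculeGraph, Vocabulary,
                               VocabularyError, graph_from_rdkit, n_pairs,
                               pair_index, prepare_rdkit_mol, rdkit_from_graph,
                               read_structures, to_chem_object,
                               write_structures)


def _graph_from_smiles(smiles, vocab):
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    from rdkit.Chem import AllChem
    AllChem.EmbedMolecule(mol, randomSeed=5)
    mol = prepare_rdkit_mol(mol)
    return graph_from_rdkit(mol, vocab)


def test_vocab_layout(vocab):
    # data states first, mask last; fake atom is a data state of atom types
    assert vocab.fake_index == len(vocab.atom_elements)
    assert vocab.atom_mask_index == vocab.n_atom_types == vocab.fake_index + 1
    assert vocab.charge_mask_index == vocab.n_charges
    assert vocab.bond_mask_index == vocab.n_bond_orders == 4
    assert vocab.none_bond_index == 0
    assert vocab.decode_charge(vocab.neutral_charge_index) == 0


def test_vocab_errors(vocab):
    with pytest.raises(VocabularyError):
        vocab.encode_element("Xx")
    with pytest.raises(VocabularyError):
        vocab.encode_charge(9)
    with pytest.raises(VocabularyError):
        vocab.decode_element(vocab.fake_index)
    with pytest.raises(VocabularyError):
        Vocabulary(charges=(1, 2))
    with pytest.raises(VocabularyError):
        Vocabulary(bond_orders=("none", "single"))


def test_pair_index_matches_triu_order():
    n = 6
    iu = np.triu_indices(n, k=1)
    for k, (i, j) in enumerate(zip(*iu)):
        assert pair_index(int(i), int(j), n) == k
        assert pair_index(int(j), int(i), n) == k
    assert n_pairs(n) == len(iu[0])


def test_bond_matrix_round_trip(vocab, rng):
    n = 5
    bonds = rng.integers(0, 4, size=n_pairs(n))
    g = MoleculeGraph(rng.standard_normal((n, 3)), np.zeros(n, np.int64),
                      np.full(n, vocab.neutral_charge_index), bonds, vocab)
    mat = g.bond_matrix()
    assert np.array_equal(mat, mat.T)
    assert np.array_equal(MoleculeGraph.bonds_from_matrix(mat), bonds)
    with pytest.raises(ValueError):
        MoleculeGraph.bonds_from_matrix(np.triu(mat))


def test_validation_errors(vocab):
    with pytest.raises(ValueError):
        MoleculeGraph(np.full((2, 3), np.nan), [0, 0],
                      [vocab.neutral_charge_index] * 2, [0], vocab)
    with pytest.raises(ValueError):
        MoleculeGraph(np.zeros((2, 3)), [0, 99],
                      [vocab.neutral_charge_index] * 2, [0], vocab)
    with pytest.raises(ValueError):
        MoleculeGraph(np.zeros((3, 3)), [0] * 3,
                      [vocab.neutral_charge_index] * 3, [0], vocab)


def test_rdkit_round_trip(vocab):
    g = _graph_from_smiles("CCO", vocab)
    mol = rdkit_from_graph(g)
    Chem.SanitizeMol(mol)
    assert Chem.MolToSmiles(Chem.RemoveHs(mol)) == "CCO"
    # coordinates are zero-centered on import
    assert np.allclose(g.coords.mean(axis=0), 0.0, atol=1e-12)


def test_serialization_guards(vocab):
    g = _graph_from_smiles("C", vocab)
    masked = g.copy()
    masked.atom_types[0] = vocab.atom_mask_index
    with pytest.raises(MaskedStateError):
        rdkit_from_graph(masked)
    fake = g.copy()
    fake.atom_types[0] = vocab.fake_index
    with pytest.raises(VocabularyError):
        rdkit_from_graph(fake)


def test_to_chem_object_invalid(vocab):
    # carbon bonded to five hydrogens: decodes but fails sanitization
    n = 6
    bonds = np.zeros(n_pairs(n), np.int64)
    for j in range(1, 6):
        bonds[pair_index(0, j, n)] = 1
    types = np.array([vocab.encode_element("C")] + [0] * 5)
    g = MoleculeGraph(np.random.default_rng(0).standard_normal((n, 3)), types,
                      np.full(n, vocab.neutral_charge_index), bonds, vocab)
    _, ok = to_chem_object(g)
    assert ok is False
    _, ok = to_chem_object(_graph_from_smiles("CCO", vocab))
    assert ok is True


def test_sdf_round_trip(tmp_path, vocab):
    graphs = [_graph_from_smiles(s, vocab) for s in ("CCO", "c1ccccc1")]
    path = tmp_path / "mols.sdf"
    assert write_structures(graphs, path) == 2
    back, skipped = read_structures(path)
    assert skipped == 0 and len(back) == 2
    for a, b in zip(graphs, back):
        assert np.array_equal(a.atom_types, b.atom_types)
        assert np.array_equal(a.bonds, b.bonds)
        assert np.allclose(a.coords, b.coords, atol=1e-3)  # SDF precision
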