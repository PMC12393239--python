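import numpy as np
import pytest

from atomflow._autodiff import Tensor
from atomflow.network import (Denoiser, ModelConfig, build_graph_batch,
                              load_checkpoint, rbf_expand, save_checkpoint)

from conftest import TINY_CFG, random_masked_state


def test_graph_batch_small_case():
    g = build_graph_batch((3,))
    assert g.total_nodes == 3
    assert g.total_edges == 6
    # i-major directed edges, no self loops
    expect = [(0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1)]
    assert list(zip(g.edge_src.tolist(), g.edge_dst.tolist())) == expect
    # edge_rev maps (i,j) to (j,i)
    for e in range(6):
        assert g.edge_src[g.edge_rev[e]] == g.edge_dst[e]
        assert g.edge_dst[g.edge_rev[e]] == g.edge_src[e]
    # condensed pair order (0,1),(0,2),(1,2)
    assert g.edge_pair.tolist() == [0, 1, 0, 2, 1, 2]
    # upper_edges selects src < dst edges in condensed order
    assert np.all(g.edge_src[g.upper_edges] < g.edge_dst[g.upper_edges])
    assert g.edge_pair[g.upper_edges].tolist() == [0, 1, 2]
    assert g.neighbor_count.tolist() == [2, 2, 2]


def test_graph_batch_offsets():
    g = build_graph_batch((2, 3))
    assert g.node_offset.tolist() == [0, 2]
    assert g.node_mol.tolist() == [0, 0, 1, 1, 1]
    # edges never cross molecules
    assert np.all(g.node_mol[g.edge_src] == g.node_mol[g.edge_dst])
    assert g.pair_slices == ((0, 1), (1, 4))


def test_rbf_expand_properties():
    d = Tensor(np.array([0.0, 2.5, 5.0]))
    out = rbf_expand(d, 8, 10.0)
    assert out.data.shape == (3, 8)
    assert np.all(out.data > 0) and np.all(out.data <= 1.0)
    # distance sitting exactly on a center activates it fully
    assert np.isclose(out.data[0, 0], 1.0)


def test_predict_endpoint_shapes(tiny_model, vocab, rng):
    st = random_masked_state(5, vocab, rng)
    pred = tiny_model.predict_endpoint(st)
    assert pred.coords_hat.shape == (5, 3)
    assert pred.type_logits.shape == (5, vocab.n_atom_types)
    assert pred.charge_logits.shape == (5, vocab.n_charges)
    assert pred.bond_logits.shape == (10, vocab.n_bond_orders)


def test_batch_equals_single(tiny_model, vocab, rng):
    """Block-diagonal batching must not change any molecule's output."""
    states = [random_masked_state(n, vocab, rng) for n in (4, 6, 5)]
    batched = tiny_model.predict_endpoint(states)
    for st, pb in zip(states, batched):
        ps = tiny_model.predict_endpoint(st)
        assert np.allclose(ps.coords_hat, pb.coords_hat, atol=1e-10)
        assert np.allclose(ps.type_logits, pb.type_logits, atol=1e-10)
        assert np.allclose(ps.bond_logits, pb.bond_logits, atol=1e-10)


def test_self_conditioning_changes_output(tiny_model, vocab, rng):
    st = random_masked_state(5, vocab, rng)
    base = tiny_model.predict_endpoint(st)
    cond = tiny_model.predict_endpoint(st, prev=base)
    assert not np.allclose(base.coords_hat, cond.coords_hat)
    # size mismatch between prev and state is rejected
    other = tiny_model.predict_endpoint(random_masked_state(6, vocab, rng))
    with pytest.raises(ValueError):
        tiny_model.predict_endpoint(st, prev=other)


def test_determinism(tiny_model, vocab):
    rng = np.random.default_rng(3)
    st = random_masked_state(5, vocab, rng)
    a = tiny_model.predict_endpoint(st)
    b = tiny_model.predict_endpoint(st)
    assert np.array_equal(a.coords_hat, b.coords_hat)


def test_checkpoint_round_trip(tmp_path, tiny_model, vocab, rng):
    path = tmp_path / "model.npz"
    save_checkpoint(tiny_model, path)
    restored = load_checkpoint(path)
    assert restored.cfg == tiny_model.cfg
    assert restored.vocab == tiny_model.vocab
    st = random_masked_state(5, vocab, rng)
    a = tiny_model.predict_endpoint(st)
    b = restored.predict_endpoint(st)
    assert np.array_equal(a.coords_hat, b.coords_hat)
    assert np.array_equal(a.bond_logits, b.bond_logits)


def test_parameter_count_scales():
    small = Denoiser(TINY_CFG, seed=0)
    big = Denoiser(ModelConfig(n_blocks=3, ds=32, dv=8, de=16, n_rbf=8,
                               time_embedding_dim=8, n_cross=2), seed=0)
    assert big.n_parameters() > small.n_parameters() > 0
    # named parameters are unique and cover all parameters
    names = [n for n, _ in small.named_parameters()]
    assert len(names) == len(set(names)) == len(small.parameters())


def test_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(n_blocks=0)
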