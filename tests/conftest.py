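import numpy as np
import pytest

import atomflow as af
from atomflow.molgraph import MoleculeGraph, Vocabulary, n_pairs
from atomflow.network import Denoiser, ModelConfig


TINY_CFG = ModelConfig(n_blocks=2, ds=16, dv=4, de=12, n_rbf=8,
                       time_embedding_dim=8, n_cross=2)


@pytest.fixture(scope="session")
def vocab():
    return Vocabulary()


@pytest.fixture(scope="session")
def toy10():
    return af.make_toy_dataset(10, seed=7)


@pytest.fixture(scope="session")
def tiny_model():
    return Denoiser(TINY_CFG, seed=0)


def random_masked_state(n, vocab, rng, t=0.5):
    """A random partially masked interpolant state (valid token ranges)."""
    v = vocab
    types1 = rng.integers(0, v.n_atom_types, size=n)
    charges1 = rng.integers(0, v.n_charges, size=n)
    bonds1 = rng.integers(0, v.n_bond_orders, size=n_pairs(n))
    at = np.where(rng.random(n) < t, types1, v.atom_mask_index)
    ct = np.where(rng.random(n) < t, charges1, v.charge_mask_index)
    et = np.where(rng.random(n_pairs(n)) < t, bonds1, v.bond_mask_index)
    g = MoleculeGraph(rng.standard_normal((n, 3)), at, ct, et, v)
    return af.InterpolantState(g, t)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
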