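"""Download-free synthetic data for testing and desk-scale experiments.

A frozen list of small drug-like SMILES ships with the package; 3D
conformers are embedded with RDKit's distance-geometry method (ETKDG) under
a fixed seed, so every fixture is deterministic and hermetic.
"""

from __future__ import annotations

import warnings
from importlib import resources

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .molgraph import MoleculeGraph, Vocabulary, graph_from_rdkit

__all__ = ["toy_smiles", "make_toy_dataset", "make_point_cloud"]


def toy_smiles():
    """The bundled (smiles, name) list."""
    text = resources.files("atomflow.data").joinpath("toy_smiles.smi").read_text()
    entries = []
    for line in text.strip().splitlines():
        smi, name = line.split()
        entries.append((smi, name))
    return entries


def _embed(smiles: str, seed: int, vocab: Vocabulary):
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    mol = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    if AllChem.EmbedMolecule(mol, params) != 0:
        return None
    Chem.Kekulize(mol, clearAromaticFlags=True)
    return graph_from_rdkit(mol, vocab)


def make_toy_dataset(n_mols: int, seed: int, max_heavy_atoms: int = 12,
                     vocab: Vocabulary = None):
    """Generate ``n_mols`` small 3D molecules deterministically.

    Molecules cycle through the bundled SMILES list (each pass uses a fresh
    embedding seed, so repeats are distinct conformers).  Every output has
    explicit hydrogens, kekulized bonds, and zero centroid.  Embedding
    failures are skipped with a warning.
    """
    vocab = vocab or Vocabulary()
    pool = [(smi, name) for smi, name in toy_smiles()
            if Chem.MolFromSmiles(smi).GetNumHeavyAtoms() <= max_heavy_atoms]
    out = []
    idx = 0
    attempts = 0
    while len(out) < n_mols and attempts < 10 * n_mols + 100:
        smi, name = pool[idx % len(pool)]
        # embedding seed must be deterministic in (seed, position); keep < 2^31
        embed_seed = (seed * 7919 + idx * 104729 + 1) % (2 ** 31 - 1)
        g = _embed(smi, embed_seed, vocab)
        idx += 1
        attempts += 1
        if g is None:
            warnings.warn(f"3D embedding failed for {name} ({smi}); skipping")
            continue
        out.append(g)
    return out


def make_point_cloud(n_points: int, seed: int) -> np.ndarray:
    """Standard-normal 3D point cloud, deterministic under seed."""
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n_points, 3))
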