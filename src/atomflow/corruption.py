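"""Train-time robustness features: fake-atom augmentation and late-stage
geometry distortion.

Fake atoms give the sampler a mechanism to add or remove atoms: a uniform
number of extra atoms (up to a fraction p of the real count) is appended to
each ground-truth molecule, each placed at a Gaussian offset from a randomly
chosen real "anchor" atom, typed as the fake class, neutral, and unbonded.

Geometry distortion perturbs a random subset of interpolated coordinates
for t past a threshold, so the denoiser learns to repair off-path
geometries instead of only ever seeing exact interpolants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .molgraph import MoleculeGraph, n_pairs, pair_index

__all__ = ["FakeAtomParams", "DistortionParams", "add_fake_atoms",
           "strip_fake_atoms", "distort_coords"]


@dataclass
class FakeAtomParams:
    """Fraction p of real atoms eligible as fake-atom head-room and the
    std-dev (Angstrom) of the Gaussian offset from the anchor atom."""

    p: float = 0.3
    offset_sigma: float = 1.0

    def __post_init__(self):
        if self.p < 0:
            raise ValueError("p must be >= 0")


@dataclass
class DistortionParams:
    """Bernoulli rate, time threshold, and displacement std-dev (Angstrom)
    of the late-stage coordinate perturbation."""

    p_distort: float = 0.2
    t_distort: float = 0.5
    sigma_distort: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.p_distort <= 1.0:
            raise ValueError("p_distort must be in [0, 1]")
        if not 0.0 <= self.t_distort <= 1.0:
            raise ValueError("t_distort must be in [0, 1]")
        if self.sigma_distort <= 0:
            raise ValueError("sigma_distort must be > 0")


def add_fake_atoms(g1: MoleculeGraph, params: FakeAtomParams,
                   rng: np.random.Generator) -> MoleculeGraph:
    """Append k ~ U{0, ..., floor(p N)} fake atoms to a ground-truth graph.

    Each fake atom gets a uniformly chosen real anchor, a position
    anchor + N(0, sigma^2 I), the fake atom-type token, the neutral charge
    token, and 'none' bonds to every other atom.
    """
    if g1.has_fake_atoms():
        raise ValueError("graph already contains fake atoms")
    v = g1.vocab
    n = g1.n_atoms
    k_max = int(np.floor(params.p * n))
    k = int(rng.integers(0, k_max + 1))
    if k == 0:
        return g1.copy()
    anchors = rng.integers(0, n, size=k)
    offsets = params.offset_sigma * rng.standard_normal((k, 3))
    coords = np.concatenate([g1.coords, g1.coords[anchors] + offsets])
    atom_types = np.concatenate(
        [g1.atom_types, np.full(k, v.fake_index, dtype=np.int64)])
    charges = np.concatenate(
        [g1.charges, np.full(k, v.neutral_charge_index, dtype=np.int64)])
    m = n + k
    mat = np.full((m, m), v.none_bond_index, dtype=np.int64)
    mat[:n, :n] = g1.bond_matrix()
    bonds = MoleculeGraph.bonds_from_matrix(mat)
    return MoleculeGraph(coords, atom_types, charges, bonds, v)


def strip_fake_atoms(g: MoleculeGraph) -> MoleculeGraph:
    """Remove fake-typed atoms and their incident bond entries, preserving
    the order of surviving atoms."""
    keep = np.flatnonzero(g.atom_types != g.vocab.fake_index)
    if keep.size == g.n_atoms:
        return g.copy()
    mat = g.bond_matrix()[np.ix_(keep, keep)]
    return MoleculeGraph(g.coords[keep], g.atom_types[keep],
                         g.charges[keep], MoleculeGraph.bonds_from_matrix(mat),
                         g.vocab)


def distort_coords(xt: np.ndarray, t: float, params: DistortionParams,
                   rng: np.random.Generator):
    """Perturb a Bernoulli(p_distort) subset of atoms by N(0, sigma^2 I)
    when t >= t_distort; returns (coords, flag mask) for diagnostics."""
    xt = np.asarray(xt, dtype=np.float64)
    n = xt.shape[0]
    if t < params.t_distort or params.p_distort == 0.0:
        return xt.copy(), np.zeros(n, dtype=bool)
    mask = rng.random(n) < params.p_distort
    eps = params.sigma_distort * rng.standard_normal((n, 3))
    return xt + mask[:, None] * eps, mask
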