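"""Molecular data model, categorical vocabularies, and SDF I/O.

A molecule is a fully-connected graph over atoms: Cartesian coordinates,
an atom-type token and a formal-charge token per atom, and a bond-order
token per unordered atom pair.  All categorical modalities carry one extra
*mask* token (the discrete-flow prior state); the atom-type vocabulary
additionally carries a *fake atom* class used by the generative model to
add and remove atoms.

Bond storage is one token per unordered pair ``i < j`` in condensed
(upper-triangle) order; directed edges are materialized only inside the
network, which guarantees symmetric bond assignments by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Vocabulary",
    "MoleculeGraph",
    "InterpolantState",
    "VocabularyError",
    "MaskedStateError",
    "read_structures",
    "write_structures",
    "to_chem_object",
    "pair_index",
    "n_pairs",
]

DEFAULT_ELEMENTS = ("H", "B", "C", "N", "O", "F", "Al", "Si", "P", "S",
                    "Cl", "As", "Br", "I", "Hg", "Bi")
DEFAULT_CHARGES = (-2, -1, 0, 1, 2, 3)
BOND_ORDERS = ("none", "single", "double", "triple")

_RDKIT_BOND = {
    "single": Chem.BondType.SINGLE,
    "double": Chem.BondType.DOUBLE,
    "triple": Chem.BondType.TRIPLE,
}
_BOND_TOKEN_FROM_RDKIT = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
}


class VocabularyError(ValueError):
    """An element, charge or bond order outside the configured vocabulary."""


class MaskedStateError(ValueError):
    """A mask token appeared where only terminal data states are allowed."""


def n_pairs(n_atoms: int) -> int:
    return n_atoms * (n_atoms - 1) // 2


def pair_index(i: int, j: int, n_atoms: int) -> int:
    """Condensed index of unordered pair (i, j), i != j, matching
    upper-triangle row-major order (same convention as scipy squareform)."""
    if i > j:
        i, j = j, i
    return i * n_atoms - i * (i + 1) // 2 + (j - i - 1)


@dataclass(frozen=True)
class Vocabulary:
    """Token vocabularies for the three categorical modalities.

    Data-state indices come first in each modality; the mask token is the
    final index.  The fake-atom class is a *data* state of the atom-type
    modality (it is a valid terminal state during generation; fake atoms
    are stripped before chemistry evaluation).
    """

    atom_elements: tuple = DEFAULT_ELEMENTS
    charges: tuple = DEFAULT_CHARGES
    bond_orders: tuple = BOND_ORDERS

    def __post_init__(self):
        if tuple(self.bond_orders) != BOND_ORDERS:
            raise VocabularyError(
                "bond vocabulary must be exactly (none, single, double, triple)")
        if 0 not in self.charges:
            raise VocabularyError("charge vocabulary must include 0")

    # --- sizes (data states only; logits use these widths) ---------------
    @property
    def n_atom_types(self) -> int:
        return len(self.atom_elements) + 1  # + fake class

    @property
    def n_charges(self) -> int:
        return len(self.charges)

    @property
    def n_bond_orders(self) -> int:
        return len(self.bond_orders)

    # --- special indices --------------------------------------------------
    @property
    def fake_index(self) -> int:
        return len(self.atom_elements)

    @property
    def atom_mask_index(self) -> int:
        return self.n_atom_types

    @property
    def charge_mask_index(self) -> int:
        return self.n_charges

    @property
    def bond_mask_index(self) -> int:
        return self.n_bond_orders

    @property
    def neutral_charge_index(self) -> int:
        return self.charges.index(0)

    @property
    def none_bond_index(self) -> int:
        return 0

    # --- encode / decode ---------------------------------------------------
    def encode_element(self, symbol: str) -> int:
        try:
            return self.atom_elements.index(symbol)
        except ValueError:
            raise VocabularyError(f"element {symbol!r} not in vocabulary") from None

    def decode_element(self, token: int) -> str:
        if token == self.fake_index:
            raise VocabularyError("fake-atom token has no element symbol")
        return self.atom_elements[token]

    def encode_charge(self, charge: int) -> int:
        try:
            return self.charges.index(charge)
        except ValueError:
            raise VocabularyError(f"formal charge {charge} not in vocabulary") from None

    def decode_charge(self, token: int) -> int:
        return self.charges[token]


@dataclass
class MoleculeGraph:
    """Full molecular state: coordinates plus categorical tokens.

    ``bonds`` holds one token per unordered atom pair in condensed order.
    """

    coords: np.ndarray
    atom_types: np.ndarray
    charges: np.ndarray
    bonds: np.ndarray
    vocab: Vocabulary = field(default_factory=Vocabulary)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        self.atom_types = np.asarray(self.atom_types, dtype=np.int64)
        self.charges = np.asarray(self.charges, dtype=np.int64)
        self.bonds = np.asarray(self.bonds, dtype=np.int64)
        n = self.n_atoms
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.atom_types.shape != (n,) or self.charges.shape != (n,):
            raise ValueError("atom_types/charges must have length n_atoms")
        if self.bonds.shape != (n_pairs(n),):
            raise ValueError("bonds must have length n_atoms*(n_atoms-1)/2")
        v = self.vocab
        if self.atom_types.size and (self.atom_types.min() < 0
                                     or self.atom_types.max() > v.atom_mask_index):
            raise ValueError("atom-type token out of range")
        if self.charges.size and (self.charges.min() < 0
                                  or self.charges.max() > v.charge_mask_index):
            raise ValueError("charge token out of range")
        if self.bonds.size and (self.bonds.min() < 0
                                or self.bonds.max() > v.bond_mask_index):
            raise ValueError("bond token out of range")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def has_mask_tokens(self) -> bool:
        v = self.vocab
        return bool(np.any(self.atom_types == v.atom_mask_index)
                    or np.any(self.charges == v.charge_mask_index)
                    or np.any(self.bonds == v.bond_mask_index))

    def has_fake_atoms(self) -> bool:
        return bool(np.any(self.atom_types == self.vocab.fake_index))

    def bond_matrix(self) -> np.ndarray:
        """Dense symmetric N x N token matrix (diagonal = 'none')."""
        n = self.n_atoms
        mat = np.full((n, n), self.vocab.none_bond_index, dtype=np.int64)
        iu = np.triu_indices(n, k=1)
        mat[iu] = self.bonds
        mat[iu[1], iu[0]] = self.bonds
        return mat

    @staticmethod
    def bonds_from_matrix(mat: np.ndarray) -> np.ndarray:
        n = mat.shape[0]
        if not np.array_equal(mat, mat.T):
            raise ValueError("bond matrix must be symmetric")
        return mat[np.triu_indices(n, k=1)].astype(np.int64)

    def copy(self) -> "MoleculeGraph":
        return MoleculeGraph(self.coords.copy(), self.atom_types.copy(),
                             self.charges.copy(), self.bonds.copy(), self.vocab)


@dataclass
class InterpolantState:
    """A molecule at time t on the conditional probability path."""

    graph: MoleculeGraph
    t: float

    def __post_init__(self):
        if not 0.0 <= self.t <= 1.0:
            raise ValueError(f"t={self.t} outside [0, 1]")


# ---------------------------------------------------------------------------
# RDKit conversion
# ---------------------------------------------------------------------------

def graph_from_rdkit(mol: Chem.Mol, vocab: Vocabulary,
                     center: bool = True) -> MoleculeGraph:
    """Build a MoleculeGraph from a sanitized, kekulized RDKit mol with a
    3D conformer.  Coordinates are shifted to zero centroid (the prior is a
    standard Gaussian at the origin)."""
    n = mol.GetNumAtoms()
    conf = mol.GetConformer()
    coords = np.array(conf.GetPositions(), dtype=np.float64)
    if center:
        coords = coords - coords.mean(axis=0)
    atom_types = np.empty(n, dtype=np.int64)
    charges = np.empty(n, dtype=np.int64)
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        atom_types[i] = vocab.encode_element(atom.GetSymbol())
        charges[i] = vocab.encode_charge(atom.GetFormalCharge())
    bonds = np.full(n_pairs(n), vocab.none_bond_index, dtype=np.int64)
    for bond in mol.GetBonds():
        token = _BOND_TOKEN_FROM_RDKIT.get(bond.GetBondType())
        if token is None:
            raise VocabularyError(
                f"bond type {bond.GetBondType()} not in kekulized vocabulary")
        bonds[pair_index(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), n)] = token
    return MoleculeGraph(coords, atom_types, charges, bonds, vocab)


def rdkit_from_graph(g: MoleculeGraph) -> Chem.RWMol:
    """Decode tokens to an (unsanitized) RDKit molecule with one conformer.

    Requires mask tokens absent and fake atoms stripped.
    """
    v = g.vocab
    if g.has_mask_tokens():
        raise MaskedStateError("cannot serialize masked state")
    if g.has_fake_atoms():
        raise VocabularyError("fake atoms must be stripped before decoding")
    mol = Chem.RWMol()
    for i in range(g.n_atoms):
        atom = Chem.Atom(v.decode_element(int(g.atom_types[i])))
        atom.SetFormalCharge(v.decode_charge(int(g.charges[i])))
        atom.SetNoImplicit(True)
        mol.AddAtom(atom)
    n = g.n_atoms
    for i in range(n):
        for j in range(i + 1, n):
            token = int(g.bonds[pair_index(i, j, n)])
            if token != v.none_bond_index:
                mol.AddBond(i, j, _RDKIT_BOND[v.bond_orders[token]])
    conf = Chem.Conformer(n)
    for i in range(n):
        conf.SetAtomPosition(i, tuple(float(x) for x in g.coords[i]))
    mol.AddConformer(conf)
    return mol


def to_chem_object(g: MoleculeGraph):
    """Decode a graph to an RDKit molecule and attempt sanitization.

    Returns ``(mol, ok)``; chemically invalid graphs (e.g. valence
    violations) yield ``ok=False`` rather than raising.
    """
    mol = rdkit_from_graph(g)
    try:
        Chem.SanitizeMol(mol)
        return mol, True
    except Exception:
        return mol, False


# ---------------------------------------------------------------------------
# SDF I/O
# ---------------------------------------------------------------------------

def prepare_rdkit_mol(mol: Chem.Mol, add_hydrogens: bool = False) -> Chem.Mol:
    """Sanitize, optionally add explicit hydrogens (with coordinates), and
    kekulize, clearing aromatic flags."""
    Chem.SanitizeMol(mol)
    if add_hydrogens:
        mol = Chem.AddHs(mol, addCoords=True)
    Chem.Kekulize(mol, clearAromaticFlags=True)
    return mol


def read_structures(path, add_hydrogens: bool = False, vocab: Vocabulary = None):
    """Read an SDF into MoleculeGraphs.

    Molecules that fail sanitization are skipped and counted; an element
    outside the vocabulary raises :class:`VocabularyError`.  Returns
    ``(graphs, n_skipped)``.
    """
    vocab = vocab or Vocabulary()
    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    if supplier is None:
        raise IOError(f"cannot read SDF file {path}")
    graphs, skipped = [], 0
    for mol in supplier:
        if mol is None:
            skipped += 1
            continue
        try:
            mol = prepare_rdkit_mol(mol, add_hydrogens=add_hydrogens)
        except VocabularyError:
            raise
        except Exception:
            skipped += 1
            continue
        graphs.append(graph_from_rdkit(mol, vocab))
    return graphs, skipped


def write_structures(mols, path) -> int:
    """Write MoleculeGraphs to an SDF (V2000).  Returns the record count.

    Mask tokens and fake atoms must be absent (strip fake atoms first).
    """
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)  # bonds are already kekulized tokens
    count = 0
    for g in mols:
        mol = rdkit_from_graph(g)
        writer.write(mol)
        count += 1
    writer.close()
    return count
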