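"""Evaluation suite: validity, functional-group deviation, ring-system
out-of-distribution rate, and the additive-effects trajectory analysis.

Functional-group frequency is the number of SMARTS-pattern instances per
molecule (counts, not presence).  The FG deviation between a reference set
and a sample is the L1 distance between their frequency tables over the
structural-alert pattern collection.  Ring systems are fused/spiro-connected
ring-atom groups, identified by the canonical SMILES of the ring-system
subgraph (substituents truncated); the OOD ring rate is the fraction of
ring-system *occurrences* whose identifier never appears in a reference
count table.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
from rdkit import Chem

from .molgraph import MoleculeGraph, to_chem_object

__all__ = ["MetricReport", "load_alert_patterns", "validity_rate",
           "fg_frequencies", "fg_deviation", "extract_ring_systems",
           "ood_ring_rate", "additive_effects_fit", "evaluate"]


@dataclass
class MetricReport:
    validity_rate: float
    fg_frequencies: dict
    fg_deviation: float = None
    ood_ring_rate: float = None
    n_molecules: int = 0

    def to_dict(self):
        return {
            "validity_rate": self.validity_rate,
            "fg_frequencies": self.fg_frequencies,
            "fg_deviation": self.fg_deviation,
            "ood_ring_rate": self.ood_ring_rate,
            "n_molecules": self.n_molecules,
        }


# ---------------------------------------------------------------------------
# Structural-alert patterns
# ---------------------------------------------------------------------------

def load_alert_patterns(path=None):
    """Read a SMARTS pattern file (one 'SMARTS name' per line, '#' comments).

    Defaults to the bundled Dundee + Glaxo Wellcome alert collections.
    Returns an ordered dict name -> compiled query; unparseable patterns
    raise a ValueError naming the pattern.
    """
    if path is None:
        texts = []
        for fname in ("alerts_dundee.smarts", "alerts_glaxo.smarts"):
            texts.append(resources.files("atomflow.data").joinpath(fname).read_text())
        text = "\n".join(texts)
    else:
        with open(path) as fh:
            text = fh.read()
    patterns = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        smarts, name = line.split(None, 1)
        query = Chem.MolFromSmarts(smarts)
        if query is None:
            raise ValueError(f"unparseable SMARTS pattern {name!r}: {smarts}")
        patterns[name.strip()] = query
    return patterns


def _as_rdkit(mols):
    """Sanitized RDKit molecules (and flags) from graphs or rdkit mols."""
    out = []
    for m in mols:
        if isinstance(m, MoleculeGraph):
            mol, ok = to_chem_object(m)
        else:
            mol, ok = m, True
        out.append((mol, ok))
    return out


def validity_rate(mols) -> float:
    """Fraction of molecules whose decoded chemistry sanitizes."""
    if len(mols) == 0:
        raise ValueError("empty molecule list")
    pairs = _as_rdkit(mols)
    return sum(ok for _, ok in pairs) / len(pairs)


def fg_frequencies(mols, patterns: dict) -> dict:
    """Per-pattern instance count across all molecules, divided by the
    number of molecules.  Unsanitizable molecules contribute no matches but
    count in the denominator."""
    if len(mols) == 0:
        raise ValueError("empty molecule list")
    counts = {name: 0 for name in patterns}
    for mol, ok in _as_rdkit(mols):
        if not ok:
            continue
        for name, query in patterns.items():
            counts[name] += len(mol.GetSubstructMatches(query, uniquify=True))
    n = len(mols)
    return {name: c / n for name, c in counts.items()}


def fg_deviation(sample_freqs: dict, reference_freqs: dict) -> float:
    """Sum over patterns of |reference frequency - sample frequency|."""
    if set(sample_freqs) != set(reference_freqs):
        raise ValueError("pattern sets differ between sample and reference")
    return float(sum(abs(reference_freqs[k] - sample_freqs[k])
                     for k in sample_freqs))


# ---------------------------------------------------------------------------
# Ring systems
# ---------------------------------------------------------------------------

def extract_ring_systems(mol) -> list:
    """Canonical identifiers of the ring systems in one molecule.

    Rings sharing at least one atom (fused or spiro) are merged into one
    system; each system is emitted as the canonical SMILES of its induced
    subgraph (ring atoms and the bonds among them, substituents truncated).
    Returns one identifier per occurrence (duplicates retained).
    """
    if isinstance(mol, MoleculeGraph):
        mol, ok = to_chem_object(mol)
        if not ok:
            return []
    rings = [set(r) for r in mol.GetRingInfo().AtomRings()]
    systems = []
    for ring in rings:
        merged = ring
        rest = []
        for sys_atoms in systems:
            if merged & sys_atoms:
                merged = merged | sys_atoms
            else:
                rest.append(sys_atoms)
        systems = rest + [merged]
    ids = []
    for atoms in systems:
        atoms = sorted(atoms)
        bonds = [b.GetIdx() for b in mol.GetBonds()
                 if b.GetBeginAtomIdx() in atoms and b.GetEndAtomIdx() in atoms]
        smi = Chem.MolFragmentToSmiles(mol, atomsToUse=atoms, bondsToUse=bonds,
                                       canonical=True)
        ids.append(smi)
    return ids


def ood_ring_rate(mols, reference: dict) -> float:
    """Fraction of ring-system occurrences absent from the reference
    identifier -> count table.  Molecules without rings contribute nothing;
    returns 0.0 if no ring systems are observed."""
    if reference is None:
        raise ValueError("a ring-system reference table is required")
    total, unseen = 0, 0
    for mol, ok in _as_rdkit(mols):
        if not ok:
            continue
        for ident in extract_ring_systems(mol):
            total += 1
            if reference.get(ident, 0) == 0:
                unseen += 1
    return unseen / total if total else 0.0


def ring_reference_from_mols(mols) -> dict:
    """Build an identifier -> count reference table from a molecule set."""
    table = {}
    for mol, ok in _as_rdkit(mols):
        if not ok:
            continue
        for ident in extract_ring_systems(mol):
            table[ident] = table.get(ident, 0) + 1
    return table


# ---------------------------------------------------------------------------
# Additive-effects analysis
# ---------------------------------------------------------------------------

def additive_effects_fit(responses: np.ndarray, design: np.ndarray):
    """Ordinary least squares of per-model responses on binary feature
    flags, with intercept, independently per time point.

    responses: (n_models, n_times); design: (n_models, n_features).
    Returns (coefficients (n_features, n_times), intercept (n_times,),
    relative effects coefficient/intercept).
    """
    responses = np.atleast_2d(np.asarray(responses, dtype=np.float64))
    design = np.atleast_2d(np.asarray(design, dtype=np.float64))
    n_models = design.shape[0]
    x = np.hstack([np.ones((n_models, 1)), design])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("design matrix (with intercept) is rank deficient")
    beta, *_ = np.linalg.lstsq(x, responses, rcond=None)
    intercept = beta[0]
    coeffs = beta[1:]
    relative = coeffs / intercept
    return coeffs, intercept, relative


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------

def evaluate(sample_mols, reference_mols=None, patterns: dict = None,
             ring_reference: dict = None) -> MetricReport:
    """Compute the full metric report for a sampled molecule set."""
    patterns = patterns if patterns is not None else load_alert_patterns()
    freqs = fg_frequencies(sample_mols, patterns)
    dev = None
    if reference_mols is not None:
        ref_freqs = fg_frequencies(reference_mols, patterns)
        dev = fg_deviation(freqs, ref_freqs)
    ood = None
    if ring_reference is not None:
        ood = ood_ring_rate(sample_mols, ring_reference)
    return MetricReport(
        validity_rate=validity_rate(sample_mols),
        fg_frequencies=freqs,
        fg_deviation=dev,
        ood_ring_rate=ood,
        n_molecules=len(sample_mols),
    )
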