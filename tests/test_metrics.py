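import numpy as np
import pytest
from rdkit import Chem

from atomflow.metrics import (additive_effects_fit, evaluate,
                              extract_ring_systems, fg_deviation,
                              fg_frequencies, load_alert_patterns,
                              ood_ring_rate, ring_reference_from_mols,
                              validity_rate)


def _mols(*smiles):
    return [Chem.MolFromSmiles(s) for s in smiles]


def test_load_bundled_alert_patterns():
    patterns = load_alert_patterns()
    assert len(patterns) >= 30
    assert all(q is not None for q in patterns.values())


def test_load_alert_patterns_bad_smarts(tmp_path):
    path = tmp_path / "bad.smarts"
    path.write_text("[NX3] amine\nC(( broken_pattern\n")
    with pytest.raises(ValueError, match="broken_pattern"):
        load_alert_patterns(path)


def test_load_alert_patterns_comments_and_blanks(tmp_path):
    path = tmp_path / "ok.smarts"
    path.write_text("# comment\n\n[OX2H] hydroxyl\n")
    patterns = load_alert_patterns(path)
    assert list(patterns) == ["hydroxyl"]


def test_validity_rate(toy10):
    assert validity_rate(toy10) == 1.0
    with pytest.raises(ValueError):
        validity_rate([])


def test_fg_frequencies_counts_instances():
    patterns = {
        "hydroxyl": Chem.MolFromSmarts("[OX2H]"),
        "nitro": Chem.MolFromSmarts("[N+](=O)[O-]"),
    }
    # ethylene glycol has two hydroxyls; phenol one; benzene none
    freqs = fg_frequencies(_mols("OCCO", "Oc1ccccc1", "c1ccccc1"), patterns)
    assert np.isclose(freqs["hydroxyl"], 3 / 3)
    assert freqs["nitro"] == 0.0


def test_fg_frequencies_order_and_duplication_invariance():
    patterns = {"hydroxyl": Chem.MolFromSmarts("[OX2H]")}
    mols = _mols("OCCO", "c1ccccc1")
    a = fg_frequencies(mols, patterns)
    b = fg_frequencies(mols[::-1], patterns)
    c = fg_frequencies(mols + mols, patterns)
    assert a == b == c


def test_fg_deviation_properties():
    a = {"x": 0.01, "y": 0.5}
    b = {"x": 0.03, "y": 0.5}
    assert np.isclose(fg_deviation(a, b), 0.02)
    assert fg_deviation(a, a) == 0.0
    assert fg_deviation(a, b) == fg_deviation(b, a)
    with pytest.raises(ValueError):
        fg_deviation(a, {"x": 0.0})


def test_extract_ring_systems_cases():
    assert extract_ring_systems(Chem.MolFromSmiles("CCC")) == []
    # biphenyl: two separate benzene systems with one identifier
    bi = extract_ring_systems(Chem.MolFromSmiles("c1ccc(-c2ccccc2)cc1"))
    assert len(bi) == 2 and len(set(bi)) == 1
    # decalin: one fused two-ring system
    deca = extract_ring_systems(Chem.MolFromSmiles("C1CCC2CCCCC2C1"))
    assert len(deca) == 1
    # naphthalene fused system differs from benzene
    benz = extract_ring_systems(Chem.MolFromSmiles("c1ccccc1"))
    naph = extract_ring_systems(Chem.MolFromSmiles("c1ccc2ccccc2c1"))
    assert benz[0] != naph[0]


def test_ood_ring_rate_cases():
    mols = _mols("c1ccccc1", "c1ccc(-c2ccccc2)cc1", "C1CCC2CCCCC2C1")
    # occurrences: benzene x3 (one + two in biphenyl), decalin x1
    ref = ring_reference_from_mols(_mols("c1ccccc1"))
    assert np.isclose(ood_ring_rate(mols, ref), 0.25)
    assert ood_ring_rate(mols, ring_reference_from_mols(mols)) == 0.0
    assert ood_ring_rate(mols, {}) == 1.0
    assert ood_ring_rate(_mols("CC"), {}) == 0.0
    with pytest.raises(ValueError):
        ood_ring_rate(mols, None)


def test_additive_effects_fit_exact_recovery(rng):
    n_models, n_features, n_times = 16, 3, 5
    design = rng.integers(0, 2, size=(n_models, n_features)).astype(float)
    while np.linalg.matrix_rank(np.hstack([np.ones((n_models, 1)), design])) < 4:
        design = rng.integers(0, 2, size=(n_models, n_features)).astype(float)
    true_coef = rng.standard_normal((n_features, n_times))
    true_icept = rng.standard_normal(n_times)
    responses = true_icept + design @ true_coef
    coef, icept, rel = additive_effects_fit(responses, design)
    assert np.allclose(coef, true_coef, atol=1e-10)
    assert np.allclose(icept, true_icept, atol=1e-10)
    assert np.allclose(rel, true_coef / true_icept, atol=1e-8)


def test_additive_effects_degenerate_cases(rng):
    design = np.array([[0.0], [1.0], [0.0], [1.0]])
    responses = np.full((4, 3), 2.5)
    coef, icept, _ = additive_effects_fit(responses, design)
    assert np.allclose(coef, 0.0, atol=1e-12)
    assert np.allclose(icept, 2.5)
    with pytest.raises(ValueError):
        additive_effects_fit(responses, np.ones((4, 2)))


def test_evaluate_report(toy10):
    patterns = {"hydroxyl": Chem.MolFromSmarts("[OX2H]")}
    report = evaluate(toy10, reference_mols=toy10, patterns=patterns,
                      ring_reference=ring_reference_from_mols(toy10))
    d = report.to_dict()
    assert d["validity_rate"] == 1.0
    assert d["fg_deviation"] == 0.0
    assert d["ood_ring_rate"] == 0.0
    assert d["n_molecules"] == 10
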