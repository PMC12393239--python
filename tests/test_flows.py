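import numpy as np
import pytest

from atomflow._autodiff import Tensor
from atomflow.flows import (DFMParams, EndpointPrediction, LossWeights,
                            coord_loss, coord_loss_weight,
                            discrete_transition, discrete_transition_batch,
                            endpoint_vector_field, interp_coords,
                            masked_ce_loss, probability_velocity,
                            sample_discrete_path, total_loss)


def test_interp_coords_endpoints(rng):
    x0 = rng.standard_normal((5, 3))
    x1 = rng.standard_normal((5, 3))
    assert np.allclose(interp_coords(x0, x1, 0.0), x0)
    assert np.allclose(interp_coords(x0, x1, 1.0), x1)
    mid = interp_coords(x0, x1, 0.25)
    assert np.allclose(mid, 0.75 * x0 + 0.25 * x1)
    with pytest.raises(ValueError):
        interp_coords(x0, x1, 1.5)


def test_endpoint_vector_field(rng):
    x0 = rng.standard_normal((4, 3))
    x1 = rng.standard_normal((4, 3))
    t = 0.3
    xt = interp_coords(x0, x1, t)
    # on the conditional path the learned field equals the true velocity x1-x0
    v = endpoint_vector_field(x1, xt, t)
    assert np.allclose(v, x1 - x0)
    with pytest.raises(ValueError):
        endpoint_vector_field(x1, xt, 1.0)


def test_coord_loss_weight_clamp_values():
    assert coord_loss_weight(0.001) == 0.005
    assert coord_loss_weight(0.5) == 1.0
    assert coord_loss_weight(0.99) == 1.5
    assert coord_loss_weight(1.0) == 1.5


def test_coord_loss_tensor_numpy_agree(rng):
    xh = rng.standard_normal((6, 3))
    x1 = rng.standard_normal((6, 3))
    a = coord_loss(xh, x1, 0.4)
    b = coord_loss(Tensor(xh, requires_grad=True), x1, 0.4)
    assert np.isclose(a, float(b.data))


def test_sample_discrete_path_endpoints(rng):
    tokens1 = rng.integers(0, 4, size=200)
    assert np.all(sample_discrete_path(tokens1, 0.0, rng, 4) == 4)
    assert np.array_equal(sample_discrete_path(tokens1, 1.0, rng, 4), tokens1)
    with pytest.raises(ValueError):
        sample_discrete_path(np.array([4]), 0.5, rng, 4)


def test_probability_velocity_rows_sum_to_zero(rng):
    p1 = rng.dirichlet(np.ones(4))
    for token, eta in [(4, 0.0), (4, 2.0), (1, 0.0), (1, 2.0)]:
        row = probability_velocity(p1, token, 0.3, eta, mask_index=4)
        assert row.shape == (5,)
        assert abs(row.sum()) < 1e-12
    # masked token flows toward data states at rate (1+eta t)/(1-t) p1
    row = probability_velocity(p1, 4, 0.5, 0.0, 4)
    assert np.allclose(row[:4], 2.0 * p1)
    # unmasked token flows toward mask at rate eta
    row = probability_velocity(p1, 2, 0.5, 3.0, 4)
    assert row[4] == 3.0 and row[2] == -3.0
    with pytest.raises(ValueError):
        probability_velocity(p1, 4, 1.0, 0.0, 4)


def test_discrete_transition_final_step_unmasks(rng):
    p1 = np.array([0.0, 1.0, 0.0, 0.0])
    # at the last step dt/(1-t) = 1: unmask probability is exactly 1
    row = probability_velocity(p1, 4, 1.0 - 0.01, 0.0, 4)
    out = [discrete_transition(4, row, 0.01, rng) for _ in range(50)]
    assert all(o == 1 for o in out)


def test_discrete_transition_eta0_never_remasks(rng):
    tokens = np.array([1, 2, 3, 0] * 50)
    p1 = np.tile(np.full(4, 0.25), (200, 1))
    out = discrete_transition_batch(tokens, p1, t=0.5, dt=0.01, eta=0.0,
                                    mask_index=4, rng=rng)
    assert np.array_equal(out, tokens)


def test_discrete_transition_batch_matches_scalar_law(rng):
    # masked tokens unmask with probability dt (1+eta t)/(1-t), binomial 3 sigma
    n = 20000
    t, dt, eta = 0.4, 0.05, 1.5
    p_unmask = dt * (1 + eta * t) / (1 - t)
    tokens = np.full(n, 4)
    p1 = np.tile(np.array([1.0, 0.0, 0.0, 0.0]), (n, 1))
    out = discrete_transition_batch(tokens, p1, t, dt, eta, 4, rng)
    frac = np.mean(out != 4)
    sigma = np.sqrt(p_unmask * (1 - p_unmask) / n)
    assert abs(frac - p_unmask) < 3 * sigma
    assert np.all(np.isin(out, [0, 4]))  # one-hot p1: only state 0 reachable


def test_masked_ce_loss_closed_forms(rng):
    d = 5
    logits = np.zeros((10, d))  # uniform predictor
    tokens1 = rng.integers(0, d, size=10)
    all_masked = np.full(10, d)
    assert np.isclose(masked_ce_loss(logits, tokens1, all_masked), np.log(d))
    assert masked_ce_loss(logits, tokens1, tokens1) == 0.0
    with pytest.raises(ValueError):
        masked_ce_loss(logits, all_masked, all_masked)
    # Tensor path agrees with numpy path
    tt = masked_ce_loss(Tensor(logits, requires_grad=True), tokens1, all_masked)
    assert np.isclose(float(tt.data), np.log(d))


def test_dfm_params():
    p = DFMParams(eta=0.0, n_steps=200)
    assert p.dt == 1.0 / 200
    with pytest.raises(ValueError):
        DFMParams(eta=-1.0)
    with pytest.raises(ValueError):
        DFMParams(n_steps=0)


def test_loss_weights_validation():
    with pytest.raises(ValueError):
        LossWeights(coords=-1.0)
    with pytest.raises(ValueError):
        LossWeights(coord_weight_clamp=(2.0, 1.0))


def test_total_loss_breakdown(toy10, rng, vocab):
    from atomflow.engine import _interpolant
    from atomflow.corruption import DistortionParams
    g1 = toy10[2]
    st = _interpolant(g1, 0.5, rng, DistortionParams())
    n = g1.n_atoms
    pred = EndpointPrediction(
        coords_hat=rng.standard_normal((n, 3)),
        type_logits=rng.standard_normal((n, vocab.n_atom_types)),
        charge_logits=rng.standard_normal((n, vocab.n_charges)),
        bond_logits=rng.standard_normal((len(g1.bonds), vocab.n_bond_orders)),
    )
    total, breakdown = total_loss(pred, g1, st, LossWeights())
    assert set(breakdown) == {"coords", "atom_types", "charges", "bonds"}
    assert total >= 0
    assert np.isclose(total, sum(breakdown.values()))


def test_endpoint_prediction_rejects_nonfinite(rng):
    with pytest.raises(ValueError):
        EndpointPrediction(np.full((2, 3), np.inf), np.zeros((2, 4)),
                           np.zeros((2, 3)), np.zeros((1, 4)))
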