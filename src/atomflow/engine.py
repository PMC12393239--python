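"""Training and sampling procedures.

Training: per molecule, append fake atoms, couple a Gaussian prior to the
target (alignment + assignment), draw t ~ U(0,1), sample the conditional
path of every modality, apply late-stage distortion, run the denoiser and
take an Adam step on the weighted multi-modal loss.  In half of the steps
the denoiser is run twice: the first (gradient-free) prediction is fed back
as the self-conditioning input of the second pass.

Sampling: Euler integration of the learned coordinate ODE and simultaneous
CTMC simulation of the categorical modalities on a uniform K-step grid,
self-conditioning on the previous step's prediction from the second step
onward; any token still masked after the final step is decoded from the
final prediction's argmax, and fake atoms are stripped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .corruption import (DistortionParams, FakeAtomParams, add_fake_atoms,
                         distort_coords, strip_fake_atoms)
from .coupling import couple
from .flows import (DFMParams, EndpointPrediction, LossWeights,
                    discrete_transition_batch, interp_coords,
                    sample_discrete_path, total_loss)
from .molgraph import InterpolantState, MoleculeGraph, n_pairs

__all__ = ["Adam", "TrajectoryRecord", "training_step", "train",
           "sample_molecules", "x1_movement", "empirical_size_sampler"]


class Adam:
    """Standard Adam over the model's parameter Tensors."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


@dataclass
class TrajectoryRecord:
    """Denoiser-output snapshots along one sampling trajectory."""

    times: list = field(default_factory=list)
    predictions: list = field(default_factory=list)
    states: list = None

    def __post_init__(self):
        t = np.asarray(self.times)
        if t.size and (np.any(np.diff(t) <= 0) or t.min() < 0 or t.max() >= 1):
            raise ValueError("times must be strictly increasing in [0, 1)")


def _interpolant(g1: MoleculeGraph, t: float, rng, dist_params: DistortionParams):
    """Sample g_t on the conditional path of every modality."""
    v = g1.vocab
    pair = couple(g1, rng)
    xt = interp_coords(pair.g0.coords, g1.coords, t)
    xt, _ = distort_coords(xt, t, dist_params, rng)
    at = sample_discrete_path(g1.atom_types, t, rng, v.atom_mask_index)
    ct = sample_discrete_path(g1.charges, t, rng, v.charge_mask_index)
    et = sample_discrete_path(g1.bonds, t, rng, v.bond_mask_index)
    return InterpolantState(MoleculeGraph(xt, at, ct, et, v), t)


def training_step(batch, model, optimizer: Adam, weights: LossWeights,
                  fa_params: FakeAtomParams, dist_params: DistortionParams,
                  rng: np.random.Generator, self_cond_prob: float = 0.5):
    """One Adam step on a batch of ground-truth molecules.

    Returns the per-modality loss breakdown (floats, averaged over the
    batch) under key names coords/atom_types/charges/bonds plus 'total'.
    """
    if len(batch) == 0:
        raise ValueError("batch must be nonempty")
    targets, states = [], []
    for g1 in batch:
        g1a = add_fake_atoms(g1, fa_params, rng)
        t = float(rng.random())
        targets.append(g1a)
        states.append(_interpolant(g1a, t, rng, dist_params))
    conditioned = (model.cfg.self_conditioning
                   and rng.random() < self_cond_prob)
    if conditioned:
        with np.errstate(over="ignore"):
            prev = model.predict_endpoint(states, grad=False)
        preds = model.predict_endpoint(states, prev=prev, grad=True)
    else:
        preds = model.predict_endpoint(states, grad=True)
    total = None
    breakdown_acc = {}
    for pred, g1a, st in zip(preds, targets, states):
        loss, breakdown = total_loss(pred, g1a, st, weights)
        total = loss if total is None else total + loss
        for k, val in breakdown.items():
            x = float(val.data) if hasattr(val, "data") else float(val)
            breakdown_acc[k] = breakdown_acc.get(k, 0.0) + x / len(batch)
    total = total * (1.0 / len(batch))
    optimizer.zero_grad()
    total.backward()
    optimizer.step()
    breakdown_acc["total"] = float(total.data)
    return breakdown_acc


def train(model, dataset, n_steps: int, batch_size: int, rng,
          lr: float = 1e-3, weights: LossWeights = None,
          fa_params: FakeAtomParams = None,
          dist_params: DistortionParams = None,
          log_file=None, log_every: int = 10):
    """Simple training loop; returns the per-step loss history."""
    weights = weights or LossWeights()
    fa_params = fa_params or FakeAtomParams()
    dist_params = dist_params or DistortionParams()
    optimizer = Adam(model.parameters(), lr=lr)
    history = []
    handle = open(log_file, "w") if log_file else None
    for step in range(n_steps):
        idx = rng.choice(len(dataset), size=min(batch_size, len(dataset)),
                         replace=False)
        batch = [dataset[i] for i in idx]
        breakdown = training_step(batch, model, optimizer, weights,
                                  fa_params, dist_params, rng)
        history.append(breakdown)
        if handle and step % log_every == 0:
            handle.write(json.dumps({"step": step, **breakdown}) + "\n")
    if handle:
        handle.close()
    return history


def empirical_size_sampler(dataset):
    """Size distribution fitted from the real-atom counts of a dataset."""
    sizes = np.asarray([g.n_atoms for g in dataset])

    def sampler(rng):
        return int(rng.choice(sizes))

    return sampler


def sample_molecules(model, n_mols: int, size_sampler, params: DFMParams,
                     rng: np.random.Generator, record: bool = False,
                     fake_headroom_p: float = 0.3):
    """Generate molecules with K Euler/CTMC steps (Algorithm-style loop).

    Capacity per molecule is a sampled real-atom count plus uniform
    fake-atom head-room mirroring the train-time law.  Returns the stripped
    molecule graphs, plus one TrajectoryRecord per molecule if ``record``.
    """
    if params.n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    v = model.vocab
    k_steps = params.n_steps
    eta = params.eta
    states = []
    for _ in range(n_mols):
        n_real = int(size_sampler(rng))
        cap = n_real + int(rng.integers(0, int(np.floor(fake_headroom_p * n_real)) + 1))
        g = MoleculeGraph(
            coords=rng.standard_normal((cap, 3)),
            atom_types=np.full(cap, v.atom_mask_index, dtype=np.int64),
            charges=np.full(cap, v.charge_mask_index, dtype=np.int64),
            bonds=np.full(n_pairs(cap), v.bond_mask_index, dtype=np.int64),
            vocab=v,
        )
        states.append(InterpolantState(g, 0.0))
    prev = None
    records = [TrajectoryRecord() for _ in range(n_mols)] if record else None
    preds = None
    for k in range(k_steps):
        t = k / k_steps
        use_prev = prev if (k >= 1 and model.cfg.self_conditioning) else None
        preds = model.predict_endpoint(states, prev=use_prev)
        if record:
            for rec, pred in zip(records, preds):
                rec.times.append(t)
                rec.predictions.append(pred)
        # exact step coefficients: 1 - t = (K - k)/K, dt/(1-t) = 1/(K-k)
        coef = 1.0 / (k_steps - k)
        new_states = []
        for st, pred in zip(states, preds):
            g = st.graph
            x = g.coords + coef * (pred.coords_hat - g.coords)
            at = _ctmc_step(g.atom_types, pred.type_logits, t, params.dt,
                            eta, v.atom_mask_index, rng)
            ct = _ctmc_step(g.charges, pred.charge_logits, t, params.dt,
                            eta, v.charge_mask_index, rng)
            et = _ctmc_step(g.bonds, pred.bond_logits, t, params.dt,
                            eta, v.bond_mask_index, rng)
            t_next = min((k + 1) / k_steps, 1.0)
            new_states.append(InterpolantState(
                MoleculeGraph(x, at, ct, et, v), t_next))
        states = new_states
        prev = preds
    out = []
    for st, pred in zip(states, preds):
        g = st.graph
        at = _fill_masked(g.atom_types, pred.type_logits, v.atom_mask_index)
        ct = _fill_masked(g.charges, pred.charge_logits, v.charge_mask_index)
        et = _fill_masked(g.bonds, pred.bond_logits, v.bond_mask_index)
        final = MoleculeGraph(g.coords, at, ct, et, v)
        out.append(strip_fake_atoms(final))
    if record:
        return out, records
    return out


def _ctmc_step(tokens, logits, t, dt, eta, mask_index, rng):
    from .network import _softmax_np
    return discrete_transition_batch(tokens, _softmax_np(logits), t, dt,
                                     eta, mask_index, rng)


def _fill_masked(tokens, logits, mask_index):
    tokens = tokens.copy()
    masked = tokens == mask_index
    if masked.any():
        tokens[masked] = logits[masked].argmax(axis=-1)
    return tokens


def x1_movement(traj: TrajectoryRecord) -> np.ndarray:
    """Mean per-atom displacement of the predicted endpoint between
    consecutive integration steps; length K-1."""
    preds = traj.predictions
    if len(preds) < 2:
        raise ValueError("need at least two snapshots")
    out = np.empty(len(preds) - 1)
    for i in range(len(preds) - 1):
        a = preds[i].coords_hat
        b = preds[i + 1].coords_hat
        out[i] = float(np.linalg.norm(b - a, axis=-1).mean())
    return out
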