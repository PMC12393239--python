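"""Conditional paths, vector fields, probability velocities, and losses.

Coordinates follow Euclidean conditional flow matching on a straight-line
(Dirac) path with endpoint parameterization: the network predicts the final
coordinates X1_hat and the learned velocity is (X1_hat - Xt)/(1 - t).

Categorical modalities (atom types, charges, bond orders) follow discrete
flow matching: a continuous-time Markov chain from an all-mask prior whose
conditional path puts probability t on the final state and 1 - t on mask.
Tokens unmask at rate (1 + eta*t)/(1 - t) and, for eta > 0, re-mask at rate
eta; eta = 0 gives pure progressive unmasking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import log_softmax as np_log_softmax

from ._autodiff import Tensor, log_softmax

__all__ = [
    "LossWeights", "DFMParams", "EndpointPrediction",
    "interp_coords", "endpoint_vector_field", "coord_loss_weight",
    "coord_loss", "sample_discrete_path", "probability_velocity",
    "discrete_transition", "masked_ce_loss", "total_loss",
]

COORD_WEIGHT_FLOOR = 0.005
COORD_WEIGHT_CEILING = 1.5


@dataclass
class LossWeights:
    """Per-modality loss weights lambda_m and the clamp on the coordinate
    loss's time weighting w(t) = clamp(t/(1-t))."""

    coords: float = 1.0
    atom_types: float = 1.0
    charges: float = 1.0
    bonds: float = 1.0
    coord_weight_clamp: tuple = (COORD_WEIGHT_FLOOR, COORD_WEIGHT_CEILING)

    def __post_init__(self):
        if min(self.coords, self.atom_types, self.charges, self.bonds) < 0:
            raise ValueError("loss weights must be >= 0")
        floor, ceiling = self.coord_weight_clamp
        if not floor < ceiling:
            raise ValueError("clamp floor must be below ceiling")


@dataclass
class DFMParams:
    """Discrete-flow sampling parameters: stochasticity eta and the number
    of uniform Euler/CTMC steps K (dt = 1/K)."""

    eta: float = 0.0
    n_steps: int = 250

    def __post_init__(self):
        if self.eta < 0:
            raise ValueError("eta must be >= 0")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")

    @property
    def dt(self) -> float:
        return 1.0 / self.n_steps


@dataclass
class EndpointPrediction:
    """Denoiser output: predicted final coordinates plus categorical logits
    over data states (fake-atom class included, mask excluded)."""

    coords_hat: np.ndarray
    type_logits: np.ndarray
    charge_logits: np.ndarray
    bond_logits: np.ndarray

    def __post_init__(self):
        for name in ("coords_hat", "type_logits", "charge_logits", "bond_logits"):
            arr = getattr(self, name)
            data = arr.data if isinstance(arr, Tensor) else arr
            if not np.all(np.isfinite(data)):
                raise ValueError(f"non-finite values in {name}")

    def detached(self) -> "EndpointPrediction":
        def d(x):
            return x.data.copy() if isinstance(x, Tensor) else np.asarray(x)
        return EndpointPrediction(d(self.coords_hat), d(self.type_logits),
                                  d(self.charge_logits), d(self.bond_logits))

    @property
    def n_atoms(self) -> int:
        x = self.coords_hat
        return (x.data if isinstance(x, Tensor) else x).shape[0]


# ---------------------------------------------------------------------------
# Continuous modality
# ---------------------------------------------------------------------------

def interp_coords(x0, x1, t: float):
    """Deterministic straight-line interpolant (1-t) x0 + t x1."""
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"t={t} outside [0, 1]")
    return (1.0 - t) * np.asarray(x0) + t * np.asarray(x1)


def endpoint_vector_field(coords_hat, xt, t: float):
    """Learned velocity under endpoint parameterization: (X1_hat - Xt)/(1-t)."""
    if t >= 1.0:
        raise ValueError("vector field is singular at t >= 1")
    return (np.asarray(coords_hat) - np.asarray(xt)) / (1.0 - t)


def coord_loss_weight(t: float, clamp=(COORD_WEIGHT_FLOOR, COORD_WEIGHT_CEILING)):
    """Clamped time weighting min(max(floor, t/(1-t)), ceiling)."""
    floor, ceiling = clamp
    if t >= 1.0:
        return ceiling
    return float(min(max(floor, t / (1.0 - t)), ceiling))


def _mse(a, b):
    diff = a - b
    return (diff * diff).mean() if isinstance(diff, Tensor) else float(np.mean(diff ** 2))


def coord_loss(coords_hat, x1, t: float,
               clamp=(COORD_WEIGHT_FLOOR, COORD_WEIGHT_CEILING)):
    """w(t) times the MSE between predicted and true final coordinates
    (mean over atoms and axes)."""
    w = coord_loss_weight(t, clamp)
    if isinstance(coords_hat, Tensor):
        return _mse(coords_hat, Tensor(np.asarray(x1))) * w
    return w * _mse(np.asarray(coords_hat), np.asarray(x1))


# ---------------------------------------------------------------------------
# Discrete modality
# ---------------------------------------------------------------------------

def sample_discrete_path(tokens1: np.ndarray, t: float,
                         rng: np.random.Generator, mask_index: int) -> np.ndarray:
    """Each token independently equals its final state with probability t,
    else the mask token."""
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"t={t} outside [0, 1]")
    tokens1 = np.asarray(tokens1, dtype=np.int64)
    if np.any(tokens1 == mask_index):
        raise ValueError("final tokens may not contain the mask state")
    keep = rng.random(tokens1.shape) < t
    return np.where(keep, tokens1, mask_index)


def probability_velocity(p1_probs: np.ndarray, token_t: int, t: float,
                         eta: float, mask_index: int) -> np.ndarray:
    """CTMC probability-velocity row over all states (data states + mask).

    Masked token: flow (1 + eta*t)/(1 - t) * p1(j) toward each data state j.
    Unmasked token: flow eta toward mask.  The diagonal entry is minus the
    off-diagonal sum, so the row sums to zero.
    """
    if t >= 1.0:
        raise ValueError("probability velocity is singular at t >= 1")
    p1 = np.asarray(p1_probs, dtype=np.float64)
    d = p1.shape[-1]
    row = np.zeros(d + 1)
    if token_t == mask_index:
        row[:d] = (1.0 + eta * t) / (1.0 - t) * p1
    else:
        row[mask_index] = eta
    row[token_t] = -row.sum() + row[token_t]
    return row


_warned_overflow = False


def discrete_transition(token_t: int, velocity_row: np.ndarray, dt: float,
                        rng: np.random.Generator) -> int:
    """One CTMC Euler step: sample Categorical(delta(current) + velocity*dt).

    Negative raw probabilities (possible from the diagonal at large eta*dt
    or at the final step) are clamped to zero and the row renormalized; a
    raw probability above one is warned about once per process.
    """
    global _warned_overflow
    probs = np.asarray(velocity_row, dtype=np.float64) * dt
    probs[token_t] += 1.0
    if probs.max() > 1.0 + 1e-12 and not _warned_overflow:
        warnings.warn("transition probability exceeded 1; clamping")
        _warned_overflow = True
    probs = np.clip(probs, 0.0, None)
    total = probs.sum()
    if total <= 0.0:
        return int(token_t)
    probs /= total
    return int(rng.choice(probs.size, p=probs))


def discrete_transition_batch(tokens_t: np.ndarray, p1_probs: np.ndarray,
                              t: float, dt: float, eta: float,
                              mask_index: int,
                              rng: np.random.Generator) -> np.ndarray:
    """Vectorized CTMC Euler step for a batch of independent tokens.

    Equivalent to calling :func:`probability_velocity` +
    :func:`discrete_transition` per token.
    """
    tokens_t = np.asarray(tokens_t, dtype=np.int64)
    n, d = p1_probs.shape
    probs = np.zeros((n, d + 1))
    masked = tokens_t == mask_index
    rate = (1.0 + eta * t) / (1.0 - t)
    probs[masked, :d] = rate * p1_probs[masked] * dt
    probs[~masked, mask_index] = eta * dt
    rows = np.arange(n)
    probs[rows, tokens_t] = 0.0
    off_sum = probs.sum(axis=1)
    probs[rows, tokens_t] = 1.0 - off_sum
    probs = np.clip(probs, 0.0, None)
    probs /= probs.sum(axis=1, keepdims=True)
    cum = np.cumsum(probs, axis=1)
    u = rng.random((n, 1))
    return (u < cum).argmax(axis=1).astype(np.int64)


def masked_ce_loss(logits, tokens1: np.ndarray, tokens_t: np.ndarray,
                   mask_index: int = None):
    """Cross-entropy over items currently masked; 0 if none are masked.

    ``mask_index`` defaults to the logit width (mask is the final token
    index and logits cover data states only).
    """
    tokens1 = np.asarray(tokens1, dtype=np.int64)
    tokens_t = np.asarray(tokens_t, dtype=np.int64)
    is_tensor = isinstance(logits, Tensor)
    data = logits.data if is_tensor else np.asarray(logits, dtype=np.float64)
    d = data.shape[-1]
    mask_index = d if mask_index is None else mask_index
    if np.any(tokens1 == mask_index) or np.any(tokens1 >= d):
        raise ValueError("final tokens may not contain the mask state")
    sel = np.flatnonzero(tokens_t == mask_index)
    if sel.size == 0:
        return Tensor(0.0) if is_tensor else 0.0
    if is_tensor:
        logp = log_softmax(logits, axis=-1)
        picked = logp[(sel, tokens1[sel])]
        return -picked.mean()
    logp = np_log_softmax(data, axis=-1)
    return float(-logp[sel, tokens1[sel]].mean())


def total_loss(pred: EndpointPrediction, g1, gt_state, weights: LossWeights):
    """Weighted sum of per-modality losses; returns (total, breakdown)."""
    g = gt_state.graph
    t = gt_state.t
    lx = coord_loss(pred.coords_hat, g1.coords, t, weights.coord_weight_clamp)
    la = masked_ce_loss(pred.type_logits, g1.atom_types, g.atom_types)
    lc = masked_ce_loss(pred.charge_logits, g1.charges, g.charges)
    le = masked_ce_loss(pred.bond_logits, g1.bonds, g.bonds)
    total = (weights.coords * lx + weights.atom_types * la
             + weights.charges * lc + weights.bonds * le)
    breakdown = {"coords": lx, "atom_types": la, "charges": lc, "bonds": le}
    return total, breakdown
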