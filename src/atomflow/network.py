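"""The denoiser network: cross-product GVP layers and Molecule Update Blocks.

Molecules are fully-connected directed graphs.  Each node carries a
position, invariant scalar features and rank-1 geometric vector features;
each directed edge carries invariant scalar features.  A forward pass runs
input embedding, an optional self-conditioning residual, ``n_blocks``
Molecule Update Blocks (node feature update -> node position update -> edge
feature update), and shallow prediction heads.  Final node positions are
the predicted endpoint coordinates.

The Geometric Vector Perceptron here augments the usual norm/gating wiring
with channel-wise cross products of linearly mixed input vectors.  Cross
products of true vectors are pseudovectors, so mixing the two breaks mirror
symmetry: the network is equivariant to rotations and translations (SE(3))
but, deliberately, not to reflections, and can therefore distinguish
stereoisomers.

Several molecules are processed at once as one block-diagonal graph (edges
only within molecules), so batched training and sampling need no padding.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from ._autodiff import Tensor, concat, cross, index_sum
from .flows import EndpointPrediction
from .molgraph import InterpolantState, Vocabulary

__all__ = ["ModelConfig", "NetworkState", "GVP", "MoleculeUpdateBlock",
           "Denoiser", "GraphBatch", "build_graph_batch", "gvp_apply",
           "save_checkpoint", "load_checkpoint"]

_EPS = 1e-8


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    n_blocks: int = 4
    ds: int = 64            # node scalar width
    dv: int = 16            # node vector channels
    de: int = 32            # edge scalar width
    n_rbf: int = 16         # radial basis functions for distances
    rbf_max: float = 10.0   # Angstrom; basis centers span [0, rbf_max]
    time_embedding_dim: int = 16
    self_conditioning: bool = True
    n_cross: int = 4        # cross-product channels per GVP

    def __post_init__(self):
        for name in ("n_blocks", "ds", "dv", "de", "n_rbf",
                     "time_embedding_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


# ---------------------------------------------------------------------------
# Graph bookkeeping for block-diagonal batches
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GraphBatch:
    """Index structure for a batch of fully-connected molecular graphs."""

    n_atoms: tuple                 # per-molecule atom counts
    node_offset: np.ndarray        # start index of each molecule's nodes
    node_mol: np.ndarray           # molecule index per node
    edge_src: np.ndarray           # sender node per directed edge
    edge_dst: np.ndarray           # receiver node per directed edge
    edge_rev: np.ndarray           # index of the reversed edge
    edge_pair: np.ndarray          # condensed unordered-pair index per edge
    pair_slices: tuple             # (start, stop) into condensed arrays per mol
    upper_edges: np.ndarray        # edges with src < dst, in condensed order
    neighbor_count: np.ndarray     # in-degree per node (n_i - 1)

    @property
    def total_nodes(self) -> int:
        return int(self.node_mol.size)

    @property
    def total_edges(self) -> int:
        return int(self.edge_src.size)


@lru_cache(maxsize=512)
def build_graph_batch(n_atoms: tuple) -> GraphBatch:
    srcs, dsts, revs, pairs, uppers = [], [], [], [], []
    node_mol, counts = [], []
    node_off, pair_off, edge_off = 0, 0, 0
    pair_slices, node_offsets = [], []
    for m, n in enumerate(n_atoms):
        node_offsets.append(node_off)
        i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        keep = i != j
        ii, jj = i[keep], j[keep]          # i-major directed edge order
        e_index = np.full((n, n), -1, dtype=np.int64)
        e_index[ii, jj] = np.arange(ii.size)
        srcs.append(ii + node_off)
        dsts.append(jj + node_off)
        revs.append(e_index[jj, ii] + edge_off)
        lo, hi = np.minimum(ii, jj), np.maximum(ii, jj)
        pairs.append(lo * n - lo * (lo + 1) // 2 + (hi - lo - 1) + pair_off)
        # upper-triangle edges ordered to match the condensed pair layout
        up = e_index[np.triu_indices(n, k=1)] + edge_off
        uppers.append(up)
        node_mol.append(np.full(n, m, dtype=np.int64))
        counts.append(np.full(n, max(n - 1, 1), dtype=np.int64))
        pair_slices.append((pair_off, pair_off + n * (n - 1) // 2))
        node_off += n
        pair_off += n * (n - 1) // 2
        edge_off += ii.size
    return GraphBatch(
        n_atoms=tuple(n_atoms),
        node_offset=np.asarray(node_offsets, dtype=np.int64),
        node_mol=np.concatenate(node_mol),
        edge_src=np.concatenate(srcs),
        edge_dst=np.concatenate(dsts),
        edge_rev=np.concatenate(revs),
        edge_pair=np.concatenate(pairs),
        pair_slices=tuple(pair_slices),
        upper_edges=np.concatenate(uppers),
        neighbor_count=np.concatenate(counts),
    )


@dataclass
class NetworkState:
    """Features flowing through the network for one block-diagonal batch."""

    positions: Tensor        # (Nn, 3)
    node_scalars: Tensor     # (Nn, ds)
    node_vectors: Tensor     # (Nn, dv, 3)
    edge_scalars: Tensor     # (Ne, de)
    graph: GraphBatch


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------

class Module:
    """Tiny parameter container with recursive named-parameter traversal."""

    def parameters(self):
        return [t for _, t in self.named_parameters()]

    def named_parameters(self, prefix=""):
        out = []
        for name in sorted(vars(self)):
            val = vars(self)[name]
            if isinstance(val, Tensor):
                out.append((prefix + name, val))
            elif isinstance(val, Module):
                out.extend(val.named_parameters(prefix + name + "."))
            elif isinstance(val, (list, tuple)):
                for k, item in enumerate(val):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(f"{prefix}{name}.{k}."))
        return out

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


class Linear(Module):
    def __init__(self, d_in, d_out, rng, bias=True):
        self.weight = Tensor(rng.standard_normal((d_in, d_out)) / np.sqrt(d_in),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x):
        out = x @ self.weight
        return out + self.bias if self.bias is not None else out


class MLP(Module):
    """Two-layer perceptron with SiLU, linear output."""

    def __init__(self, d_in, d_hidden, d_out, rng):
        self.lin1 = Linear(d_in, d_hidden, rng)
        self.lin2 = Linear(d_hidden, d_out, rng)

    def __call__(self, x):
        return self.lin2(self.lin1(x).silu())


class ChannelMix(Module):
    """Linear mix of vector channels: (out, in) weight applied to (.., in, 3)."""

    def __init__(self, n_in, n_out, rng):
        self.weight = Tensor(rng.standard_normal((n_out, n_in)) / np.sqrt(n_in),
                             requires_grad=True)

    def __call__(self, v):
        return self.weight @ v


def _vec_norms(v: Tensor) -> Tensor:
    return ((v * v).sum(axis=-1) + _EPS).sqrt()


class GVP(Module):
    """Geometric vector perceptron with cross-product channels.

    Maps (scalars (.., in_s), vectors (.., in_v, 3)) to widths
    (out_s, out_v).  Scalar outputs are rotation- and reflection-invariant;
    vector outputs are equivariant to proper rotations only, because
    ``n_cross`` channels are cross products of mixed input vectors.
    Setting ``gate_identity`` disables the final vector-gating nonlinearity
    (used by the position-update head so zero vectors map to zero exactly).
    """

    def __init__(self, in_s, in_v, out_s, out_v, rng, n_cross=4,
                 scalar_act="silu", gate_identity=False):
        assert in_v >= 1
        self.in_s, self.in_v, self.out_s, self.out_v = in_s, in_v, out_s, out_v
        h_v = max(in_v, out_v, 1)
        self.wh = ChannelMix(in_v, h_v, rng)
        self.n_cross = n_cross
        if n_cross > 0:
            self.wa = ChannelMix(in_v, n_cross, rng)
            self.wb = ChannelMix(in_v, n_cross, rng)
        self.ws = Linear(in_s + h_v + n_cross, out_s, rng) if out_s else None
        self.wmu = ChannelMix(h_v + n_cross, out_v, rng) if out_v else None
        self.scalar_act = scalar_act
        self.gate_identity = gate_identity
        if out_v and not gate_identity:
            gate_in = out_s if out_s else in_s + h_v + n_cross
            self.wg = Linear(gate_in, out_v, rng)

    def __call__(self, s, v):
        vh = self.wh(v)
        feats = vh
        if self.n_cross > 0:
            feats = concat([vh, cross(self.wa(v), self.wb(v))], axis=-2)
        s_cat = concat([s, _vec_norms(feats)], axis=-1)
        s_out = None
        if self.ws is not None:
            s_out = self.ws(s_cat)
            if self.scalar_act == "silu":
                s_out = s_out.silu()
        v_out = None
        if self.wmu is not None:
            v_out = self.wmu(feats)
            if not self.gate_identity:
                gate = self.wg(s_out if s_out is not None else s_cat).sigmoid()
                nd = v_out.ndim
                v_out = v_out * gate.reshape(*gate.shape, 1)
        return s_out, v_out


def gvp_apply(gvp: GVP, scalars, vectors):
    """Functional form of a GVP forward pass."""
    return gvp(scalars, vectors)


class GVPChain(Module):
    def __init__(self, layers):
        self.layers = list(layers)

    def __call__(self, s, v):
        for layer in self.layers:
            s, v = layer(s, v)
        return s, v


class LayerNorm(Module):
    def __init__(self, d, rng):
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)

    def __call__(self, x):
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * (var + _EPS) ** -0.5 * self.gamma + self.beta


def _vector_norm_layer(v: Tensor) -> Tensor:
    """Scale vector channels by the RMS of their norms (no learned params)."""
    sq = (v * v).sum(axis=-1).mean(axis=-1, keepdims=True)  # (.., 1)
    scale = (sq + _EPS) ** -0.5
    return v * scale.reshape(*scale.shape, 1)


def rbf_expand(d: Tensor, n_rbf: int, rbf_max: float) -> Tensor:
    """Gaussian radial basis embedding of distances; centers evenly spaced
    on [0, rbf_max], width equal to the spacing."""
    centers = np.linspace(0.0, rbf_max, n_rbf)
    width = rbf_max / max(n_rbf - 1, 1)
    dd = d.reshape(*d.shape, 1) if isinstance(d, Tensor) else \
        Tensor(np.asarray(d)[..., None])
    z = (dd - centers) * (1.0 / width)
    return (z * z * -0.5).exp()


class MoleculeUpdateBlock(Module):
    """One NFU -> NPU -> EFU stage."""

    def __init__(self, cfg: ModelConfig, rng):
        ds, dv, de, nc = cfg.ds, cfg.dv, cfg.de, cfg.n_cross
        msg_s = ds + de + cfg.n_rbf
        msg_v = dv + 1
        self.psi_m = GVPChain([
            GVP(msg_s, msg_v, ds, dv, rng, n_cross=nc),
            GVP(ds, dv, ds, dv, rng, n_cross=nc),
            GVP(ds, dv, ds, dv, rng, n_cross=nc, scalar_act="none"),
        ])
        self.psi_u = GVPChain([
            GVP(ds, dv, ds, dv, rng, n_cross=nc),
            GVP(ds, dv, ds, dv, rng, n_cross=nc),
            GVP(ds, dv, ds, dv, rng, n_cross=nc, scalar_act="none"),
        ])
        self.psi_x = GVPChain([
            GVP(ds, dv, ds, dv, rng, n_cross=nc),
            GVP(ds, dv, ds, dv, rng, n_cross=nc),
            GVP(ds, dv, 0, 1, rng, n_cross=nc, gate_identity=True),
        ])
        self.phi_e = MLP(2 * ds + cfg.n_rbf, de, de, rng)
        self.ln_node = LayerNorm(ds, rng)
        self.ln_edge = LayerNorm(de, rng)
        self.cfg = cfg

    def _edge_geometry(self, positions, graph):
        rel = positions[graph.edge_src] - positions[graph.edge_dst]
        d = ((rel * rel).sum(axis=-1) + _EPS).sqrt()
        return rel, d

    def node_feature_update(self, state: NetworkState) -> NetworkState:
        g = state.graph
        rel, d = self._edge_geometry(state.positions, g)
        unit = rel * d.reshape(*d.shape, 1) ** -1.0
        rbf = rbf_expand(d, self.cfg.n_rbf, self.cfg.rbf_max)
        msg_s_in = concat([state.node_scalars[g.edge_src],
                           state.edge_scalars, rbf], axis=-1)
        msg_v_in = concat([state.node_vectors[g.edge_src],
                           unit.reshape(-1, 1, 3)], axis=-2)
        ms, mv = self.psi_m(msg_s_in, msg_v_in)
        inv = 1.0 / g.neighbor_count.astype(np.float64)
        agg_s = index_sum(ms, g.edge_dst, g.total_nodes) * inv[:, None]
        agg_v = index_sum(mv, g.edge_dst, g.total_nodes) * inv[:, None, None]
        us, uv = self.psi_u(agg_s, agg_v)
        s = self.ln_node(state.node_scalars + us)
        v = _vector_norm_layer(state.node_vectors + uv)
        return NetworkState(state.positions, s, v, state.edge_scalars, g)

    def node_position_update(self, state: NetworkState) -> NetworkState:
        _, dx = self.psi_x(state.node_scalars, state.node_vectors)
        x = state.positions + dx.reshape(-1, 3)
        return NetworkState(x, state.node_scalars, state.node_vectors,
                            state.edge_scalars, state.graph)

    def edge_feature_update(self, state: NetworkState) -> NetworkState:
        g = state.graph
        _, d = self._edge_geometry(state.positions, g)
        rbf = rbf_expand(d, self.cfg.n_rbf, self.cfg.rbf_max)
        upd = self.phi_e(concat([state.node_scalars[g.edge_src],
                                 state.node_scalars[g.edge_dst], rbf], axis=-1))
        e = self.ln_edge(state.edge_scalars + upd)
        return NetworkState(state.positions, state.node_scalars,
                            state.node_vectors, e, g)

    def __call__(self, state: NetworkState) -> NetworkState:
        state = self.node_feature_update(state)
        state = self.node_position_update(state)
        return self.edge_feature_update(state)


def sinusoidal_embedding(t: np.ndarray, dim: int) -> np.ndarray:
    half = dim // 2
    freqs = np.exp(np.linspace(0.0, np.log(1000.0), half))
    args = np.asarray(t)[..., None] * freqs
    return np.concatenate([np.sin(args), np.cos(args)], axis=-1)


class Denoiser(Module):
    """The full endpoint-predicting network f_theta(g_t) -> g1_hat."""

    def __init__(self, cfg: ModelConfig, vocab: Vocabulary = None, seed: int = 0):
        self.cfg = cfg
        self.vocab = vocab or Vocabulary()
        rng = np.random.default_rng(seed)
        v = self.vocab
        ds, de = cfg.ds, cfg.de
        emb = 32
        # +1 rows for the mask token of each modality
        self.type_emb = Tensor(0.1 * rng.standard_normal((v.n_atom_types + 1, emb)),
                               requires_grad=True)
        self.charge_emb = Tensor(0.1 * rng.standard_normal((v.n_charges + 1, emb // 2)),
                                 requires_grad=True)
        self.bond_emb = Tensor(0.1 * rng.standard_normal((v.n_bond_orders + 1, de)),
                               requires_grad=True)
        self.node_in = MLP(emb + emb // 2 + cfg.time_embedding_dim, ds, ds, rng)
        if cfg.self_conditioning:
            self.sc_node = MLP(cfg.n_rbf + v.n_atom_types + v.n_charges, ds, ds, rng)
            self.sc_edge = MLP(v.n_bond_orders + cfg.n_rbf, de, de, rng)
            self.sc_vec = ChannelMix(1, cfg.dv, rng)
        self.blocks = [MoleculeUpdateBlock(cfg, rng) for _ in range(cfg.n_blocks)]
        self.type_head = MLP(ds, ds, v.n_atom_types, rng)
        self.charge_head = MLP(ds, ds, v.n_charges, rng)
        self.bond_head = MLP(de, de, v.n_bond_orders, rng)

    # -- embedding ---------------------------------------------------------
    def embed_inputs(self, states, graph: GraphBatch) -> NetworkState:
        """Initial features: node scalars from (type, charge, time) through
        a shallow MLP; edge scalars from the bond-token embedding; node
        vectors zero; positions copied."""
        cfg = self.cfg
        coords = np.concatenate([st.graph.coords for st in states])
        types = np.concatenate([st.graph.atom_types for st in states])
        charges = np.concatenate([st.graph.charges for st in states])
        bonds = np.concatenate([st.graph.bonds for st in states])
        t_mol = np.asarray([st.t for st in states])
        t_emb = sinusoidal_embedding(t_mol, cfg.time_embedding_dim)[graph.node_mol]
        s0 = self.node_in(concat([self.type_emb[types],
                                  self.charge_emb[charges],
                                  Tensor(t_emb)], axis=-1))
        e0 = self.bond_emb[bonds[graph.edge_pair]]
        v0 = Tensor(np.zeros((graph.total_nodes, cfg.dv, 3)))
        return NetworkState(Tensor(coords), s0, v0, e0, graph)

    # -- self-conditioning -------------------------------------------------
    def self_conditioning_residual(self, states, prev, graph: GraphBatch,
                                   state: NetworkState) -> NetworkState:
        """Residual node/edge embeddings from the difference between the
        current state and the previous endpoint prediction; exact bypass
        (zero residual) when no previous prediction exists."""
        if prev is None or not self.cfg.self_conditioning:
            return state
        for st, pr in zip(states, prev):
            if pr.n_atoms != st.graph.n_atoms:
                raise ValueError("self-conditioning size mismatch")
        prev = [p.detached() for p in prev]
        xhat = np.concatenate([p.coords_hat for p in prev])
        xt = np.concatenate([st.graph.coords for st in states])
        delta = xhat - xt
        dn = np.sqrt((delta ** 2).sum(axis=-1) + _EPS)
        rbf_d = rbf_expand(Tensor(dn), self.cfg.n_rbf, self.cfg.rbf_max)
        type_p = _softmax_np(np.concatenate([p.type_logits for p in prev]))
        charge_p = _softmax_np(np.concatenate([p.charge_logits for p in prev]))
        node_res = self.sc_node(concat([rbf_d, Tensor(type_p),
                                        Tensor(charge_p)], axis=-1))
        vec_res = self.sc_vec(Tensor(delta[:, None, :]))
        bond_p = _softmax_np(np.concatenate([p.bond_logits for p in prev]))
        d_prev = np.sqrt(((xhat[graph.edge_src] - xhat[graph.edge_dst]) ** 2
                          ).sum(axis=-1) + _EPS)
        rbf_prev = rbf_expand(Tensor(d_prev), self.cfg.n_rbf, self.cfg.rbf_max)
        edge_res = self.sc_edge(concat([Tensor(bond_p[graph.edge_pair]),
                                        rbf_prev], axis=-1))
        return NetworkState(state.positions,
                            state.node_scalars + node_res,
                            state.node_vectors + vec_res,
                            state.edge_scalars + edge_res, graph)

    # -- full forward --------------------------------------------------------
    def predict_endpoint(self, states, prev=None, grad: bool = False):
        """Run the denoiser on a list of InterpolantStates (batched as one
        block-diagonal graph).  Returns one EndpointPrediction per molecule;
        with ``grad=True`` the outputs are autodiff Tensors."""
        single = isinstance(states, InterpolantState)
        if single:
            states = [states]
            prev = [prev] if prev is not None else None
        for p in self.parameters():
            p.requires_grad = grad
            p.grad = None
        graph = build_graph_batch(tuple(st.graph.n_atoms for st in states))
        state = self.embed_inputs(states, graph)
        state = self.self_conditioning_residual(states, prev, graph, state)
        for k, block in enumerate(self.blocks):
            state = block(state)
            if not np.all(np.isfinite(state.node_scalars.data)):
                raise FloatingPointError(f"non-finite activations in block {k}")
        type_logits = self.type_head(state.node_scalars)
        charge_logits = self.charge_head(state.node_scalars)
        edge_logits = self.bond_head(state.edge_scalars)
        # pair-symmetrize: average logits of (i,j) and (j,i)
        rev = edge_logits[graph.edge_rev]
        bond_logits = (edge_logits + rev) * 0.5
        bond_logits = bond_logits[graph.upper_edges]
        preds = []
        for m, (start, n) in enumerate(zip(graph.node_offset, graph.n_atoms)):
            sl = slice(int(start), int(start) + n)
            ps, pe = graph.pair_slices[m]
            pred = EndpointPrediction(
                coords_hat=_take(state.positions, sl, grad),
                type_logits=_take(type_logits, sl, grad),
                charge_logits=_take(charge_logits, sl, grad),
                bond_logits=_take(bond_logits, slice(ps, pe), grad),
            )
            preds.append(pred)
        return preds[0] if single else preds


def _take(x: Tensor, sl, grad: bool):
    piece = x[sl]
    return piece if grad else piece.data


def _softmax_np(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def _config_blob(model: Denoiser) -> str:
    return json.dumps({
        "config": dataclasses.asdict(model.cfg),
        "vocab": {"atom_elements": list(model.vocab.atom_elements),
                  "charges": list(model.vocab.charges),
                  "bond_orders": list(model.vocab.bond_orders)},
    }, sort_keys=True)


def save_checkpoint(model: Denoiser, path) -> None:
    blob = _config_blob(model)
    arrays = {name: p.data for name, p in model.named_parameters()}
    digest = hashlib.sha256(blob.encode()).hexdigest()
    np.savez(path, __meta__=np.frombuffer(blob.encode(), dtype=np.uint8),
             __hash__=np.frombuffer(digest.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> Denoiser:
    with np.load(path) as data:
        blob = bytes(data["__meta__"]).decode()
        digest = bytes(data["__hash__"]).decode()
        if hashlib.sha256(blob.encode()).hexdigest() != digest:
            raise ValueError("checkpoint config/vocabulary hash mismatch")
        meta = json.loads(blob)
        cfg = ModelConfig(**meta["config"])
        vocab = Vocabulary(atom_elements=tuple(meta["vocab"]["atom_elements"]),
                           charges=tuple(meta["vocab"]["charges"]),
                           bond_orders=tuple(meta["vocab"]["bond_orders"]))
        model = Denoiser(cfg, vocab)
        params = dict(model.named_parameters())
        for name in params:
            params[name].data = data[name].copy()
    return model
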