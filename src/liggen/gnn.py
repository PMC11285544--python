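"""Relational graph layers shared by the critic and the energy network.

Two backbones are provided over the same per-relation parameterisation:

* relational graph attention (RGAT): a single-head attention that forms one
  joint softmax per node over all (relation, neighbour) pairs, so the
  coefficients of every connected node sum to exactly one across relations;
* relational GCN: the no-attention baseline with per-relation mean
  aggregation plus a self-transform ``W_0 h_i``.

Edges enter as per-relation weight matrices.  For a discrete ligand graph
the weights are the 0/1 relational adjacencies; for a relaxed (dense)
ligand they are bond probabilities, which keeps every operation
differentiable all the way to the generator output — the critic needs this
for its gradient-penalty term.

The batched core runs on autodiff tensors; thin numpy wrappers expose the
single-graph operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .molgraph import LigandGraph, ModelDims, relational_adjacency

_BIG = 1e4
_TINY = 1e-12


# ---------------------------------------------------------------------------
# parameter containers (numpy-facing)
# ---------------------------------------------------------------------------

@dataclass
class RGATLayerParams:
    """Per-relation weights ``W[r]`` of shape (F_out, F_in) and attention
    vectors ``a[r]`` of length 2*F_out; LeakyReLU slope for both the
    attention logits and the output activation."""

    W: list[np.ndarray]
    a: list[np.ndarray]
    leaky_slope: float = 0.2

    def __post_init__(self):
        if len(self.W) != len(self.a):
            raise ValueError("one attention vector per relation required")
        fout = self.W[0].shape[0]
        for W, a in zip(self.W, self.a):
            if W.shape[0] != fout or a.shape[0] != 2 * fout:
                raise ValueError("inconsistent relation parameter shapes")

    @property
    def n_relations(self) -> int:
        return len(self.W)


@dataclass
class RGCNLayerParams:
    """Self-transform ``W0`` plus per-relation weights, all (F_out, F_in)."""

    W0: np.ndarray
    W: list[np.ndarray]
    leaky_slope: float = 0.2


def random_rgat_params(rng: np.random.Generator, n_relations: int,
                       f_in: int, f_out: int,
                       leaky_slope: float = 0.2) -> RGATLayerParams:
    s = np.sqrt(2.0 / (f_in + f_out))
    return RGATLayerParams(
        W=[rng.normal(0, s, (f_out, f_in)) for _ in range(n_relations)],
        a=[rng.normal(0, s, 2 * f_out) for _ in range(n_relations)],
        leaky_slope=leaky_slope,
    )


# ---------------------------------------------------------------------------
# batched tensor core
# ---------------------------------------------------------------------------

def _attention_terms(H: Tensor, Ws: list[Tensor], avs: list[Tensor],
                     weights: list[Tensor], slope: float):
    """Per-relation projected features, un-normalised attention mass.

    Returns ``(projected, numerators, denominator)`` where ``numerators[r]``
    is ``w_r * exp(e_r - m)`` for the joint softmax and ``denominator`` has
    shape (B, N, 1).  ``m`` is a constant rowwise max over edges for
    numerical stability.
    """
    projected, logits = [], []
    for W_r, a_r in zip(Ws, avs):
        P = ad.matmul(H, W_r)  # (B, N, Fo)
        fo = W_r.shape[1]
        a_src = ad.reshape(a_r[:fo], (fo, 1))
        a_dst = ad.reshape(a_r[fo:], (fo, 1))
        s_src = ad.matmul(P, a_src)  # (B, N, 1)
        s_dst = ad.matmul(P, a_dst)
        e = ad.leaky_relu(ad.add(s_src, ad.swapaxes(s_dst, -1, -2)), slope)
        projected.append(P)
        logits.append(e)

    # constant shift: max logit over edges present for each node
    stacked = np.stack([e.data for e in logits])  # (R, B, N, N)
    wmask = np.stack([w.data > _TINY for w in weights])
    masked = np.where(wmask, stacked, -np.inf)
    m = masked.max(axis=(0, 3), keepdims=False)  # (B, N)
    m = np.where(np.isfinite(m), m, 0.0)[:, :, None]

    numerators = [ad.mul(w, ad.exp(ad.sub(e, Tensor(m))))
                  for w, e in zip(weights, logits)]
    denom = ad.sum_(_sum_list(numerators), axis=2, keepdims=True)
    return projected, numerators, denom


def _sum_list(ts: list[Tensor]) -> Tensor:
    out = ts[0]
    for t in ts[1:]:
        out = ad.add(out, t)
    return out


def rgat_attention_t(H: Tensor, Ws: list[Tensor], avs: list[Tensor],
                     weights: list[Tensor], slope: float = 0.2) -> list[Tensor]:
    """Joint-softmax attention coefficients, one (B, N, N) tensor per
    relation; rows of isolated nodes are all zero."""
    _, numer, denom = _attention_terms(H, Ws, avs, weights, slope)
    safe = ad.add(denom, _TINY)
    return [ad.div(n, safe) for n in numer]


def rgat_layer_t(H: Tensor, Ws: list[Tensor], avs: list[Tensor],
                 weights: list[Tensor], slope: float = 0.2) -> Tensor:
    """One attention layer: h_i' = LeakyReLU(sum_r sum_j alpha_ij^r W_r h_j)."""
    projected, numer, denom = _attention_terms(H, Ws, avs, weights, slope)
    safe = ad.add(denom, _TINY)
    out = None
    for P, n in zip(projected, numer):
        msg = ad.matmul(ad.div(n, safe), P)  # (B, N, Fo)
        out = msg if out is None else ad.add(out, msg)
    return ad.leaky_relu(out, slope)


def rgcn_layer_t(H: Tensor, W0: Tensor, Ws: list[Tensor],
                 weights: list[Tensor], slope: float = 0.2) -> Tensor:
    """Relational GCN: h_i' = LeakyReLU(W0 h_i + sum_r mean_j W_r h_j)."""
    out = ad.matmul(H, W0)
    for W_r, w in zip(Ws, weights):
        deg = ad.add(ad.sum_(w, axis=2, keepdims=True), _TINY)
        msg = ad.matmul(ad.div(w, deg), ad.matmul(H, W_r))
        out = ad.add(out, msg)
    return ad.leaky_relu(out, slope)


def graph_readout_t(H: Tensor, mask: Tensor) -> Tensor:
    """Masked mean of node features concatenated with the masked
    feature-wise max; ``mask`` is (B, N) with 1 for real atoms.

    The max uses a detached additive shift so that pad rows never win the
    argmax; routing gradient through the shift itself would scale it by
    the shift constant, so the selection is treated as non-differentiable
    with respect to the mask (exact for hard masks).
    """
    m3 = ad.reshape(mask, (*mask.shape, 1))
    total = ad.sum_(ad.mul(H, m3), axis=1)
    count = ad.add(ad.sum_(m3, axis=1), _TINY)
    mean_part = ad.div(total, count)
    shift = Tensor((m3.data - 1.0) * _BIG)  # constant: pads pushed down
    max_part = ad.max_(ad.add(H, shift), axis=1)
    return ad.concat([mean_part, max_part], axis=-1)


# ---------------------------------------------------------------------------
# numpy wrappers (single graph)
# ---------------------------------------------------------------------------

def _check_inputs(H: np.ndarray, adj: np.ndarray) -> None:
    if not np.isfinite(H).all():
        raise ValueError("non-finite node features")
    if adj.ndim != 3:
        raise ValueError("adjacency must be (R, N, N)")


def _wrap(H: np.ndarray, adj: np.ndarray):
    Ht = Tensor(H[None, :, :])
    weights = [Tensor(adj[r][None, :, :]) for r in range(adj.shape[0])]
    return Ht, weights


def rgat_attention(H: np.ndarray, params: RGATLayerParams,
                   adj: np.ndarray) -> np.ndarray:
    """Attention coefficients (R, N, N) for one graph.

    For every node with at least one neighbour the coefficients sum to one
    over all (relation, neighbour) pairs; isolated nodes get all zeros.
    """
    H, adj = np.asarray(H, float), np.asarray(adj, float)
    _check_inputs(H, adj)
    Ht, weights = _wrap(H, adj)
    Ws = [Tensor(W.T) for W in params.W]
    avs = [Tensor(a) for a in params.a]
    alphas = rgat_attention_t(Ht, Ws, avs, weights, params.leaky_slope)
    return np.stack([a.data[0] for a in alphas])


def rgat_layer(H: np.ndarray, params: RGATLayerParams,
               adj: np.ndarray) -> np.ndarray:
    H, adj = np.asarray(H, float), np.asarray(adj, float)
    _check_inputs(H, adj)
    Ht, weights = _wrap(H, adj)
    Ws = [Tensor(W.T) for W in params.W]
    avs = [Tensor(a) for a in params.a]
    return rgat_layer_t(Ht, Ws, avs, weights, params.leaky_slope).data[0]


def rgcn_layer(H: np.ndarray, params: RGCNLayerParams,
               adj: np.ndarray) -> np.ndarray:
    H, adj = np.asarray(H, float), np.asarray(adj, float)
    _check_inputs(H, adj)
    Ht, weights = _wrap(H, adj)
    Ws = [Tensor(W.T) for W in params.W]
    return rgcn_layer_t(Ht, Tensor(params.W0.T), Ws, weights,
                        params.leaky_slope).data[0]


def graph_readout(H: np.ndarray, pad_mask: np.ndarray) -> np.ndarray:
    """Mean-and-max readout over non-pad rows; errors on an all-pad graph."""
    H = np.asarray(H, float)
    mask = np.asarray(pad_mask, float)
    if mask.sum() < 1:
        raise ValueError("readout of an all-pad graph")
    return graph_readout_t(Tensor(H[None]), Tensor(mask[None])).data[0]


# ---------------------------------------------------------------------------
# full stack
# ---------------------------------------------------------------------------

class GNNStack:
    """Embedding, stacked relational layers, readout, and an MLP head.

    Produces one scalar per graph (critic score or energy).  Message passing
    runs over the bond relations excluding no-bond, plus an optional
    self-loop relation so isolated atoms still receive their own message.
    """

    def __init__(self, dims: ModelDims, feat_dim: int | None = None,
                 n_layers: int = 3, backbone: str = "gat",
                 self_loops: bool = True, leaky_slope: float = 0.2,
                 head_hidden: tuple[int, ...] | None = (32,),
                 rng: np.random.Generator | None = None):
        if backbone not in ("gat", "gcn"):
            raise ValueError("backbone must be 'gat' or 'gcn'")
        if n_layers < 1:
            raise ValueError("at least one layer required")
        rng = rng or np.random.default_rng(0)
        self.dims = dims
        self.backbone = backbone
        self.self_loops = bool(self_loops)
        self.slope = float(leaky_slope)
        F = int(feat_dim or dims.feat_dim)
        self.feat_dim = F
        R = dims.n_relations + (1 if self.self_loops else 0)

        def glorot(fi, fo):
            return Tensor(rng.normal(0, np.sqrt(2.0 / (fi + fo)), (fi, fo)),
                          requires_grad=True)

        self.embed = glorot(dims.n_atom_types, F)
        self.layers: list[dict] = []
        for _ in range(n_layers):
            layer = {"W": [glorot(F, F) for _ in range(R)]}
            if backbone == "gat":
                layer["a"] = [Tensor(rng.normal(0, np.sqrt(1.0 / F), 2 * F),
                                     requires_grad=True) for _ in range(R)]
            else:
                layer["W0"] = glorot(F, F)
            self.layers.append(layer)

        self.head: list[tuple[Tensor, Tensor]] = []
        if head_hidden is not None:  # None: readout-only stack, no scalar head
            sizes = (2 * F, *head_hidden, 1)
            for fi, fo in zip(sizes[:-1], sizes[1:]):
                self.head.append((glorot(fi, fo),
                                  Tensor(np.zeros(fo), requires_grad=True)))

    # -- parameters ---------------------------------------------------
    def parameters(self) -> list[Tensor]:
        out = [self.embed]
        for layer in self.layers:
            out.extend(layer["W"])
            out.extend(layer.get("a", []))
            if "W0" in layer:
                out.append(layer["W0"])
        for W, b in self.head:
            out.extend([W, b])
        return out

    # -- forward ------------------------------------------------------
    def _edge_weights(self, atoms: Tensor, bonds: Tensor,
                      mask: Tensor) -> list[Tensor]:
        N = self.dims.n_atoms
        pair = ad.mul(ad.reshape(mask, (-1, N, 1)), ad.reshape(mask, (-1, 1, N)))
        weights = [ad.mul(bonds[:, :, :, r + 1], pair)
                   for r in range(self.dims.n_relations)]
        if self.self_loops:
            eye = Tensor(np.eye(N))
            weights.append(ad.mul(ad.reshape(mask, (-1, N, 1)), eye))
        return weights

    def node_features_t(self, atoms: Tensor, bonds: Tensor) -> tuple[Tensor, Tensor]:
        """Run embedding + relational layers; return (H, mask)."""
        mask = ad.sub(1.0, atoms[:, :, self.dims.pad_index])  # (B, N)
        weights = self._edge_weights(atoms, bonds, mask)
        H = ad.matmul(atoms, self.embed)
        for layer in self.layers:
            if self.backbone == "gat":
                H = rgat_layer_t(H, layer["W"], layer["a"], weights, self.slope)
            else:
                H = rgcn_layer_t(H, layer["W0"], layer["W"], weights, self.slope)
        return H, mask

    def readout_t(self, atoms: Tensor, bonds: Tensor) -> Tensor:
        H, mask = self.node_features_t(atoms, bonds)
        return graph_readout_t(H, mask)

    def head_t(self, g: Tensor) -> Tensor:
        if not self.head:
            raise ValueError("stack was built without a scalar head")
        h = g
        for i, (W, b) in enumerate(self.head):
            h = ad.add(ad.matmul(h, W), b)
            if i < len(self.head) - 1:
                h = ad.leaky_relu(h, self.slope)
        return ad.reshape(h, (h.shape[0],))

    def score_t(self, atoms: Tensor, bonds: Tensor) -> Tensor:
        """Scalar score per graph, (B,)."""
        return self.head_t(self.readout_t(atoms, bonds))

    def __call__(self, g: LigandGraph) -> float:
        atoms = Tensor(g.atoms[None])
        bonds = Tensor(g.bonds[None])
        return float(self.score_t(atoms, bonds).data[0])


def gnn_stack(g: LigandGraph, stack: GNNStack) -> float:
    """Scalar score of one ligand graph under a configured stack."""
    return stack(g)
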