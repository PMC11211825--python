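"""Graph and MLP encoder blocks.

Implements the three building blocks the affinity model is assembled
from, on top of the package's autodiff engine:

* **GCN layer** — symmetric-normalized convolution
  ``H' = sigma(D^{-1/2} (A + I) D^{-1/2} H W)``. The adjacency may carry
  real-valued edge weights (residue contact probabilities); weights enter
  the normalization through the weighted degree.
* **GAT layer** — masked multi-head attention. Per head,
  ``e_ij = LeakyReLU(a^T [W h_i || W h_j])`` (plus an optional additive
  edge-attribute logit), softmax-normalized over the neighborhood of i
  (self included), then ``h'_i = sigma(sum_j a_ij W h_j)``; heads are
  concatenated (or averaged on a final layer).
* **MLP** — alternating linear / ReLU / dropout stack; dropout is
  disabled in evaluation mode.

The functional forms (`gcn_layer`, `gat_attention`, `gat_layer`,
`max_pool_readout`, `mlp_encode`) are the tested mathematical surface;
the `Module` classes wrap them with parameter management for training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor, as_tensor, concatenate, dropout

__all__ = [
    "Module",
    "Linear",
    "GCNParams",
    "GATParams",
    "normalized_adjacency",
    "gcn_layer",
    "gat_attention",
    "gat_layer",
    "max_pool_readout",
    "mlp_encode",
    "MLP",
    "GCNLayer",
    "GATLayer",
    "project_edge_logits",
    "glorot",
]

LEAKY_SLOPE_DEFAULT = 0.2


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> Tensor:
    """Glorot/Xavier-uniform initialized parameter tensor."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    shape = shape if shape is not None else (fan_in, fan_out)
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Module:
    """Minimal parameter container with recursive collection and train/eval mode."""

    training: bool = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()

        def collect(obj) -> None:
            if isinstance(obj, Tensor):
                # leaves only: computed tensors (e.g. cached activations)
                # have parents and are not trainable parameters
                if obj.requires_grad and not obj._parents and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for value in vars(obj).values():
                    collect(value)
            elif isinstance(obj, (list, tuple)):
                for item in obj:
                    collect(item)
            elif hasattr(obj, "__dataclass_fields__"):
                for name in obj.__dataclass_fields__:
                    collect(getattr(obj, name))

        collect(self)
        return params

    def _set_mode(self, training: bool) -> None:
        self.training = training
        for value in vars(self).values():
            items = value if isinstance(value, (list, tuple)) else [value]
            for item in items:
                if isinstance(item, Module):
                    item._set_mode(training)

    def train(self) -> "Module":
        self._set_mode(True)
        return self

    def eval(self) -> "Module":
        self._set_mode(False)
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator, bias: bool = True):
        self.weight = glorot(rng, in_dim, out_dim)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = as_tensor(x) @ self.weight
        return out + self.bias if self.bias is not None else out


@dataclass
class GCNParams:
    """One graph-convolution layer's weight (activation fixed to ReLU)."""

    weight: Tensor  # F_in x F_out

    @classmethod
    def init(cls, rng: np.random.Generator, in_dim: int, out_dim: int) -> "GCNParams":
        return cls(weight=glorot(rng, in_dim, out_dim))


@dataclass
class GATParams:
    """Multi-head attention parameters; all heads share the output width."""

    W: list[Tensor]  # per head, F_in x F_out
    a: list[Tensor]  # per head, 2 * F_out
    leaky_slope: float = LEAKY_SLOPE_DEFAULT
    edge_proj: Tensor | None = None  # F_e -> scalar logit bias, shared by heads

    @property
    def heads(self) -> int:
        return len(self.W)

    @classmethod
    def init(
        cls,
        rng: np.random.Generator,
        in_dim: int,
        out_dim: int,
        heads: int = 1,
        edge_dim: int | None = None,
        leaky_slope: float = LEAKY_SLOPE_DEFAULT,
    ) -> "GATParams":
        W = [glorot(rng, in_dim, out_dim) for _ in range(heads)]
        a = [glorot(rng, 2 * out_dim, 1, shape=(2 * out_dim,)) for _ in range(heads)]
        edge_proj = glorot(rng, edge_dim, 1, shape=(edge_dim,)) if edge_dim else None
        return cls(W=W, a=a, leaky_slope=leaky_slope, edge_proj=edge_proj)


def normalized_adjacency(adj: np.ndarray) -> np.ndarray:
    """``D^{-1/2} (A + I) D^{-1/2}`` with weighted degrees; pure NumPy constant."""
    adj = np.asarray(adj, dtype=float)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError(f"adjacency must be square, got {adj.shape}")
    a_tilde = adj + np.eye(adj.shape[0])
    deg = a_tilde.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(deg)  # self-loops guarantee deg > 0
    return a_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def gcn_layer(adj: np.ndarray, H, params: GCNParams, activation: bool = True,
              pre_normalized: bool = False) -> Tensor:
    """Symmetric-normalized graph convolution with self-loops.

    With `pre_normalized` the caller supplies ``D^{-1/2}(A+I)D^{-1/2}``
    directly (useful when stacking layers over one fixed graph).
    """
    H = as_tensor(H)
    if H.shape[0] != adj.shape[0]:
        raise ValueError(f"feature rows {H.shape[0]} != adjacency size {adj.shape[0]}")
    norm = adj if pre_normalized else normalized_adjacency(adj)
    out = Tensor(norm) @ H @ params.weight
    return out.relu() if activation else out


def _attention_mask(adj: np.ndarray) -> np.ndarray:
    """Neighborhoods for attention: graph neighbors plus the node itself."""
    return (np.asarray(adj) > 0) | np.eye(adj.shape[0], dtype=bool)


def _head_attention(adj: np.ndarray, H: Tensor, params: GATParams, head: int, edge_bias,
                    mask: np.ndarray | None = None) -> tuple[Tensor, Tensor]:
    """(attention matrix, projected features WH) for one head."""
    if H.shape[0] != adj.shape[0]:
        raise ValueError(f"feature rows {H.shape[0]} != adjacency size {adj.shape[0]}")
    WH = H @ params.W[head]
    f_out = params.W[head].shape[1]
    a = params.a[head]
    src = WH @ a[:f_out]  # contribution of node i (row)
    dst = WH @ a[f_out:]  # contribution of neighbor j (column)
    n = adj.shape[0]
    logits = src.reshape(n, 1) + dst.reshape(1, n)
    if edge_bias is not None:
        logits = logits + as_tensor(edge_bias)
    logits = logits.leaky_relu(params.leaky_slope)
    if mask is None:
        mask = _attention_mask(adj)
    return logits.softmax_rows(mask=mask), WH


def gat_attention(adj: np.ndarray, H, params: GATParams, head: int = 0, edge_bias=None) -> Tensor:
    """Attention coefficient matrix for one head.

    Entry (i, j) is the weight node i places on neighbor j; each row is a
    softmax over the masked neighborhood (self included), so rows sum
    to 1. Off-neighborhood entries are exactly zero.
    """
    att, _ = _head_attention(adj, as_tensor(H), params, head, edge_bias)
    return att


def gat_layer(
    adj: np.ndarray,
    H,
    params: GATParams,
    edge_bias=None,
    concat_heads: bool = True,
) -> Tensor:
    """Multi-head masked attention layer.

    Per head the output is ``ReLU(sum_j a_ij W h_j)``; heads are either
    concatenated (hidden layers) or averaged before the activation
    (final-layer variant).
    """
    H = as_tensor(H)
    mask = _attention_mask(adj)
    head_outputs = []
    for k in range(params.heads):
        att, WH = _head_attention(adj, H, params, k, edge_bias, mask=mask)
        head_outputs.append(att @ WH)
    if concat_heads:
        return concatenate([h.relu() for h in head_outputs], axis=1)
    mean = head_outputs[0]
    for h in head_outputs[1:]:
        mean = mean + h
    return (mean / float(params.heads)).relu()


def max_pool_readout(H) -> Tensor:
    """Column-wise maximum over nodes: a node-count/order invariant readout."""
    H = as_tensor(H)
    if H.shape[0] < 1:
        raise ValueError("readout needs at least one node")
    return H.max(axis=0)


def project_edge_logits(edge_mat: np.ndarray, edge_proj: Tensor) -> Tensor:
    """Project a dense N x N x F_e edge-attribute array to an N x N logit bias."""
    n = edge_mat.shape[0]
    fe = edge_mat.shape[2]
    flat = Tensor(edge_mat.reshape(n * n, fe))
    return (flat @ edge_proj).reshape(n, n)


def mlp_encode(x, widths: list[tuple[Tensor, Tensor]], drop: float = 0.0,
               rng: np.random.Generator | None = None, training: bool = False) -> Tensor:
    """Alternating linear/ReLU/dropout stack over (weight, bias) pairs.

    The final layer is linear (no activation, no dropout).
    """
    h = as_tensor(x)
    last = len(widths) - 1
    for i, (w, b) in enumerate(widths):
        h = h @ w + b
        if i != last:
            h = h.relu()
            if drop > 0.0:
                h = dropout(h, drop, rng or np.random.default_rng(0), training)
    return h


class MLP(Module):
    """Linear/ReLU/dropout stack; the last layer stays linear."""

    def __init__(self, dims: list[int], rng: np.random.Generator, drop: float = 0.0):
        if len(dims) < 2:
            raise ValueError("MLP needs at least input and output widths")
        self.layers = [Linear(dims[i], dims[i + 1], rng) for i in range(len(dims) - 1)]
        self.drop = drop
        self._rng = rng

    def __call__(self, x: Tensor, return_penultimate: bool = False):
        h = as_tensor(x)
        penultimate = h
        for i, layer in enumerate(self.layers):
            h = layer(h)
            if i != len(self.layers) - 1:
                h = h.relu()
                h = dropout(h, self.drop, self._rng, self.training)
                penultimate = h
        if return_penultimate:
            return h, penultimate
        return h


class GCNLayer(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.params = GCNParams.init(rng, in_dim, out_dim)

    def __call__(self, adj: np.ndarray, H) -> Tensor:
        return gcn_layer(adj, H, self.params)


class GATLayer(Module):
    """Multi-head GAT layer; concatenates heads (or averages on request)."""

    def __init__(
        self,
        in_dim: int,
        out_dim: int,
        rng: np.random.Generator,
        heads: int = 1,
        edge_dim: int | None = None,
        concat_heads: bool = True,
    ):
        self.params = GATParams.init(rng, in_dim, out_dim, heads=heads, edge_dim=edge_dim)
        self.concat_heads = concat_heads

    def __call__(self, adj: np.ndarray, H, edge_mat: np.ndarray | None = None) -> Tensor:
        edge_bias = None
        if edge_mat is not None and self.params.edge_proj is not None:
            edge_bias = project_edge_logits(edge_mat, self.params.edge_proj)
        return gat_layer(adj, H, self.params, edge_bias=edge_bias, concat_heads=self.concat_heads)
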