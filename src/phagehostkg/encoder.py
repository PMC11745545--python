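"""Edge-type-aware multi-head GATv2 encoder and inner-product decoder.

Each layer k updates node i as

    f_i^{k+1} = ELU( (1/M) sum_m sum_w sum_{j in N_w^i} alpha_ij^m W_w^k f_j^k )

where w ranges over the edge types (pp, hh, ph), N_w^i is i's
w-neighborhood including i itself, M is the number of attention heads
(heads are averaged, not concatenated), and the attention weights follow
the GATv2 ordering — the nonlinearity sits inside the scoring map:

    e_ij = a_w^k · LeakyReLU( W_w^k [f_i^k || f_j^k] ),
    alpha_ij = softmax_j(e_ij)  over N_w^i.

Weights are shared per edge type, so phage nodes aggregate over their
{pp, ph} computation graphs and host nodes over {hh, ph}; summing the
per-type aggregates inside the layer realizes the decomposition of a node's
embedding into its per-relation hidden states. The transform applied to a
neighbor's message is the right block of W (the half acting on f_j).

Interaction likelihood is scored by the inner-product decoder
Q_ph = f_p^T f_h on the final-layer embeddings.

Everything is NumPy; the analytic backward pass used for training is
validated against numerical differentiation in the test suite.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np

EDGE_TYPES = ("pp", "hh", "ph")
LEAKY_SLOPE = 0.2


def leaky_relu(x: np.ndarray, slope: float = LEAKY_SLOPE) -> np.ndarray:
    return np.where(x > 0, x, slope * x)


def elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def _elu_grad(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, 1.0, np.exp(np.minimum(x, 0.0)))


# ---------------------------------------------------------------------------
# parameters

@dataclass
class ModelParams:
    """Per-layer, per-edge-type weights for M attention heads.

    ``layers[k][w]["W"]`` has shape (M, d_out, 2*d_in) — the left half acts
    on the center node, the right half on the neighbor; ``layers[k][w]["a"]``
    has shape (M, d_out) and maps the activated pair representation to the
    attention logit.
    """

    heads: int
    dims: Tuple[int, ...]
    layers: List[Dict[str, Dict[str, np.ndarray]]] = field(default_factory=list)
    # optional affine input normalization (x - loc) / scale applied before
    # the first layer; fitted on the full node set during training and
    # stored with the model so prediction preprocesses identically
    input_loc: np.ndarray | None = None
    input_scale: np.ndarray | None = None

    @classmethod
    def init(
        cls, dims: Sequence[int] = (256, 128, 64), heads: int = 4, seed: int = 0
    ) -> "ModelParams":
        """Glorot-style uniform initialization from an explicit seed."""
        if heads < 1:
            raise ValueError("heads must be >= 1")
        rng = np.random.default_rng(seed)
        layers = []
        for din, dout in zip(dims[:-1], dims[1:]):
            per_type = {}
            for et in EDGE_TYPES:
                w_lim = np.sqrt(6.0 / (2 * din + dout))
                a_lim = np.sqrt(6.0 / (dout + 1))
                per_type[et] = {
                    "W": rng.uniform(-w_lim, w_lim, (heads, dout, 2 * din)),
                    "a": rng.uniform(-a_lim, a_lim, (heads, dout)),
                }
            layers.append(per_type)
        return cls(heads=heads, dims=tuple(dims), layers=layers)

    def flat(self) -> List[np.ndarray]:
        out = []
        for layer in self.layers:
            for et in EDGE_TYPES:
                out.append(layer[et]["W"])
                out.append(layer[et]["a"])
        return out

    def zeros_like_flat(self) -> List[np.ndarray]:
        return [np.zeros_like(p) for p in self.flat()]

    def copy(self) -> "ModelParams":
        new_layers = [
            {et: {k: v.copy() for k, v in layer[et].items()} for et in EDGE_TYPES}
            for layer in self.layers
        ]
        return ModelParams(
            self.heads, self.dims, new_layers,
            None if self.input_loc is None else self.input_loc.copy(),
            None if self.input_scale is None else self.input_scale.copy(),
        )

    def fit_input_normalization(self, X: np.ndarray) -> None:
        """Fit the affine input normalization on the node feature matrix."""
        self.input_loc = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        self.input_scale = scale

    def normalize_input(self, X: np.ndarray) -> np.ndarray:
        if self.input_loc is None:
            return X
        return (X - self.input_loc) / self.input_scale


@dataclass
class EmbeddingTable:
    """Final-layer embedding vector per graph node."""

    node_ids: List[str]
    vectors: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("non-finite embedding values")

    def __getitem__(self, node: str) -> np.ndarray:
        return self.vectors[self.node_ids.index(node)]


# ---------------------------------------------------------------------------
# elementary operations

def attention_coefficients(
    f_i: np.ndarray, f_j: np.ndarray, W: np.ndarray, a: np.ndarray
) -> float:
    """GATv2 attention logit e_ij = a · LeakyReLU(W [f_i || f_j])."""
    if W.shape[1] != f_i.size + f_j.size:
        raise ValueError(
            f"W expects a {W.shape[1]}-dim pair, got {f_i.size}+{f_j.size}"
        )
    if a.size != W.shape[0]:
        raise ValueError("attention map dimension does not match W output")
    return float(a @ leaky_relu(W @ np.concatenate([f_i, f_j])))


def attention_weights(e_values: np.ndarray) -> np.ndarray:
    """Softmax over a neighborhood's logits, with max-subtraction."""
    e = np.asarray(e_values, dtype=float)
    shifted = e - e.max()
    w = np.exp(shifted)
    return w / w.sum()


def decoder_score(f_p: np.ndarray, f_h: np.ndarray) -> float:
    """Inner-product decoder Q_ph = f_p^T f_h."""
    if f_p.shape != f_h.shape:
        raise ValueError(f"embedding dims differ: {f_p.shape} vs {f_h.shape}")
    return float(np.dot(f_p, f_h))


# ---------------------------------------------------------------------------
# layer forward/backward

def _segments(sorted_idx: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    uniq, starts, counts = np.unique(sorted_idx, return_index=True, return_counts=True)
    seg_of = np.repeat(np.arange(len(uniq)), counts)
    return uniq, starts, seg_of


def _layer_forward(
    X: np.ndarray,
    edge_arrays: Dict[str, Tuple[np.ndarray, np.ndarray]],
    layer: Dict[str, Dict[str, np.ndarray]],
    heads: int,
    dropout: float = 0.0,
    rng: np.random.Generator | None = None,
):
    n, din = X.shape
    if dropout > 0.0 and rng is not None:
        in_mask = (rng.random(X.shape) >= dropout) / (1.0 - dropout)
    else:
        in_mask = None
    Xd = X if in_mask is None else X * in_mask
    dout = layer[EDGE_TYPES[0]]["W"].shape[1]
    Z = np.zeros((n, dout))
    caches = {}
    for et in EDGE_TYPES:
        I, J = edge_arrays[et]
        if I.size == 0:
            caches[et] = None
            continue
        W, a = layer[et]["W"], layer[et]["a"]
        Wl, Wr = W[:, :, :din], W[:, :, din:]
        Gl = np.einsum("mod,nd->mno", Wl, Xd, optimize=True)
        Gr = np.einsum("mod,nd->mno", Wr, Xd, optimize=True)
        S = Gl[:, I, :] + Gr[:, J, :]
        T = leaky_relu(S)
        E = np.einsum("meo,mo->me", T, a, optimize=True)
        uniq, starts, seg_of = _segments(I)
        Emax = np.maximum.reduceat(E, starts, axis=1)
        Eexp = np.exp(E - Emax[:, seg_of])
        denom = np.add.reduceat(Eexp, starts, axis=1)
        alpha = Eexp / denom[:, seg_of]
        if dropout > 0.0 and rng is not None:
            att_mask = (rng.random(alpha.shape) >= dropout) / (1.0 - dropout)
        else:
            att_mask = None
        alpha_d = alpha if att_mask is None else alpha * att_mask
        msg = alpha_d[:, :, None] * Gr[:, J, :]
        seg_sum = np.add.reduceat(msg, starts, axis=1)
        Z[uniq] += seg_sum.sum(axis=0)
        caches[et] = (I, J, uniq, starts, seg_of, Gl, Gr, S, alpha, att_mask)
    Z /= heads
    H = elu(Z)
    return H, (Xd, in_mask, Z, caches)


def _layer_backward(
    dH: np.ndarray,
    cache,
    layer: Dict[str, Dict[str, np.ndarray]],
    heads: int,
):
    Xd, in_mask, Z, caches = cache
    n, din = Xd.shape
    dZ = dH * _elu_grad(Z) / heads
    dX = np.zeros_like(Xd)
    grads: Dict[str, Dict[str, np.ndarray]] = {}
    for et in EDGE_TYPES:
        if caches[et] is None:
            grads[et] = {k: np.zeros_like(v) for k, v in layer[et].items()}
            continue
        I, J, uniq, starts, seg_of, Gl, Gr, S, alpha, att_mask = caches[et]
        W, a = layer[et]["W"], layer[et]["a"]
        Wl, Wr = W[:, :, :din], W[:, :, din:]
        alpha_d = alpha if att_mask is None else alpha * att_mask
        GrJ = Gr[:, J, :]
        dmsg = dZ[I]  # (E, dout); identical across heads
        dalpha_d = np.einsum("eo,meo->me", dmsg, GrJ, optimize=True)
        dalpha = dalpha_d if att_mask is None else dalpha_d * att_mask
        # softmax backward per segment
        tmp = alpha * dalpha
        seg_dot = np.add.reduceat(tmp, starts, axis=1)
        dE = tmp - alpha * seg_dot[:, seg_of]
        T = leaky_relu(S)
        da = np.einsum("meo,me->mo", T, dE, optimize=True)
        dS = dE[:, :, None] * a[:, None, :]
        dS *= np.where(S > 0, 1.0, LEAKY_SLOPE)
        # accumulate per-node gradients of Gl and Gr
        dGl = np.zeros_like(Gl)
        seg_dS = np.add.reduceat(dS, starts, axis=1)
        dGl[:, uniq] = seg_dS
        dGr = np.zeros_like(Gr)
        dGr_edges = dS + alpha_d[:, :, None] * dmsg[None, :, :]
        np.add.at(dGr, (slice(None), J), dGr_edges)
        dWl = np.einsum("mno,nd->mod", dGl, Xd, optimize=True)
        dWr = np.einsum("mno,nd->mod", dGr, Xd, optimize=True)
        dX += np.einsum("mod,mno->nd", Wl, dGl, optimize=True)
        dX += np.einsum("mod,mno->nd", Wr, dGr, optimize=True)
        grads[et] = {"W": np.concatenate([dWl, dWr], axis=2), "a": da}
    if in_mask is not None:
        dX *= in_mask
    return dX, grads


def layer_forward(graph, hidden: EmbeddingTable, layer_params, heads: int) -> EmbeddingTable:
    """One attention layer applied to an embedding table (reference surface)."""
    H, _ = _layer_forward(hidden.vectors, graph.edge_arrays(), layer_params, heads)
    return EmbeddingTable(hidden.node_ids, H)


def forward(
    graph,
    X: np.ndarray,
    params: ModelParams,
    dropout: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Tuple[np.ndarray, List]:
    """Full encoder forward pass; returns embeddings and per-layer caches.

    `dropout` (applied to layer inputs and attention coefficients, as is
    conventional for attention networks) is active only when an rng is
    passed, i.e. during training.
    """
    if X.shape[1] != params.dims[0]:
        raise ValueError(
            f"feature dim {X.shape[1]} does not match model input dim {params.dims[0]}"
        )
    edge_arrays = graph.edge_arrays()
    caches = []
    H = params.normalize_input(X)
    for layer in params.layers:
        H, cache = _layer_forward(H, edge_arrays, layer, params.heads, dropout, rng)
        caches.append(cache)
    return H, caches


def backward(
    dH: np.ndarray, caches: List, params: ModelParams
) -> Tuple[np.ndarray, List[np.ndarray]]:
    """Backpropagate dLoss/dH through the encoder; returns (dX, flat grads)."""
    grads_per_layer: List[Dict] = [None] * len(params.layers)
    for k in range(len(params.layers) - 1, -1, -1):
        dH, grads_per_layer[k] = _layer_backward(dH, caches[k], params.layers[k], params.heads)
    flat = []
    for grads in grads_per_layer:
        for et in EDGE_TYPES:
            flat.append(grads[et]["W"])
            flat.append(grads[et]["a"])
    return dH, flat


def encode(graph, features, params: ModelParams) -> EmbeddingTable:
    """Embed every node of the graph; feature rows follow graph node order."""
    feats = features.subset(graph.nodes)
    H, _ = forward(graph, feats.matrix, params)
    return EmbeddingTable(graph.nodes, H)


# ---------------------------------------------------------------------------
# checkpoints

def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def save_checkpoint(params: ModelParams, config: dict, path: str | Path) -> None:
    arrays = {}
    for k, layer in enumerate(params.layers):
        for et in EDGE_TYPES:
            arrays[f"W_{k}_{et}"] = layer[et]["W"]
            arrays[f"a_{k}_{et}"] = layer[et]["a"]
    if params.input_loc is not None:
        arrays["input_loc"] = params.input_loc
        arrays["input_scale"] = params.input_scale
    meta = {
        "heads": params.heads,
        "dims": list(params.dims),
        "edge_types": list(EDGE_TYPES),
        "config_hash": config_hash(config),
        "config": config,
    }
    np.savez_compressed(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path: str | Path, expect_config: dict | None = None) -> Tuple[ModelParams, dict]:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["meta"]))
    if expect_config is not None and config_hash(expect_config) != meta["config_hash"]:
        raise ValueError(
            "checkpoint was trained under a different configuration "
            f"(hash {meta['config_hash']}); refusing to load"
        )
    dims = tuple(meta["dims"])
    layers = []
    for k in range(len(dims) - 1):
        layers.append(
            {et: {"W": data[f"W_{k}_{et}"], "a": data[f"a_{k}_{et}"]} for et in EDGE_TYPES}
        )
    params = ModelParams(heads=meta["heads"], dims=dims, layers=layers)
    if "input_loc" in data:
        params.input_loc = data["input_loc"]
        params.input_scale = data["input_scale"]
    return params, meta["config"]
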