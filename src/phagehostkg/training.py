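"""End-to-end training of the encoder–decoder under the BPR ranking loss.

For every observed (phage, host) training pair a prokaryote with no
phage–host edge to that phage is sampled uniformly as a negative, and the
loss

    L = - sum ln sigmoid(Q_ph - Q_ps)

pushes observed interaction scores above sampled non-interaction scores
(computed through the numerically stable softplus form). Training is
full-batch: one forward pass over the whole graph per epoch, negatives
resampled each epoch, parameters updated with Adam. A 10% slice of the
training positives is held out as a validation set for early stopping on
hit@1; validation pairs stay in the graph as edges (the construction is
transductive — only test-split interactions are withheld upstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np

from . import encoder as enc
from .encoder import ModelParams
from .graph import PHKG
from .kmer import FeatureMatrix


@dataclass
class TrainingConfig:
    learning_rate: float = 1e-3
    epochs: int = 500
    negatives_per_positive: int = 1
    seed: int = 0
    heads: int = 4
    dims: Tuple[int, ...] = (256, 64, 32)
    early_stop_patience: int = 50
    validation_fraction: float = 0.1
    dropout: float = 0.3
    standardize_features: bool = True

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.negatives_per_positive < 1:
            raise ValueError("negatives_per_positive must be >= 1")

    def to_dict(self) -> dict:
        return {
            "learning_rate": self.learning_rate,
            "epochs": self.epochs,
            "negatives_per_positive": self.negatives_per_positive,
            "seed": self.seed,
            "heads": self.heads,
            "dims": list(self.dims),
            "early_stop_patience": self.early_stop_patience,
            "validation_fraction": self.validation_fraction,
            "dropout": self.dropout,
            "standardize_features": self.standardize_features,
        }


@dataclass
class TrainState:
    params: ModelParams
    epoch: int
    loss_history: List[float] = field(default_factory=list)
    validation_history: List[float] = field(default_factory=list)


MIN_VALIDATION_PAIRS = 5


def sample_negative(phage: str, graph: PHKG, rng: np.random.Generator) -> str:
    """A host with no ph edge to `phage`, drawn uniformly."""
    linked = graph.neighbors(phage, "ph")
    eligible = [h for h in graph.hosts if h not in linked]
    if not eligible:
        raise ValueError(
            f"phage {phage} is ph-adjacent to every host; no negative exists"
        )
    return eligible[int(rng.integers(len(eligible)))]


def bpr_loss(pos_scores: Sequence[float], neg_scores: Sequence[float]) -> float:
    """-sum ln sigmoid(pos - neg) over paired scores, via softplus."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.shape != neg.shape:
        raise ValueError(f"score lists differ in length: {pos.shape} vs {neg.shape}")
    margin = pos - neg
    # softplus(-x) = log(1 + exp(-x)), stable on both tails
    return float(np.sum(np.logaddexp(0.0, -margin)))


def _bpr_loss_and_margin_grad(margin: np.ndarray) -> Tuple[float, np.ndarray]:
    loss = float(np.sum(np.logaddexp(0.0, -margin)))
    # d/dmargin softplus(-margin) = -sigmoid(-margin)
    grad = -1.0 / (1.0 + np.exp(margin))
    return loss, grad


class _Adam:
    def __init__(self, shapes: List[np.ndarray], lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in shapes]
        self.v = [np.zeros_like(p) for p in shapes]
        self.t = 0

    def step(self, params: List[np.ndarray], grads: List[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _epoch_loss_grad(
    graph: PHKG,
    X: np.ndarray,
    params: ModelParams,
    pos_pairs: List[Tuple[int, int]],
    neg_pairs: List[Tuple[int, int]],
    dropout: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Tuple[float, List[np.ndarray]]:
    H, caches = enc.forward(graph, X, params, dropout=dropout, rng=rng)
    pi = np.array([p for p, _ in pos_pairs])
    hi = np.array([h for _, h in pos_pairs])
    si = np.array([s for _, s in neg_pairs])
    q_pos = np.einsum("ed,ed->e", H[pi], H[hi])
    q_neg = np.einsum("ed,ed->e", H[pi], H[si])
    loss, dmargin = _bpr_loss_and_margin_grad(q_pos - q_neg)
    dH = np.zeros_like(H)
    np.add.at(dH, pi, dmargin[:, None] * (H[hi] - H[si]))
    np.add.at(dH, hi, dmargin[:, None] * H[pi])
    np.add.at(dH, si, -dmargin[:, None] * H[pi])
    _, grads = enc.backward(dH, caches, params)
    return loss, grads


def train(
    graph: PHKG,
    features: FeatureMatrix,
    train_interactions: Set[Tuple[str, str]],
    config: TrainingConfig,
) -> TrainState:
    """Full-batch BPR training with Adam, early stopping on validation hit@1.

    Fully reproducible for a given config seed: negative draws, the
    validation split and parameter initialization all derive from it. The
    parameters with the best validation hit@1 are restored at the end.
    """
    rng = np.random.default_rng(config.seed)
    feats = features.subset(graph.nodes)
    X = feats.matrix
    if X.shape[1] != config.dims[0]:
        raise ValueError(
            f"feature dim {X.shape[1]} does not match configured input dim {config.dims[0]}"
        )
    params = ModelParams.init(config.dims, config.heads, seed=int(rng.integers(2**31)))
    if config.standardize_features:
        params.fit_input_normalization(X)
    ix = graph.node_index()
    positives = sorted(train_interactions)
    for p, h in positives:
        if p not in ix or h not in ix:
            raise ValueError(f"training pair ({p}, {h}) not in graph")

    # early stopping needs a validation signal that is not pure noise; on
    # very small communities the 10% slice is a couple of pairs, so below
    # MIN_VALIDATION_PAIRS all positives are fitted for the full epoch budget
    n_val = int(round(config.validation_fraction * len(positives)))
    val_mask = np.zeros(len(positives), dtype=bool)
    if n_val >= MIN_VALIDATION_PAIRS and len(positives) > n_val:
        val_mask[rng.choice(len(positives), size=n_val, replace=False)] = True
    val_pairs = [pr for pr, m in zip(positives, val_mask) if m]
    fit_pairs = [pr for pr, m in zip(positives, val_mask) if not m]
    if not fit_pairs:
        fit_pairs = positives
        val_pairs = []

    host_ix = np.array([ix[h] for h in graph.hosts])
    flat_params = params.flat()
    adam = _Adam(flat_params, config.learning_rate)
    state = TrainState(params=params, epoch=0)
    best_val, best_params, patience_left = -1.0, params.copy(), config.early_stop_patience

    pos_idx = [(ix[p], ix[h]) for p, h in fit_pairs]
    val_truth: Dict[str, Set[str]] = {}
    for p, h in val_pairs:
        val_truth.setdefault(p, set()).add(h)

    for epoch in range(1, config.epochs + 1):
        neg_idx = []
        for (p, h) in fit_pairs:
            for _ in range(config.negatives_per_positive):
                s = sample_negative(p, graph, rng)
                neg_idx.append((ix[p], ix[s]))
        reps = np.repeat(np.arange(len(pos_idx)), config.negatives_per_positive)
        pos_rep = [pos_idx[i] for i in reps]
        loss, grads = _epoch_loss_grad(
            graph, X, params, pos_rep, neg_idx, dropout=config.dropout, rng=rng
        )
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite BPR loss at epoch {epoch}; last finite losses: "
                f"{state.loss_history[-5:]}"
            )
        adam.step(flat_params, grads)
        state.loss_history.append(loss)
        state.epoch = epoch

        val_hit = _validation_hit1(graph, X, params, val_truth, host_ix, ix)
        state.validation_history.append(val_hit)
        if val_truth:
            if val_hit > best_val + 1e-12:
                best_val = val_hit
                best_params = params.copy()
                patience_left = config.early_stop_patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    break

    if val_truth and best_val >= 0:
        state.params = best_params
    else:
        state.params = params
    return state


def train_ensemble(
    graph: PHKG,
    features: FeatureMatrix,
    train_interactions: Set[Tuple[str, str]],
    config: TrainingConfig,
    n_models: int = 3,
) -> List[TrainState]:
    """Train `n_models` independent restarts (distinct init and negative
    draws, all derived from the config seed).

    Averaging the per-phage standardized decoder scores of a few restarts
    damps initialization variance the same way head averaging does inside
    one model; prediction-side helpers in the evaluation module consume the
    list directly.
    """
    seed_rng = np.random.default_rng(config.seed)
    states = []
    for _ in range(n_models):
        sub = TrainingConfig(**{**config.to_dict(), "seed": int(seed_rng.integers(2**31))})
        sub.dims = tuple(sub.dims)
        states.append(train(graph, features, train_interactions, sub))
    return states


def _validation_hit1(
    graph: PHKG,
    X: np.ndarray,
    params: ModelParams,
    val_truth: Dict[str, Set[str]],
    host_ix: np.ndarray,
    ix: Dict[str, int],
) -> float:
    if not val_truth:
        return float("nan")
    H, _ = enc.forward(graph, X, params)
    hits = 0
    for p, hosts in val_truth.items():
        scores = H[ix[p]] @ H[host_ix].T
        top = graph.hosts[int(np.argmax(scores))]
        hits += top in hosts
    return hits / len(val_truth)
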