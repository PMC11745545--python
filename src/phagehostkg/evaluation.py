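"""Host ranking and evaluation: hit@k, taxonomic-level accuracy, data split.

For each test phage every host node is scored with the inner-product
decoder and ranked (ties broken by ascending accession for
reproducibility). hit@k is the fraction of phages whose set of true hosts
intersects the top-k predictions; because the ranking covers all candidate
hosts and one prediction is made per phage, recall and precision coincide
with accuracy in this setting. Taxonomic accuracy asks whether the top-1
host matches ANY true host at a given rank of the six-rank lineage
(phylum .. species); an "unknown" rank never matches.

The train/test split operates on phages (a phage carries all its
interactions to one side), stratified by the species label of its host:
species classes with at least three phages are split proportionally, while
classes of one or two phages are assigned wholly to one side by a simple
random draw.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import encoder as enc
from .encoder import EmbeddingTable, ModelParams
from .graph import PHKG
from .kmer import FeatureMatrix

RANKS = ("phylum", "class", "order", "family", "genus", "species")
UNKNOWN = "unknown"

Lineage = Tuple[str, ...]
TaxonomyMap = Dict[str, Lineage]


@dataclass
class PredictionRanking:
    """All hosts ordered by decoder score for one phage."""

    phage: str
    ranked_hosts: List[Tuple[str, float]]

    def top(self, k: int) -> List[str]:
        return [h for h, _ in self.ranked_hosts[:k]]


def _rank_from_scores(phage: str, hosts: Sequence[str], scores: np.ndarray) -> PredictionRanking:
    order = sorted(range(len(hosts)), key=lambda i: (-scores[i], hosts[i]))
    return PredictionRanking(phage, [(hosts[i], float(scores[i])) for i in order])


def rank_hosts(
    model: ModelParams, graph: PHKG, features: FeatureMatrix, phage: str
) -> PredictionRanking:
    """Score `phage` against every host node and rank (descending score,
    ties by ascending accession)."""
    if phage not in set(graph.phages):
        raise KeyError(f"unknown phage {phage!r}")
    table = enc.encode(graph, features, model)
    return _rank_from_scores(phage, graph.hosts, _host_scores(table, graph, phage))


def rank_all_hosts(
    model: ModelParams, graph: PHKG, features: FeatureMatrix, phages: Sequence[str]
) -> Dict[str, PredictionRanking]:
    """Rankings for many phages from a single encoder pass."""
    table = enc.encode(graph, features, model)
    return {
        p: _rank_from_scores(p, graph.hosts, _host_scores(table, graph, p))
        for p in phages
    }


def ensemble_rank_all_hosts(
    models: Sequence[ModelParams],
    graph: PHKG,
    features: FeatureMatrix,
    phages: Sequence[str],
) -> Dict[str, PredictionRanking]:
    """Rankings from averaged per-phage standardized scores of several
    independently trained models (restart-ensemble prediction)."""
    if not models:
        raise ValueError("no models given")
    acc: Dict[str, np.ndarray] = {p: np.zeros(len(graph.hosts)) for p in phages}
    for model in models:
        table = enc.encode(graph, features, model)
        for p in phages:
            s = _host_scores(table, graph, p)
            sd = s.std()
            acc[p] += (s - s.mean()) / (sd if sd > 0 else 1.0)
    return {
        p: _rank_from_scores(p, graph.hosts, acc[p] / len(models)) for p in phages
    }


def _host_scores(table: EmbeddingTable, graph: PHKG, phage: str) -> np.ndarray:
    ix = {n: i for i, n in enumerate(table.node_ids)}
    f_p = table.vectors[ix[phage]]
    host_vecs = table.vectors[[ix[h] for h in graph.hosts]]
    return host_vecs @ f_p


def hit_at_k(
    rankings: Dict[str, PredictionRanking], truth: Dict[str, Set[str]], k: int
) -> float:
    """Fraction of phages whose true-host set meets the top-k predictions."""
    if not rankings:
        raise ValueError("no rankings given")
    hits = 0
    for phage, ranking in rankings.items():
        if phage not in truth or not truth[phage]:
            raise KeyError(f"phage {phage!r} has no truth entry")
        hits += bool(set(ranking.top(k)) & truth[phage])
    return hits / len(rankings)


def taxonomic_accuracy(
    rankings: Dict[str, PredictionRanking],
    truth: Dict[str, Set[str]],
    taxonomy: TaxonomyMap,
    level: str,
) -> float:
    """Top-1 accuracy at a taxonomic rank.

    The top-ranked host counts as correct when its taxon at `level` equals
    the taxon of any true host at that level; the "unknown" sentinel never
    matches.
    """
    if level not in RANKS:
        raise ValueError(f"level must be one of {RANKS}, got {level!r}")
    li = RANKS.index(level)
    correct = 0
    for phage, ranking in rankings.items():
        top1 = ranking.top(1)[0]
        for host in truth[phage] | {top1}:
            if host not in taxonomy:
                raise KeyError(f"host {host!r} missing from taxonomy")
        pred_taxon = taxonomy[top1][li]
        if pred_taxon == UNKNOWN:
            continue
        if any(taxonomy[h][li] == pred_taxon for h in truth[phage]):
            correct += 1
    return correct / len(rankings)


def stratified_split(
    interactions: Set[Tuple[str, str]],
    taxonomy: TaxonomyMap,
    frac: float = 0.7,
    seed: int = 0,
) -> Tuple[Set[Tuple[str, str]], Set[Tuple[str, str]]]:
    """Phage-level 70/30 split stratified by host species label.

    Every phage lands on exactly one side with all of its interactions.
    Classes (species labels) with >= 3 phages are split ~frac per class;
    classes with 1–2 phages go wholly to one side by a random draw.
    """
    if not interactions:
        raise ValueError("empty interaction set")
    if not 0.0 < frac < 1.0:
        raise ValueError(f"frac must be in (0, 1), got {frac}")
    rng = np.random.default_rng(seed)
    hosts_of: Dict[str, List[str]] = {}
    for p, h in sorted(interactions):
        hosts_of.setdefault(p, []).append(h)
    label_of = {}
    for p, hosts in hosts_of.items():
        species = sorted(taxonomy[h][RANKS.index("species")] for h in hosts)
        label_of[p] = species[0]
    classes: Dict[str, List[str]] = {}
    for p in sorted(label_of):
        classes.setdefault(label_of[p], []).append(p)
    train_phages: Set[str] = set()
    test_phages: Set[str] = set()
    for label in sorted(classes):
        members = classes[label]
        if len(members) >= 3:
            perm = rng.permutation(len(members))
            n_train = int(round(frac * len(members)))
            n_train = min(max(n_train, 1), len(members) - 1)
            for rank, mi in enumerate(perm):
                (train_phages if rank < n_train else test_phages).add(members[mi])
        else:
            side = train_phages if rng.random() < frac else test_phages
            side.update(members)
    train = {(p, h) for p, h in interactions if p in train_phages}
    test = {(p, h) for p, h in interactions if p in test_phages}
    return train, test


def predictions_to_tsv(
    rankings: Dict[str, PredictionRanking], path: str | Path
) -> None:
    rows = []
    for phage in sorted(rankings):
        for rank, (host, score) in enumerate(rankings[phage].ranked_hosts, start=1):
            rows.append((phage, rank, host, score))
    pd.DataFrame(rows, columns=["phage", "rank", "host", "score"]).to_csv(
        path, sep="\t", index=False, float_format="%.8g"
    )


def metrics_report(
    rankings: Dict[str, PredictionRanking],
    truth: Dict[str, Set[str]],
    taxonomy: TaxonomyMap,
    max_k: int = 25,
) -> Dict:
    n_hosts = len(rankings[next(iter(rankings))].ranked_hosts) if rankings else 0
    ks = range(1, min(max_k, n_hosts) + 1)
    return {
        "n_phages": len(rankings),
        "hit_at_k": {str(k): hit_at_k(rankings, truth, k) for k in ks},
        "accuracy_by_level": {
            level: taxonomic_accuracy(rankings, truth, taxonomy, level) for level in RANKS
        },
    }
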