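"""Assembly of the phage–host knowledge graph (PHKG) from evidence.

Nodes are typed accessions (phage or host); undirected edges come in three
types — phage–phage (pp), host–host (hh) and phage–host (ph) — and are
stored canonically ordered without self-loops (the encoder injects the
self-contribution). Edge rules are OR-combinations of the evidence
channels with strict-inequality thresholds:

* pp: shared-cluster tail probability < tau1, or nucleotide e-value < tau2;
* hh: a 16S rRNA link exists, or nucleotide e-value < tau2;
* ph: a CRISPR or RBP link exists, or nucleotide e-value < tau2, or the
  pair is a known interaction from the *training* split.

Test-split interactions must never reach the ph rule; passing one in
raises a leakage error. Test phages still enter the graph as nodes with
features and sequence-derived edges (the setting is transductive), only
their interaction labels are withheld.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .clustering import SharedClusterStat
from .evidence import EvidenceRecord
from .kmer import FeatureMatrix

EDGE_TYPES = ("pp", "hh", "ph")


class LeakageError(RuntimeError):
    """A test-split interaction was offered to the graph builder."""


@dataclass(frozen=True)
class Thresholds:
    """Edge-existence thresholds: tau1 for the shared-cluster tail
    probability, tau2 for the nucleotide-similarity e-value."""

    tau1: float = 1e-5
    tau2: float = 1e-10

    def __post_init__(self) -> None:
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ValueError("thresholds must be positive")


Edge = Tuple[str, str]


def _canon(a: str, b: str) -> Edge:
    return (a, b) if a <= b else (b, a)


def _check_known(records: Iterable, known: Set[str], what: str) -> None:
    for rec in records:
        pair = rec.pair() if isinstance(rec, EvidenceRecord) else (rec.phage_a, rec.phage_b)
        for ent in pair:
            if ent not in known:
                raise ValueError(f"unknown accession {ent!r} in {what}")


def build_pp_edges(
    stats: Sequence[SharedClusterStat],
    blastn_records: Sequence[EvidenceRecord],
    thresholds: Thresholds,
    phages: Set[str],
) -> Set[Edge]:
    """Phage–phage edges: q < tau1 OR e-value < tau2 (single edge either way)."""
    _check_known(stats, phages, "shared-cluster stats")
    _check_known(blastn_records, phages, "phage blastn records")
    edges: Set[Edge] = set()
    for st in stats:
        if st.q < thresholds.tau1:
            edges.add(_canon(st.phage_a, st.phage_b))
    for rec in blastn_records:
        if rec.channel == "blastn" and rec.value < thresholds.tau2:
            edges.add(_canon(rec.entity_a, rec.entity_b))
    return {e for e in edges if e[0] != e[1]}


def build_hh_edges(
    rrna_records: Sequence[EvidenceRecord],
    blastn_records: Sequence[EvidenceRecord],
    thresholds: Thresholds,
    hosts: Set[str],
) -> Set[Edge]:
    """Host–host edges: a 16S link exists OR e-value < tau2."""
    _check_known(rrna_records, hosts, "16S records")
    _check_known(blastn_records, hosts, "host blastn records")
    edges: Set[Edge] = set()
    for rec in rrna_records:
        if rec.channel == "rrna16s":
            edges.add(_canon(rec.entity_a, rec.entity_b))
    for rec in blastn_records:
        if rec.channel == "blastn" and rec.value < thresholds.tau2:
            edges.add(_canon(rec.entity_a, rec.entity_b))
    return {e for e in edges if e[0] != e[1]}


def build_ph_edges(
    crispr_records: Sequence[EvidenceRecord],
    rbp_records: Sequence[EvidenceRecord],
    blastn_records: Sequence[EvidenceRecord],
    train_interactions: Set[Tuple[str, str]],
    thresholds: Thresholds,
    phages: Set[str],
    hosts: Set[str],
    test_interactions: Set[Tuple[str, str]] | None = None,
) -> Set[Edge]:
    """Phage–host edges: CRISPR OR RBP OR e-value < tau2 OR known training pair.

    `test_interactions`, when given, arms the leakage guard: any offered
    training pair that belongs to the test split raises LeakageError.
    """
    entities = phages | hosts
    for grp, what in ((crispr_records, "crispr"), (rbp_records, "rbp"), (blastn_records, "blastn")):
        _check_known(grp, entities, f"{what} records")
    if test_interactions:
        leaked = set(train_interactions) & set(test_interactions)
        if leaked:
            raise LeakageError(
                f"test-split interactions offered as training edges: {sorted(leaked)[:5]}"
            )
    for phage, host in train_interactions:
        if phage not in phages or host not in hosts:
            raise ValueError(f"unknown accession in interaction ({phage}, {host})")
    edges: Set[Edge] = set()
    for rec in list(crispr_records) + list(rbp_records):
        if rec.channel in ("crispr", "rbp"):
            edges.add(_canon(rec.entity_a, rec.entity_b))
    for rec in blastn_records:
        if rec.channel == "blastn" and rec.value < thresholds.tau2:
            edges.add(_canon(rec.entity_a, rec.entity_b))
    for phage, host in train_interactions:
        edges.add(_canon(phage, host))
    return edges


@dataclass
class PHKG:
    """The heterogeneous phage–host knowledge graph."""

    phages: List[str]
    hosts: List[str]
    edges: Dict[str, Set[Edge]]
    features: FeatureMatrix
    thresholds: Thresholds = field(default_factory=Thresholds)

    @property
    def nodes(self) -> List[str]:
        return self.phages + self.hosts

    def node_class(self, node: str) -> str:
        if node in set(self.phages):
            return "p"
        if node in set(self.hosts):
            return "h"
        raise KeyError(node)

    def neighbors(self, node: str, edge_type: str) -> Set[str]:
        out = set()
        for a, b in self.edges[edge_type]:
            if a == node:
                out.add(b)
            elif b == node:
                out.add(a)
        return out

    def isolated_nodes(self) -> List[str]:
        touched = {n for es in self.edges.values() for e in es for n in e}
        return [n for n in self.nodes if n not in touched]

    # ---- encoder-facing view ------------------------------------------
    def node_index(self) -> Dict[str, int]:
        return {n: i for i, n in enumerate(self.nodes)}

    def edge_arrays(self) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
        """Directed (center, neighbor) index arrays per edge type, with
        self-loops injected for every node of the type's participating
        classes (pp: phages, hh: hosts, ph: all nodes)."""
        ix = self.node_index()
        n_phage = len(self.phages)
        n = len(self.nodes)
        arrays = {}
        selfs = {
            "pp": list(range(n_phage)),
            "hh": list(range(n_phage, n)),
            "ph": list(range(n)),
        }
        for et in EDGE_TYPES:
            src, dst = [], []
            for a, b in sorted(self.edges[et]):
                ia, ib = ix[a], ix[b]
                src += [ia, ib]
                dst += [ib, ia]
            for i in selfs[et]:
                src.append(i)
                dst.append(i)
            order = np.argsort(np.array(src), kind="stable")
            arrays[et] = (np.array(src)[order], np.array(dst)[order])
        return arrays

    # ---- persistence ---------------------------------------------------
    def to_dir(self, out_dir: str | Path) -> None:
        from . import io as _io

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = [
            (a, b, et) for et in EDGE_TYPES for a, b in sorted(self.edges[et])
        ]
        pd.DataFrame(rows, columns=_io.EDGE_COLUMNS).to_csv(
            out / "edges.tsv", sep="\t", index=False
        )
        self.features.to_tsv(out / "features.tsv")
        _io.write_json(
            {
                "phages": self.phages,
                "hosts": self.hosts,
                "thresholds": {"tau1": self.thresholds.tau1, "tau2": self.thresholds.tau2},
            },
            out / "graph.json",
        )

    @classmethod
    def from_dir(cls, in_dir: str | Path) -> "PHKG":
        from . import io as _io

        path = Path(in_dir)
        meta = _io.read_json(path / "graph.json")
        df = pd.read_csv(path / "edges.tsv", sep="\t", dtype=str)
        edges: Dict[str, Set[Edge]] = {et: set() for et in EDGE_TYPES}
        for row in df.itertuples():
            edges[row.edge_type].add(_canon(row.node_a, row.node_b))
        features = FeatureMatrix.from_tsv(path / "features.tsv")
        return cls(
            phages=list(meta["phages"]),
            hosts=list(meta["hosts"]),
            edges=edges,
            features=features,
            thresholds=Thresholds(**meta["thresholds"]),
        )


def assemble_graph(
    phages: Sequence[str],
    hosts: Sequence[str],
    pp: Set[Edge],
    hh: Set[Edge],
    ph: Set[Edge],
    features: FeatureMatrix,
    thresholds: Thresholds = Thresholds(),
) -> Tuple[PHKG, Dict]:
    """Validate and assemble the PHKG; returns the graph and a build report."""
    phages = sorted(phages)
    hosts = sorted(hosts)
    overlap = set(phages) & set(hosts)
    if overlap:
        raise ValueError(f"accessions in both classes: {sorted(overlap)[:5]}")
    nodes = phages + hosts
    missing = [n for n in nodes if n not in set(features.node_ids)]
    if missing:
        raise ValueError(f"nodes missing a feature row: {missing}")
    features = features.subset(nodes)
    pset, hset = set(phages), set(hosts)
    for et, edge_set, legal in (
        ("pp", pp, lambda a, b: a in pset and b in pset),
        ("hh", hh, lambda a, b: a in hset and b in hset),
        ("ph", ph, lambda a, b: (a in pset) != (b in pset)),
    ):
        for a, b in edge_set:
            if a == b:
                raise ValueError(f"self-edge {a} in {et}")
            if not legal(a, b):
                raise ValueError(f"edge ({a}, {b}) has wrong endpoint classes for {et}")
    edges = {
        "pp": {_canon(*e) for e in pp},
        "hh": {_canon(*e) for e in hh},
        "ph": {_canon(*e) for e in ph},
    }
    graph = PHKG(phages=phages, hosts=hosts, edges=edges, features=features,
                 thresholds=thresholds)
    report = {
        "n_phages": len(phages),
        "n_hosts": len(hosts),
        "edge_counts": {et: len(edges[et]) for et in EDGE_TYPES},
        "isolated_nodes": graph.isolated_nodes(),
    }
    return graph, report
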