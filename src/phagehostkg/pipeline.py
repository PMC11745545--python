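"""Stage orchestration shared by the CLI and the test harness."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Set, Tuple

import pandas as pd

from . import clustering, evidence, graph as graph_mod, kmer
from .clustering import SharedClusterStat
from .evidence import EvidenceRecord
from .graph import PHKG, Thresholds


@dataclass
class EvidenceBundle:
    """All evidence produced for one community, grouped by channel."""

    pp_blastn: List[EvidenceRecord] = field(default_factory=list)
    hh_blastn: List[EvidenceRecord] = field(default_factory=list)
    ph_blastn: List[EvidenceRecord] = field(default_factory=list)
    crispr: List[EvidenceRecord] = field(default_factory=list)
    rbp: List[EvidenceRecord] = field(default_factory=list)
    rrna16s: List[EvidenceRecord] = field(default_factory=list)
    cluster_stats: List[SharedClusterStat] = field(default_factory=list)

    def records(self) -> List[EvidenceRecord]:
        """Flat record list; shared-cluster stats appear as protein_cluster
        records (value = tail probability) for pairs sharing >=1 cluster."""
        out = (
            list(self.pp_blastn) + list(self.hh_blastn) + list(self.ph_blastn)
            + list(self.crispr) + list(self.rbp) + list(self.rrna16s)
        )
        for st in self.cluster_stats:
            if st.c >= 1:
                out.append(
                    EvidenceRecord(st.phage_a, st.phage_b, "protein_cluster", min(st.q, 1.0))
                )
        return out

    def stats_frame(self) -> pd.DataFrame:
        rows = [
            (s.phage_a, s.phage_b, s.c, s.x, s.y, s.n, s.q) for s in self.cluster_stats
        ]
        return pd.DataFrame(rows, columns=["phage_a", "phage_b", "c", "x", "y", "n", "q"])

    @staticmethod
    def stats_from_frame(df: pd.DataFrame) -> List[SharedClusterStat]:
        return [
            SharedClusterStat(str(r.phage_a), str(r.phage_b), int(r.c), int(r.x),
                              int(r.y), int(r.n), float(r.q))
            for r in df.itertuples()
        ]


def extract_evidence(
    phage_genomes: Dict[str, str],
    host_genomes: Dict[str, str],
    backend: str = "fallback",
    xy_mode: str = "clusters",
) -> EvidenceBundle:
    """Run every evidence channel plus protein clustering."""
    catalog = evidence.call_genes(phage_genomes, backend=backend)
    bundle = EvidenceBundle()
    if any(catalog.values()):
        pgraph = evidence.protein_alignment_pairs(catalog, backend=backend)
        assignment = clustering.mcl_cluster(pgraph)
        bundle.cluster_stats = clustering.phage_pair_stats(
            assignment, catalog, pgraph, xy_mode=xy_mode
        )
    bundle.pp_blastn = evidence.blastn_pairs(phage_genomes, backend=backend)
    bundle.hh_blastn = evidence.blastn_pairs(host_genomes, backend=backend)
    bundle.ph_blastn = evidence.blastn_pairs(phage_genomes, host_genomes, backend=backend)
    bundle.crispr = evidence.detect_crispr_matches(phage_genomes, host_genomes, backend=backend)
    bundle.rbp = evidence.detect_rbp_matches(
        phage_genomes, host_genomes, catalog, backend=backend
    )
    bundle.rrna16s = evidence.detect_16s_links(host_genomes, backend=backend)
    return bundle


def build_graph(
    phage_genomes: Dict[str, str],
    host_genomes: Dict[str, str],
    bundle: EvidenceBundle,
    train_interactions: Set[Tuple[str, str]],
    thresholds: Thresholds = Thresholds(),
    test_interactions: Set[Tuple[str, str]] | None = None,
    features: kmer.FeatureMatrix | None = None,
) -> Tuple[PHKG, Dict]:
    """Apply the edge rules and assemble the knowledge graph."""
    phages = set(phage_genomes)
    hosts = set(host_genomes)
    if features is None:
        features = kmer.build_feature_matrix({**phage_genomes, **host_genomes})
    pp = graph_mod.build_pp_edges(bundle.cluster_stats, bundle.pp_blastn, thresholds, phages)
    hh = graph_mod.build_hh_edges(bundle.rrna16s, bundle.hh_blastn, thresholds, hosts)
    ph = graph_mod.build_ph_edges(
        bundle.crispr, bundle.rbp, bundle.ph_blastn, train_interactions,
        thresholds, phages, hosts, test_interactions=test_interactions,
    )
    return graph_mod.assemble_graph(
        sorted(phages), sorted(hosts), pp, hh, ph, features, thresholds
    )


def evidence_recall_report(
    detected: Sequence[EvidenceRecord], planted: Sequence[EvidenceRecord]
) -> Dict:
    """Channel-level recall and spurious-record rate of detected vs planted."""
    def keyset(records):
        out = set()
        for r in records:
            a, b = sorted((r.entity_a, r.entity_b))
            out.add((a, b, r.channel))
        return out

    det, plant = keyset(detected), keyset(planted)
    channels = sorted({c for _, _, c in plant} | {c for _, _, c in det})
    report = {}
    for ch in channels:
        d = {k for k in det if k[2] == ch}
        p = {k for k in plant if k[2] == ch}
        recall = len(d & p) / len(p) if p else float("nan")
        spurious = len(d - p) / len(d) if d else 0.0
        report[ch] = {"planted": len(p), "detected": len(d),
                      "recall": recall, "spurious_rate": spurious}
    all_p, all_d = plant, det
    report["overall"] = {
        "planted": len(all_p), "detected": len(all_d),
        "recall": len(all_d & all_p) / len(all_p) if all_p else float("nan"),
        "spurious_rate": len(all_d - all_p) / len(all_d) if all_d else 0.0,
    }
    return report
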