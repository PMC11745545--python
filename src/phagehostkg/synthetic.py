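"""Synthetic phage–host communities with planted, recoverable signal.

The generator fabricates small communities in which every evidence channel
carries signal by construction:

* hosts in the same taxonomic group carry an identical sentinel-anchored
  16S marker block (host–host signal);
* every true (phage, host) pair shares a prophage-like segment — a
  contiguous >=500 bp stretch copied from the host genome into the phage
  (nucleotide signal);
* every true pair shares a CRISPR spacer: a phage subsequence copied into
  the host flanked by that host's fixed 25 bp direct repeat (CRISPR signal);
* each phage carries a tagged receptor-binding protein whose coding block
  is also planted into each true host (RBP signal);
* phages draw protein-coding blocks from a shared pool of family peptides,
  so related phages share protein clusters (protein signal).

Background DNA is not uniform: each host group draws a base composition
from a Dirichlet prior, each host jitters it log-normally, and each phage's
background composition matches its primary host's (with small noise). This
emulates the species-specific oligonucleotide signatures of real genomes
and the amelioration of phage composition toward the host — the property
that makes k-mer features informative for host prediction in the first
place.

Non-interacting pairs share none of the planted blocks beyond chance. All
randomness flows from a single seeded generator, so a fixed seed gives
bit-identical communities. This is deliberately not a realistic genome
simulator: there is no codon model, mutation process or read simulation —
only planted blocks in composition-biased random background DNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np

from . import io as _io
from .evidence import RBP_TAG_PEPTIDE, RRNA_BODY_LEN, SENTINEL_16S, EvidenceRecord

_BASES = np.array(list("ACGT"))
_AMINO = "ACDEFGHIKLMNPQRSTVWY"
# one fixed codon per amino acid (reverse translation of planted peptides)
_CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTT", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
}

SHARED_SEGMENT_LEN = 800  # prophage-like copied segment, >= 500 bp
REPEAT_LEN = 25           # per-host CRISPR direct repeat
PLANTED_PROTEIN_AA = 80   # planted family proteins, >= 60 codons
RBP_PROTEIN_AA = 60
_MIN_GAP = 50             # random filler between planted blocks

# background-composition model: group-level Dirichlet base probabilities,
# log-normal per-host jitter, and phage composition ameliorated toward the
# primary host's with small residual noise
GROUP_COMPOSITION_ALPHA = 12.0
HOST_COMPOSITION_JITTER = 0.10
PHAGE_COMPOSITION_JITTER = 0.03


@dataclass(frozen=True)
class CommunitySpec:
    """Parameters of one synthetic community."""

    n_hosts: int
    n_phages: int
    n_host_groups: int = 3
    genome_len_host: int = 30_000
    genome_len_phage: int = 15_000
    spacer_len: int = 32
    n_planted_proteins: int = 3
    interaction_density: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_hosts", "n_phages", "n_host_groups", "genome_len_host",
                     "genome_len_phage", "spacer_len", "n_planted_proteins"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if not 0.0 < self.interaction_density <= 1.0:
            raise ValueError(
                f"interaction_density must be in (0, 1], got {self.interaction_density}"
            )
        if self.genome_len_phage < self.spacer_len:
            raise ValueError("genome_len_phage must be >= spacer_len")


@dataclass
class SyntheticCommunity:
    """A generated community plus the ground truth of what was planted."""

    spec: CommunitySpec
    host_genomes: Dict[str, str]
    phage_genomes: Dict[str, str]
    truth_interactions: Set[Tuple[str, str]]
    taxonomy: Dict[str, Tuple[str, ...]]
    planted_evidence: List[EvidenceRecord] = field(default_factory=list)
    #: (phage, host) -> the CRISPR spacer planted in both genomes
    planted_spacers: Dict[Tuple[str, str], str] = field(default_factory=dict)

    def validate(self) -> None:
        for phage, host in self.truth_interactions:
            if phage not in self.phage_genomes or host not in self.host_genomes:
                raise ValueError(f"truth pair ({phage}, {host}) references unknown accession")
        phages_with_host = {p for p, _ in self.truth_interactions}
        missing = set(self.phage_genomes) - phages_with_host
        if missing:
            raise ValueError(f"phages without any true host: {sorted(missing)}")
        if set(self.taxonomy) != set(self.host_genomes):
            raise ValueError("taxonomy does not cover exactly the host accessions")


def _random_dna(rng: np.random.Generator, n: int, pi: np.ndarray | None = None) -> str:
    if pi is None:
        return "".join(_BASES[rng.integers(0, 4, n)])
    return "".join(_BASES[rng.choice(4, size=n, p=pi)])


def _jitter(rng: np.random.Generator, pi: np.ndarray, sigma: float) -> np.ndarray:
    out = pi * np.exp(rng.normal(0.0, sigma, 4))
    return out / out.sum()


def _random_peptide(rng: np.random.Generator, n: int) -> str:
    aa = np.array(list(_AMINO))
    return "".join(aa[rng.integers(0, len(aa), n)])


def _encode_cds(peptide: str) -> str:
    return "".join(_CODON[aa] for aa in peptide) + "TAA"


def _group_lineage(group: int) -> Tuple[str, ...]:
    return (
        f"Phylum{group // 16}", f"Class{group // 8}", f"Order{group // 4}",
        f"Family{group // 2}", f"Genus{group}", f"Species{group}",
    )


def _assemble_genome(
    rng: np.random.Generator,
    blocks: Sequence[str],
    total_len: int,
    what: str,
    pi: np.ndarray | None = None,
) -> str:
    block_len = sum(len(b) for b in blocks)
    n_gaps = len(blocks) + 1
    filler = total_len - block_len
    if filler < _MIN_GAP * n_gaps:
        raise ValueError(
            f"{what} length {total_len} too small for {block_len} bp of planted "
            f"blocks plus minimal spacing; increase the genome length"
        )
    extra = filler - _MIN_GAP * n_gaps
    gaps = rng.multinomial(extra, np.full(n_gaps, 1.0 / n_gaps)) + _MIN_GAP
    parts = [_random_dna(rng, int(gaps[0]), pi)]
    for block, gap in zip(blocks, gaps[1:]):
        parts.append(block)
        parts.append(_random_dna(rng, int(gap), pi))
    return "".join(parts)


def generate_community(spec: CommunitySpec) -> SyntheticCommunity:
    """Generate a community with planted signal in every evidence channel."""
    rng = np.random.default_rng(spec.seed)
    hosts = [f"H{i:03d}" for i in range(spec.n_hosts)]
    phages = [f"P{i:03d}" for i in range(spec.n_phages)]
    group_of = {h: i % spec.n_host_groups for i, h in enumerate(hosts)}
    taxonomy = {h: _group_lineage(group_of[h]) for h in hosts}

    # ---- primitive planted blocks -------------------------------------
    group_16s = {
        g: SENTINEL_16S + _random_dna(rng, RRNA_BODY_LEN)
        for g in range(spec.n_host_groups)
    }
    host_repeat = {h: _random_dna(rng, REPEAT_LEN) for h in hosts}
    n_families = max(4, spec.n_phages // 2)
    family_peptides = [
        "M" + _random_peptide(rng, PLANTED_PROTEIN_AA - 1) for _ in range(n_families)
    ]
    rbp_peptide = {
        p: "M" + RBP_TAG_PEPTIDE + _random_peptide(rng, RBP_PROTEIN_AA - 1 - len(RBP_TAG_PEPTIDE))
        for p in phages
    }
    family_pick = {
        p: sorted(
            rng.choice(n_families, size=min(spec.n_planted_proteins, n_families),
                       replace=False).tolist()
        )
        for p in phages
    }

    # ---- truth interactions -------------------------------------------
    truth: Set[Tuple[str, str]] = set()
    draw = rng.random((spec.n_phages, spec.n_hosts))
    for i, p in enumerate(phages):
        for j, h in enumerate(hosts):
            if draw[i, j] < spec.interaction_density:
                truth.add((p, h))
        if not any((p, h) in truth for h in hosts):
            truth.add((p, hosts[int(rng.integers(spec.n_hosts))]))

    # ---- background compositions ---------------------------------------
    group_pi = {
        g: rng.dirichlet([GROUP_COMPOSITION_ALPHA] * 4) for g in range(spec.n_host_groups)
    }
    host_pi = {h: _jitter(rng, group_pi[group_of[h]], HOST_COMPOSITION_JITTER) for h in hosts}
    primary_host = {
        p: min(h for ph, h in truth if ph == p) for p in phages
    }
    phage_pi = {
        p: _jitter(rng, host_pi[primary_host[p]], PHAGE_COMPOSITION_JITTER) for p in phages
    }

    pair_segment = {
        pair: _random_dna(rng, SHARED_SEGMENT_LEN, host_pi[pair[1]]) for pair in sorted(truth)
    }
    pair_spacer = {pair: _random_dna(rng, spec.spacer_len) for pair in sorted(truth)}

    # ---- phage genomes -------------------------------------------------
    phage_genomes: Dict[str, str] = {}
    for p in phages:
        blocks: List[str] = [_encode_cds(family_peptides[f]) for f in family_pick[p]]
        blocks.append(_encode_cds(rbp_peptide[p]))
        for pair in sorted(pr for pr in truth if pr[0] == p):
            blocks.append(pair_segment[pair])
            blocks.append(pair_spacer[pair])
        phage_genomes[p] = _assemble_genome(
            rng, blocks, spec.genome_len_phage, f"phage {p}", phage_pi[p]
        )

    # ---- host genomes --------------------------------------------------
    host_genomes: Dict[str, str] = {}
    for h in hosts:
        partners = sorted(pr for pr in truth if pr[1] == h)
        blocks = [group_16s[group_of[h]]]
        if partners:
            array = host_repeat[h]
            for pair in partners:
                array += pair_spacer[pair] + host_repeat[h]
            blocks.append(array)
        for pair in partners:
            blocks.append(pair_segment[pair])
            blocks.append(_encode_cds(rbp_peptide[pair[0]]))
        host_genomes[h] = _assemble_genome(
            rng, blocks, spec.genome_len_host, f"host {h}", host_pi[h]
        )

    # ---- planted evidence ledger ---------------------------------------
    # Besides the per-pair prophage segment, planted blocks imply further
    # genuine nucleotide sharing: identical 16S blocks within a host group,
    # identical family CDSs between phages drawing the same family, and the
    # RBP CDS of a shared phage partner between two hosts. All are listed so
    # detector output can be audited against exactly what was planted.
    planted: List[EvidenceRecord] = []
    partners_of_host = {h: {p for p, hh in truth if hh == h} for h in hosts}
    for i, a in enumerate(hosts):
        for b in hosts[i + 1 :]:
            if group_of[a] == group_of[b]:
                planted.append(EvidenceRecord(a, b, "rrna16s", 1.0))
                planted.append(EvidenceRecord(a, b, "blastn", 1.0))
            elif partners_of_host[a] & partners_of_host[b]:
                planted.append(EvidenceRecord(a, b, "blastn", 1.0))
    for phage, host in sorted(truth):
        planted.append(EvidenceRecord(phage, host, "blastn", 1.0))
        planted.append(EvidenceRecord(phage, host, "crispr", 1.0))
        planted.append(EvidenceRecord(phage, host, "rbp", 1.0))
    for i, a in enumerate(phages):
        for b in phages[i + 1 :]:
            if set(family_pick[a]) & set(family_pick[b]):
                planted.append(EvidenceRecord(a, b, "protein_cluster", 1.0))
                planted.append(EvidenceRecord(a, b, "blastn", 1.0))

    community = SyntheticCommunity(
        spec=spec,
        host_genomes=host_genomes,
        phage_genomes=phage_genomes,
        truth_interactions=truth,
        taxonomy=taxonomy,
        planted_evidence=planted,
        planted_spacers=pair_spacer,
    )
    community.validate()
    return community


def write_fixture(community: SyntheticCommunity, out_dir: str | Path) -> Dict:
    """Write FASTA + TSV fixture files and return the JSON manifest."""
    if not community.phage_genomes or not community.host_genomes:
        raise ValueError("cannot write an empty community (no phages or no hosts)")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "host_fasta": out / "hosts.fasta",
        "phage_fasta": out / "phages.fasta",
        "interactions": out / "interactions.tsv",
        "taxonomy": out / "taxonomy.tsv",
        "planted_evidence": out / "planted_evidence.tsv",
    }
    _io.write_fasta(community.host_genomes, paths["host_fasta"])
    _io.write_fasta(community.phage_genomes, paths["phage_fasta"])
    _io.write_interactions(community.truth_interactions, paths["interactions"])
    _io.write_taxonomy(community.taxonomy, paths["taxonomy"])
    from .evidence import records_to_frame

    records_to_frame(community.planted_evidence).to_csv(
        paths["planted_evidence"], sep="\t", index=False
    )
    manifest = {
        "n_hosts": len(community.host_genomes),
        "n_phages": len(community.phage_genomes),
        "n_fasta_records": len(community.host_genomes) + len(community.phage_genomes),
        "n_interactions": len(community.truth_interactions),
        "seed": community.spec.seed,
        "files": {k: str(v) for k, v in paths.items()},
    }
    _io.write_json(manifest, out / "manifest.json")
    return manifest
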