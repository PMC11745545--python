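"""Pairwise similarity evidence between phages and prokaryotic hosts.

Five sequence-derived channels feed the knowledge graph:

* ``protein_cluster`` — phage–phage: tail probability of sharing at least c
  protein clusters (computed downstream from the protein graph built here);
* ``blastn``          — any pair: nucleotide-level similarity, an e-value;
* ``crispr``          — phage–host: a host CRISPR spacer matching the phage;
* ``rbp``             — phage–host: a phage receptor-binding protein with a
  translated match in the host genome;
* ``rrna16s``         — host–host: near-identical 16S rRNA sequences.

Each detector has two backends. The ``external`` backend adapts the field's
standard tools (prodigal for gene calling, blastn for nucleotide alignment;
CRT / Barrnap / RBP detectors are adapted only through their tabular output
because they are not generally installed). The ``fallback`` backend is a
self-contained detector with an explicit, documented contract — exact
shared 7-mer peptides for protein links, a direct-repeat scanner plus
<=1-mismatch spacer search for CRISPR, a sentinel-anchored 16S extractor,
and a suffix-automaton longest-shared-substring statistic with a calibrated
pseudo-e-value standing in for BLASTN. Fallback detectors are deterministic
and are what the test fixtures exercise.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Set, Tuple

import edlib
import pandas as pd
from Bio.Seq import Seq

# ---------------------------------------------------------------------------
# channel registry and the record type

CHANNELS = ("protein_cluster", "blastn", "crispr", "rbp", "rrna16s", "known_interaction")

# legal (class of entity_a, class of entity_b) per channel; p = phage, h = host
_CHANNEL_CLASSES = {
    "protein_cluster": {("p", "p")},
    "blastn": {("p", "p"), ("h", "h"), ("p", "h")},
    "crispr": {("p", "h")},
    "rbp": {("p", "h")},
    "rrna16s": {("h", "h")},
    "known_interaction": {("p", "h")},
}


@dataclass(frozen=True)
class EvidenceRecord:
    """One typed pairwise similarity observation.

    ``value`` is an e-value for ``blastn``, a tail probability for
    ``protein_cluster`` and 1.0 for the binary channels.
    """

    entity_a: str
    entity_b: str
    channel: str

    value: float = 1.0

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown evidence channel {self.channel!r}")
        if self.channel in ("protein_cluster", "crispr", "rbp", "rrna16s", "known_interaction"):
            if not 0.0 <= self.value <= 1.0:
                raise ValueError(f"{self.channel} value must be a probability, got {self.value}")
        elif self.value < 0:
            raise ValueError(f"e-value must be >= 0, got {self.value}")

    def pair(self) -> Tuple[str, str]:
        return (self.entity_a, self.entity_b)


def validate_record_classes(
    records: Iterable[EvidenceRecord], phages: Set[str], hosts: Set[str]
) -> None:
    """Check that each record's endpoint classes are legal for its channel."""
    for rec in records:
        classes = []
        for ent in (rec.entity_a, rec.entity_b):
            if ent in phages:
                classes.append("p")
            elif ent in hosts:
                classes.append("h")
            else:
                raise ValueError(f"unknown accession {ent!r} in evidence record")
        key = tuple(classes)
        legal = _CHANNEL_CLASSES[rec.channel]
        if key not in legal and key[::-1] not in legal:
            raise ValueError(
                f"channel {rec.channel} cannot link classes {key[0]}-{key[1]} "
                f"({rec.entity_a}, {rec.entity_b})"
            )


def records_to_frame(records: Iterable[EvidenceRecord]) -> pd.DataFrame:
    rows = [(r.entity_a, r.entity_b, r.channel, r.value) for r in records]
    return pd.DataFrame(rows, columns=["entity_a", "entity_b", "channel", "value"])


def records_from_frame(df: pd.DataFrame) -> List[EvidenceRecord]:
    return [
        EvidenceRecord(str(r.entity_a), str(r.entity_b), str(r.channel), float(r.value))
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# fallback detector conventions (shared with the synthetic-community planter)

#: sentinel motif anchoring the 16S rRNA marker block that the fallback
#: extractor keys on; the block is the sentinel plus RRNA_BODY_LEN bases
SENTINEL_16S = "ATGGCTGGCGGTGTGGGTTA"
RRNA_BODY_LEN = 400
#: peptide tag marking receptor-binding proteins for the fallback detector
RBP_TAG_PEPTIDE = "WNDGRTAW"

MIN_ORF_CODONS = 60
PEPTIDE_KMER = 7
#: shared-peptide-7-mer count -> pseudo-e-value (monotone decreasing);
#: 5 shared 7-mers crosses the 1e-5 protein-link threshold
_PROTEIN_E_BASE = 2.0
_PROTEIN_E_SLOPE = 1.5
#: longest-shared-substring length -> pseudo-e-value; calibrated so a
#: >=500 bp shared segment scores e < 1e-10 while the ~25 bp chance LCS of
#: unrelated 50 kb genomes scores e > 1e-3
_BLASTN_E_INTERCEPT = 3.0
_BLASTN_E_SCALE = 20.0
#: records with a pseudo-e-value above this are not reported at all
BLASTN_REPORT_EVALUE = 1e-4

PROTEIN_LINK_EVALUE = 1e-5

MIN_CRISPR_REPEAT = 20
MAX_CRISPR_REPEAT = 40
MIN_SPACER = 20
MAX_SPACER = 50
RRNA_IDENTITY = 0.97
RBP_MIN_MATCH_AA = 25


class ExternalToolError(RuntimeError):
    """Raised when an external-backend tool is unavailable."""


def _require_tool(name: str, channel: str) -> str:
    path = shutil.which(name)
    if path is None:
        raise ExternalToolError(
            f"external tool {name!r} for the {channel} channel is not on PATH; "
            f"rerun with backend='fallback' or provide a precomputed evidence table"
        )
    return path


# ---------------------------------------------------------------------------
# gene calling

GeneCatalog = Dict[str, List[str]]


def call_genes(genomes: Dict[str, str], backend: str = "fallback") -> GeneCatalog:
    """Predict protein sequences for every genome.

    The external backend shells out to prodigal (metagenome mode) and parses
    its protein FASTA. The fallback extracts every open reading frame of at
    least 60 codons — any in-frame ATG up to the next in-frame stop, on all
    six frames — and translates it with the standard code, so a planted CDS
    is always recovered verbatim among the calls.
    """
    if not genomes:
        raise ValueError("empty genome map")
    if backend == "external":
        return _call_genes_prodigal(genomes)
    if backend != "fallback":
        raise ValueError(f"unknown backend {backend!r}")
    catalog: GeneCatalog = {}
    for acc in sorted(genomes):
        catalog[acc] = _orf_proteins(genomes[acc])
    return catalog


def _orf_proteins(genome: str) -> List[str]:
    proteins: List[str] = []
    seen: Set[str] = set()
    seq = genome.upper()
    for strand_seq in (seq, str(Seq(seq).reverse_complement())):
        for frame in range(3):
            sub = strand_seq[frame:]
            sub = sub[: len(sub) - len(sub) % 3]
            if not sub:
                continue
            aa = str(Seq(sub).translate())
            start = 0
            for stop in _iter_stops(aa):
                segment = aa[start:stop]
                pos = segment.find("M")
                while pos != -1:
                    if len(segment) - pos >= MIN_ORF_CODONS and stop < len(aa):
                        prot = segment[pos:]
                        if prot not in seen:
                            seen.add(prot)
                            proteins.append(prot)
                    pos = segment.find("M", pos + 1)
                start = stop + 1
    return proteins


def _iter_stops(aa: str):
    for i, c in enumerate(aa):
        if c == "*":
            yield i
    yield len(aa)


def _call_genes_prodigal(genomes: Dict[str, str]) -> GeneCatalog:
    from . import io as _io

    prodigal = _require_tool("prodigal", "protein_cluster")
    catalog: GeneCatalog = {acc: [] for acc in genomes}
    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "genomes.fa"
        faa = Path(tmp) / "proteins.faa"
        _io.write_fasta(genomes, fasta)
        subprocess.run(
            [prodigal, "-i", str(fasta), "-a", str(faa), "-p", "meta", "-q",
             "-o", str(Path(tmp) / "genes.out")],
            check=True, capture_output=True,
        )
        from Bio import SeqIO

        for rec in SeqIO.parse(str(faa), "fasta"):
            acc = rec.id.rsplit("_", 1)[0]
            catalog.setdefault(acc, []).append(str(rec.seq).rstrip("*"))
    return catalog


# ---------------------------------------------------------------------------
# protein-protein alignment graph

@dataclass
class ProteinGraph:
    """Weighted graph over protein sequences; nodes are (accession, index) ids."""

    nodes: List[str]
    proteins: Dict[str, str]
    owner: Dict[str, str]
    edges: Dict[Tuple[str, str], float]


def catalog_protein_ids(catalog: GeneCatalog) -> ProteinGraph:
    nodes, proteins, owner = [], {}, {}
    for acc in sorted(catalog):
        for i, prot in enumerate(catalog[acc]):
            pid = f"{acc}|{i}"
            nodes.append(pid)
            proteins[pid] = prot
            owner[pid] = acc
    return ProteinGraph(nodes, proteins, owner, {})


def protein_shared_kmer_evalue(shared: int) -> float:
    """Pseudo-e-value for a protein pair sharing `shared` distinct 7-mers."""
    return 10.0 ** (_PROTEIN_E_BASE - _PROTEIN_E_SLOPE * shared)


def protein_alignment_pairs(catalog: GeneCatalog, backend: str = "fallback") -> ProteinGraph:
    """Build the protein similarity graph used for Markov clustering.

    Edges join protein pairs whose alignment e-value is below 1e-5. The
    fallback scores a pair by its count of shared distinct 7-mer peptides,
    mapped through a calibrated monotone pseudo-e-value; unrelated proteins
    essentially never share five or more 7-mers, while homologs share many.
    """
    if not catalog or not any(catalog.values()):
        raise ValueError("empty gene catalog")
    if backend == "external":
        _require_tool("diamond", "protein_cluster")
    elif backend != "fallback":
        raise ValueError(f"unknown backend {backend!r}")
    graph = catalog_protein_ids(catalog)
    index: Dict[str, Set[int]] = defaultdict(set)
    node_ix = {pid: i for i, pid in enumerate(graph.nodes)}
    for pid in graph.nodes:
        prot = graph.proteins[pid]
        for j in range(len(prot) - PEPTIDE_KMER + 1):
            index[prot[j : j + PEPTIDE_KMER]].add(node_ix[pid])
    shared: Dict[Tuple[int, int], int] = defaultdict(int)
    for members in index.values():
        if len(members) < 2:
            continue
        ms = sorted(members)
        for i, a in enumerate(ms):
            for b in ms[i + 1 :]:
                shared[(a, b)] += 1
    for (a, b), count in shared.items():
        e = protein_shared_kmer_evalue(count)
        if e < PROTEIN_LINK_EVALUE:
            graph.edges[(graph.nodes[a], graph.nodes[b])] = 1.0
    return graph


def protein_pairs_from_alignment_table(catalog: GeneCatalog, table: pd.DataFrame) -> ProteinGraph:
    """Build the protein graph from precomputed tabular alignments (outfmt 6)."""
    graph = catalog_protein_ids(catalog)
    known = set(graph.nodes)
    for row in table.itertuples():
        a, b = str(row.qseqid), str(row.sseqid)
        if a == b or a not in known or b not in known:
            continue
        if float(row.evalue) < PROTEIN_LINK_EVALUE:
            key = (a, b) if a < b else (b, a)
            graph.edges[key] = 1.0
    return graph


# ---------------------------------------------------------------------------
# CRISPR spacers

def detect_crispr_matches(
    phage_genomes: Dict[str, str],
    host_genomes: Dict[str, str],
    backend: str = "fallback",
) -> List[EvidenceRecord]:
    """Link a phage to a host whose CRISPR array stores a matching spacer.

    The fallback finds arrays as >=2 copies of a 20–40 bp direct repeat
    separated by 20–50 bp spacers, then reports a record when a spacer
    matches a phage genome with at most one mismatch over at least 95% of
    its length (the edit-distance-1 search is done with edlib).
    """
    if not phage_genomes or not host_genomes:
        raise ValueError("empty genome map")
    if backend == "external":
        _require_tool("crt", "crispr")
    elif backend != "fallback":
        raise ValueError(f"unknown backend {backend!r}")
    records: List[EvidenceRecord] = []
    for host in sorted(host_genomes):
        spacers = find_crispr_spacers(host_genomes[host])
        if not spacers:
            continue
        for phage in sorted(phage_genomes):
            target = phage_genomes[phage]
            for spacer in spacers:
                res = edlib.align(spacer, target, mode="HW", task="distance", k=1)
                if res["editDistance"] != -1:
                    records.append(EvidenceRecord(phage, host, "crispr", 1.0))
                    break
    return records


def find_crispr_spacers(genome: str) -> List[str]:
    """Extract spacer sequences from direct-repeat arrays in one genome."""
    seq = genome.upper()
    k = MIN_CRISPR_REPEAT
    positions: Dict[str, List[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        positions[seq[i : i + k]].append(i)
    spacers: List[str] = []
    seen: Set[str] = set()
    for kmer, occ in positions.items():
        if len(occ) < 2:
            continue
        for p1, p2 in zip(occ, occ[1:]):
            d = p2 - p1
            if not (MIN_CRISPR_REPEAT + MIN_SPACER <= d <= MAX_CRISPR_REPEAT + MAX_SPACER):
                continue
            # canonical start: repeat not left-extendable
            if p1 > 0 and p2 > 0 and seq[p1 - 1] == seq[p2 - 1]:
                continue
            r = k
            while (
                r < MAX_CRISPR_REPEAT
                and p2 + r < len(seq)
                and p1 + r < p2
                and seq[p1 + r] == seq[p2 + r]
            ):
                r += 1
            spacer = seq[p1 + r : p2]
            if MIN_SPACER <= len(spacer) <= MAX_SPACER and spacer not in seen:
                seen.add(spacer)
                spacers.append(spacer)
    return spacers


# ---------------------------------------------------------------------------
# receptor-binding proteins

def detect_rbp_matches(
    phage_genomes: Dict[str, str],
    host_genomes: Dict[str, str],
    catalog: GeneCatalog,
    backend: str = "fallback",
) -> List[EvidenceRecord]:
    """Link a phage to hosts carrying a translated copy of one of its RBPs.

    The fallback marks catalog proteins containing the RBP tag peptide as
    receptor-binding proteins, then reports a record when such a protein has
    an exact translated match of >=25 aa in any six-frame translation of a
    host genome.
    """
    if backend == "external":
        _require_tool("PhageRBPDetection", "rbp")
    elif backend != "fallback":
        raise ValueError(f"unknown backend {backend!r}")
    host_frames = {
        host: _six_frame_translations(host_genomes[host]) for host in sorted(host_genomes)
    }
    records: List[EvidenceRecord] = []
    for phage in sorted(phage_genomes):
        rbps = [p for p in catalog.get(phage, []) if RBP_TAG_PEPTIDE in p]
        if not rbps:
            continue
        for host, frames in host_frames.items():
            if any(_has_translated_match(rbp, frames) for rbp in rbps):
                records.append(EvidenceRecord(phage, host, "rbp", 1.0))
    return records


def _six_frame_translations(genome: str) -> List[str]:
    seq = genome.upper()
    frames = []
    for strand_seq in (seq, str(Seq(seq).reverse_complement())):
        for frame in range(3):
            sub = strand_seq[frame:]
            sub = sub[: len(sub) - len(sub) % 3]
            if sub:
                frames.append(str(Seq(sub).translate()))
    return frames


def _has_translated_match(protein: str, frames: List[str]) -> bool:
    if len(protein) < RBP_MIN_MATCH_AA:
        return False
    probe = protein if len(protein) <= 200 else protein[:200]
    for frame in frames:
        if probe in frame:
            return True
    # fall back to any >=25 aa window for partial insertions
    for start in range(0, len(protein) - RBP_MIN_MATCH_AA + 1, RBP_MIN_MATCH_AA):
        window = protein[start : start + RBP_MIN_MATCH_AA]
        if any(window in frame for frame in frames):
            return True
    return False


# ---------------------------------------------------------------------------
# 16S rRNA

def detect_16s_links(
    host_genomes: Dict[str, str], backend: str = "fallback"
) -> List[EvidenceRecord]:
    """Link host pairs with near-identical 16S rRNA marker blocks.

    The fallback extracts the marker as the fixed sentinel motif plus the
    following 400 bases and links two hosts when the blocks agree at >=97%
    identity over their full length (the conventional species-level bound).
    Hosts lacking the sentinel are excluded silently.
    """
    if backend == "external":
        _require_tool("barrnap", "rrna16s")
    elif backend != "fallback":
        raise ValueError(f"unknown backend {backend!r}")
    blocks: Dict[str, str] = {}
    for host in sorted(host_genomes):
        block = extract_16s_block(host_genomes[host])
        if block is not None:
            blocks[host] = block
    records = []
    hosts = sorted(blocks)
    for i, a in enumerate(hosts):
        for b in hosts[i + 1 :]:
            if _identity(blocks[a], blocks[b]) >= RRNA_IDENTITY:
                records.append(EvidenceRecord(a, b, "rrna16s", 1.0))
    return records


def extract_16s_block(genome: str) -> str | None:
    seq = genome.upper()
    pos = seq.find(SENTINEL_16S)
    if pos == -1:
        return None
    block = seq[pos : pos + len(SENTINEL_16S) + RRNA_BODY_LEN]
    if len(block) < len(SENTINEL_16S) + RRNA_BODY_LEN:
        return None
    return block


def _identity(a: str, b: str) -> float:
    if len(a) != len(b):
        return 0.0
    return sum(x == y for x, y in zip(a, b)) / len(a)


# ---------------------------------------------------------------------------
# nucleotide similarity (BLASTN or longest-shared-substring stand-in)

class SuffixAutomaton:
    """Suffix automaton of one string; answers longest-common-substring queries."""

    __slots__ = ("next", "link", "length", "last")

    def __init__(self, s: str):
        self.next: List[Dict[str, int]] = [{}]
        self.link: List[int] = [-1]
        self.length: List[int] = [0]
        self.last = 0
        for ch in s:
            self._extend(ch)

    def _extend(self, ch: str) -> None:
        cur = len(self.next)
        self.next.append({})
        self.length.append(self.length[self.last] + 1)
        self.link.append(-1)
        p = self.last
        while p != -1 and ch not in self.next[p]:
            self.next[p][ch] = cur
            p = self.link[p]
        if p == -1:
            self.link[cur] = 0
        else:
            q = self.next[p][ch]
            if self.length[p] + 1 == self.length[q]:
                self.link[cur] = q
            else:
                clone = len(self.next)
                self.next.append(dict(self.next[q]))
                self.length.append(self.length[p] + 1)
                self.link.append(self.link[q])
                while p != -1 and self.next[p].get(ch) == q:
                    self.next[p][ch] = clone
                    p = self.link[p]
                self.link[q] = clone
                self.link[cur] = clone
        self.last = cur

    def longest_common_substring(self, t: str) -> int:
        v, length, best = 0, 0, 0
        for ch in t:
            while v and ch not in self.next[v]:
                v = self.link[v]
                length = self.length[v]
            if ch in self.next[v]:
                v = self.next[v][ch]
                length += 1
                if length > best:
                    best = length
        return best


def shared_substring_evalue(lcs_length: int) -> float:
    """Monotone pseudo-e-value for a longest shared substring of given length."""
    return 10.0 ** (_BLASTN_E_INTERCEPT - lcs_length / _BLASTN_E_SCALE)


def blastn_pairs(
    genomes_a: Dict[str, str],
    genomes_b: Dict[str, str] | None = None,
    backend: str = "fallback",
) -> List[EvidenceRecord]:
    """Nucleotide similarity records with e-values for genome pairs.

    With one genome map, scores all unordered pairs within it; with two,
    scores the cross product. The external backend runs blastn and keeps
    the best e-value per pair; the fallback computes the longest exact
    shared substring via a suffix automaton and maps its length through a
    calibrated pseudo-e-value, reporting only pairs below 1e-4.
    """
    if backend == "external":
        return _blastn_external(genomes_a, genomes_b)
    if backend != "fallback":
        raise ValueError(f"unknown backend {backend!r}")
    records: List[EvidenceRecord] = []
    if genomes_b is None:
        accs = sorted(genomes_a)
        automata = {acc: SuffixAutomaton(genomes_a[acc].upper()) for acc in accs}
        for i, a in enumerate(accs):
            for b in accs[i + 1 :]:
                lcs = automata[a].longest_common_substring(genomes_a[b].upper())
                e = shared_substring_evalue(lcs)
                if e < BLASTN_REPORT_EVALUE:
                    records.append(EvidenceRecord(a, b, "blastn", e))
    else:
        automata = {acc: SuffixAutomaton(genomes_b[acc].upper()) for acc in sorted(genomes_b)}
        for a in sorted(genomes_a):
            for b in sorted(genomes_b):
                lcs = automata[b].longest_common_substring(genomes_a[a].upper())
                e = shared_substring_evalue(lcs)
                if e < BLASTN_REPORT_EVALUE:
                    records.append(EvidenceRecord(a, b, "blastn", e))
    return records


def _blastn_external(
    genomes_a: Dict[str, str], genomes_b: Dict[str, str] | None
) -> List[EvidenceRecord]:
    from . import io as _io

    blastn = _require_tool("blastn", "blastn")
    targets = genomes_a if genomes_b is None else genomes_b
    best: Dict[Tuple[str, str], float] = {}
    with tempfile.TemporaryDirectory() as tmp:
        qpath = Path(tmp) / "query.fa"
        spath = Path(tmp) / "subject.fa"
        _io.write_fasta(genomes_a, qpath)
        _io.write_fasta(targets, spath)
        out = subprocess.run(
            [blastn, "-query", str(qpath), "-subject", str(spath),
             "-outfmt", "6 qseqid sseqid pident length evalue bitscore",
             "-evalue", "1e-3"],
            check=True, capture_output=True, text=True,
        ).stdout
        for line in out.splitlines():
            q, s, _pid, _len, evalue, _bits = line.split("\t")[:6]
            if q == s:
                continue
            key = (q, s) if genomes_b is not None else (min(q, s), max(q, s))
            e = float(evalue)
            if key not in best or e < best[key]:
                best[key] = e
    return [EvidenceRecord(a, b, "blastn", e) for (a, b), e in sorted(best.items())]
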