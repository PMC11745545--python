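"""Node features: k-mer frequency vectors of genomic DNA.

Each phage and host node is represented by the frequency of every length-k
word over the forward strand (k=4 by default, giving 256 features). Columns
follow the fixed lexicographic order of k-mers over A < C < G < T. Windows
containing ambiguity codes (N etc.) are skipped; frequencies are counts over
valid windows, so each row sums to 1 unless a sequence yields no valid
window at all (then the row is all zeros). The strand is not canonicalized
and counts are not log-transformed: the feature is the plain forward-strand
4-mer spectrum.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Sequence, Union

import numpy as np
import pandas as pd

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i

GenomeMap = Dict[str, Union[str, Sequence[str]]]


def kmer_order(k: int) -> List[str]:
    """Lexicographic k-mer column labels over the alphabet A<C<G<T."""
    return ["".join(p) for p in itertools.product("ACGT", repeat=k)]


def kmer_frequency_vector(sequence: str, k: int = 4) -> np.ndarray:
    """Frequency of every k-mer among the valid length-k windows of `sequence`.

    A window is valid when all of its bases are A/C/G/T (case-insensitive);
    other windows are skipped. Returns an all-zero vector (with a warning)
    when the sequence has no valid window.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    n_cols = 4**k
    codes = _BASE_CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    if codes.size < k:
        warnings.warn(f"sequence of length {codes.size} has no {k}-mer window")
        return np.zeros(n_cols)
    # rolling base-4 encoding of each window; invalidate windows touching
    # any non-ACGT base
    n_win = codes.size - k + 1
    idx = np.zeros(n_win, dtype=np.int64)
    valid = np.ones(n_win, dtype=bool)
    for offset in range(k):
        col = codes[offset : offset + n_win]
        idx = idx * 4 + np.where(col >= 0, col, 0)
        valid &= col >= 0
    counts = np.bincount(idx[valid], minlength=n_cols).astype(float)
    total = counts.sum()
    if total == 0:
        warnings.warn("sequence yields no valid k-mer window (ambiguous bases)")
        return np.zeros(n_cols)
    return counts / total


@dataclass
class FeatureMatrix:
    """Node feature matrix: one row of 4^k k-mer frequencies per accession."""

    node_ids: List[str]
    matrix: np.ndarray
    k: int = 4

    def __post_init__(self) -> None:
        if len(self.node_ids) != self.matrix.shape[0]:
            raise ValueError("node_ids and matrix row count disagree")

    def row(self, accession: str) -> np.ndarray:
        return self.matrix[self.node_ids.index(accession)]

    def subset(self, accessions: Sequence[str]) -> "FeatureMatrix":
        index = {a: i for i, a in enumerate(self.node_ids)}
        rows = [index[a] for a in accessions]
        return FeatureMatrix(list(accessions), self.matrix[rows], self.k)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.matrix, columns=kmer_order(self.k))
        df.insert(0, "accession", self.node_ids)
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t")
        ids = df["accession"].astype(str).tolist()
        mat = df.drop(columns="accession").to_numpy(dtype=float)
        k = int(round(np.log(mat.shape[1]) / np.log(4)))
        return cls(ids, mat, k)

    def to_npz(self, path: str | Path) -> None:
        np.savez_compressed(path, node_ids=np.array(self.node_ids), matrix=self.matrix, k=self.k)

    @classmethod
    def from_npz(cls, path: str | Path) -> "FeatureMatrix":
        data = np.load(path, allow_pickle=False)
        return cls([str(x) for x in data["node_ids"]], data["matrix"], int(data["k"]))


def build_feature_matrix(genomes: GenomeMap, k: int = 4) -> FeatureMatrix:
    """One k-mer frequency row per accession, rows in sorted-accession order.

    A genome may be a single sequence or a list of contigs; counts are pooled
    per accession with windows never spanning contig boundaries.
    """
    if not genomes:
        raise ValueError("empty genome map")
    accessions = sorted(genomes)
    if len(accessions) != len(set(accessions)):
        raise ValueError("duplicate accessions in genome map")
    rows = []
    for acc in accessions:
        seqs = genomes[acc]
        contigs = [seqs] if isinstance(seqs, str) else list(seqs)
        counts = np.zeros(4**k)
        weight = 0.0
        for contig in contigs:
            n_valid_windows = 0
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                vec = kmer_frequency_vector(contig, k)
            s = vec.sum()
            if s > 0:
                # recover per-contig window count to pool across contigs
                n_valid_windows = _valid_window_count(contig, k)
                counts += vec * n_valid_windows
                weight += n_valid_windows
        rows.append(counts / weight if weight > 0 else counts)
    return FeatureMatrix(accessions, np.array(rows), k)


def _valid_window_count(sequence: str, k: int) -> int:
    codes = _BASE_CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    if codes.size < k:
        return 0
    n_win = codes.size - k + 1
    valid = np.ones(n_win, dtype=bool)
    for offset in range(k):
        valid &= codes[offset : offset + n_win] >= 0
    return int(valid.sum())
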