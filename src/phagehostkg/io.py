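"""Readers and writers for the on-disk interchange formats.

Everything the pipeline persists between stages is plain text: FASTA for
genomes, TSV with a header row for tabular data (interactions, taxonomy,
evidence, edge lists, feature matrices) and JSON for reports/manifests.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, Set, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

INTERACTION_COLUMNS = ["phage_accession", "host_accession"]
TAXONOMY_RANKS = ["phylum", "class", "order", "family", "genus", "species"]
TAXONOMY_COLUMNS = ["host_accession"] + TAXONOMY_RANKS
EVIDENCE_COLUMNS = ["entity_a", "entity_b", "channel", "value"]
EDGE_COLUMNS = ["node_a", "node_b", "edge_type"]


def read_fasta(path: str | Path) -> Dict[str, str]:
    """Read a FASTA file into an accession -> uppercase sequence map."""
    genomes: Dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in genomes:
            raise ValueError(f"duplicate accession in {path}: {record.id}")
        genomes[record.id] = str(record.seq).upper()
    return genomes


def write_fasta(genomes: Dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=acc, description="")
        for acc, seq in sorted(genomes.items())
    ]
    SeqIO.write(records, str(path), "fasta")


def read_interactions(path: str | Path) -> Set[Tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in INTERACTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"interaction table {path} missing columns {missing}")
    return {
        (row.phage_accession, row.host_accession) for row in df.itertuples()
    }


def write_interactions(pairs: Iterable[Tuple[str, str]], path: str | Path) -> None:
    df = pd.DataFrame(sorted(pairs), columns=INTERACTION_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_taxonomy(path: str | Path) -> Dict[str, Tuple[str, ...]]:
    """Read host taxonomy as accession -> (phylum, ..., species)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("unknown")
    missing = [c for c in TAXONOMY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"taxonomy table {path} missing columns {missing}")
    arr = df[TAXONOMY_COLUMNS].to_numpy(dtype=object)
    return {row[0]: tuple(row[1:]) for row in arr}


def write_taxonomy(taxonomy: Dict[str, Tuple[str, ...]], path: str | Path) -> None:
    rows = [[acc, *lineage] for acc, lineage in sorted(taxonomy.items())]
    pd.DataFrame(rows, columns=TAXONOMY_COLUMNS).to_csv(path, sep="\t", index=False)


def read_evidence_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"entity_a": str, "entity_b": str, "channel": str})
    missing = [c for c in EVIDENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"evidence table {path} missing columns {missing}")
    return df


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def read_tabular_alignment(path: str | Path) -> pd.DataFrame:
    """Parse outfmt-6-style tabular alignment output (no header row)."""
    cols = ["qseqid", "sseqid", "pident", "length", "evalue", "bitscore"]
    df = pd.read_csv(path, sep="\t", header=None, usecols=range(len(cols)), names=cols)
    return df
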