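import numpy as np
import pytest

from phagehostkg import evidence as ev
from phagehostkg import pipeline


# ---------------------------------------------------------------------------
# record type

def test_record_value_ranges():
    ev.EvidenceRecord("P0", "H0", "crispr", 1.0)
    with pytest.raises(ValueError):
        ev.EvidenceRecord("P0", "H0", "crispr", 2.0)
    with pytest.raises(ValueError):
        ev.EvidenceRecord("P0", "P1", "blastn", -1.0)
    with pytest.raises(ValueError):
        ev.EvidenceRecord("P0", "P1", "telepathy")


def test_channel_class_legality():
    phages, hosts = {"P0", "P1"}, {"H0"}
    ev.validate_record_classes(
        [ev.EvidenceRecord("P0", "P1", "protein_cluster", 0.1)], phages, hosts
    )
    with pytest.raises(ValueError, match="cannot link"):
        ev.validate_record_classes(
            [ev.EvidenceRecord("P0", "H0", "rrna16s")], phages, hosts
        )
    with pytest.raises(ValueError, match="unknown accession"):
        ev.validate_record_classes(
            [ev.EvidenceRecord("P9", "H0", "crispr")], phages, hosts
        )


# ---------------------------------------------------------------------------
# gene calling

def _encode(protein: str) -> str:
    table = {"M": "ATG", "A": "GCT", "K": "AAA", "L": "CTT", "W": "TGG",
             "N": "AAT", "D": "GAT", "G": "GGT", "R": "CGT", "T": "ACT"}
    return "".join(table[a] for a in protein) + "TAA"


def test_planted_forward_orf_recovered():
    protein = "M" + "AKL" * 30  # 91 aa
    genome = "CC" + _encode(protein) + "CCCCCC"
    catalog = ev.call_genes({"g": genome})
    assert protein in catalog["g"]


def test_no_start_codon_no_proteins():
    catalog = ev.call_genes({"g": "C" * 500})
    assert catalog["g"] == []


def test_short_orfs_filtered():
    protein = "M" + "AK" * 10  # 21 aa < 60
    catalog = ev.call_genes({"g": _encode(protein)})
    assert catalog["g"] == []


def test_reverse_strand_orf_recovered():
    from Bio.Seq import Seq

    protein = "M" + "LAK" * 25
    genome = str(Seq("AA" + _encode(protein) + "GG").reverse_complement())
    catalog = ev.call_genes({"g": genome})
    assert protein in catalog["g"]


def test_planted_community_proteins_recovered(community_small):
    catalog = ev.call_genes(community_small.phage_genomes)
    # every phage carries its tagged receptor-binding protein
    for phage, proteins in catalog.items():
        assert any(ev.RBP_TAG_PEPTIDE in p for p in proteins), phage


# ---------------------------------------------------------------------------
# protein alignment graph

def test_identical_proteins_linked():
    prot = "MADKLWNRGT" * 8
    g = ev.protein_alignment_pairs({"a": [prot], "b": [prot]})
    assert ("a|0", "b|0") in g.edges


def test_random_protein_pairs_rarely_linked():
    rng = np.random.default_rng(0)
    aa = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    prots = ["".join(aa[rng.integers(0, 20, 100)]) for _ in range(45)]
    g = ev.protein_alignment_pairs({f"g{i}": [p] for i, p in enumerate(prots)})
    n_pairs = 45 * 44 // 2
    assert len(g.edges) / n_pairs < 0.01


def test_planted_family_forms_clique():
    fam = "MHDKLWNRGTAC" * 7
    g = ev.protein_alignment_pairs({"a": [fam], "b": [fam], "c": [fam]})
    assert {("a|0", "b|0"), ("a|0", "c|0"), ("b|0", "c|0")} <= set(g.edges)


def test_pseudo_evalue_monotone_and_calibrated():
    es = [ev.protein_shared_kmer_evalue(s) for s in range(0, 12)]
    assert all(a > b for a, b in zip(es, es[1:]))
    assert ev.protein_shared_kmer_evalue(5) < ev.PROTEIN_LINK_EVALUE
    assert ev.protein_shared_kmer_evalue(2) > ev.PROTEIN_LINK_EVALUE


# ---------------------------------------------------------------------------
# CRISPR

def test_crispr_truth_pairs_recovered(community_small):
    records = ev.detect_crispr_matches(
        community_small.phage_genomes, community_small.host_genomes
    )
    found = {(r.entity_a, r.entity_b) for r in records}
    assert found == community_small.truth_interactions


def test_crispr_array_without_matching_spacer_yields_nothing():
    rng = np.random.default_rng(1)
    bases = np.array(list("ACGT"))
    mk = lambda n: "".join(bases[rng.integers(0, 4, n)])
    repeat, spacer = mk(25), mk(32)
    host = mk(2000) + repeat + spacer + repeat + mk(2000)
    assert ev.find_crispr_spacers(host) != []
    records = ev.detect_crispr_matches({"P0": mk(5000)}, {"H0": host})
    assert records == []


def test_spacer_matched_with_one_mismatch():
    rng = np.random.default_rng(2)
    bases = np.array(list("ACGT"))
    mk = lambda n: "".join(bases[rng.integers(0, 4, n)])
    repeat, spacer = mk(25), mk(32)
    host = mk(500) + repeat + spacer + repeat + mk(500)
    mutated = spacer[:10] + ("A" if spacer[10] != "A" else "C") + spacer[11:]
    phage = mk(1000) + mutated + mk(1000)
    records = ev.detect_crispr_matches({"P0": phage}, {"H0": host})
    assert [(r.entity_a, r.entity_b) for r in records] == [("P0", "H0")]


# ---------------------------------------------------------------------------
# RBP

def test_rbp_links_only_truth_pairs(community_small):
    catalog = ev.call_genes(community_small.phage_genomes)
    records = ev.detect_rbp_matches(
        community_small.phage_genomes, community_small.host_genomes, catalog
    )
    assert {(r.entity_a, r.entity_b) for r in records} == community_small.truth_interactions


def test_phage_without_rbp_yields_nothing(community_small):
    catalog = {p: [] for p in community_small.phage_genomes}
    records = ev.detect_rbp_matches(
        community_small.phage_genomes, community_small.host_genomes, catalog
    )
    assert records == []


# ---------------------------------------------------------------------------
# 16S

def test_16s_links_same_group_only(community_small):
    records = ev.detect_16s_links(community_small.host_genomes)
    got = {tuple(sorted((r.entity_a, r.entity_b))) for r in records}
    groups = {h: lin for h, lin in community_small.taxonomy.items()}
    hosts = sorted(community_small.host_genomes)
    expected = {
        (a, b)
        for i, a in enumerate(hosts)
        for b in hosts[i + 1 :]
        if groups[a] == groups[b]
    }
    assert got == expected


def test_host_without_marker_block_excluded():
    rng = np.random.default_rng(3)
    bases = np.array(list("ACGT"))
    plain = "".join(bases[rng.integers(0, 4, 2000)])
    assert ev.extract_16s_block(plain) is None
    assert ev.detect_16s_links({"H0": plain, "H1": plain}) == []


# ---------------------------------------------------------------------------
# nucleotide similarity

def test_suffix_automaton_matches_brute_force():
    rng = np.random.default_rng(4)
    bases = np.array(list("ACGT"))
    for _ in range(20):
        s = "".join(bases[rng.integers(0, 4, rng.integers(5, 60))])
        t = "".join(bases[rng.integers(0, 4, rng.integers(5, 60))])
        best = 0
        for i in range(len(s)):
            for j in range(i + 1, len(s) + 1):
                if s[i:j] in t:
                    best = max(best, j - i)
        assert ev.SuffixAutomaton(s).longest_common_substring(t) == best


def test_blastn_self_alignment_significant():
    rng = np.random.default_rng(5)
    bases = np.array(list("ACGT"))
    g = "".join(bases[rng.integers(0, 4, 2000)])
    records = ev.blastn_pairs({"a": g, "b": g})
    assert len(records) == 1 and records[0].value <= 1e-10


def test_blastn_planted_segment_below_threshold():
    rng = np.random.default_rng(6)
    bases = np.array(list("ACGT"))
    mk = lambda n: "".join(bases[rng.integers(0, 4, n)])
    segment = mk(500)
    rec = ev.blastn_pairs({"p": mk(3000) + segment}, {"h": segment + mk(3000)})
    assert len(rec) == 1 and rec[0].value < 1e-10


def test_random_genome_pairs_not_significant():
    rng = np.random.default_rng(7)
    bases = np.array(list("ACGT"))
    genomes = {f"g{i}": "".join(bases[rng.integers(0, 4, 20000)]) for i in range(15)}
    records = ev.blastn_pairs(genomes)  # 105 pairs
    assert all(r.value > 1e-10 for r in records)
    assert len(records) == 0  # nothing even reaches the reporting floor


# ---------------------------------------------------------------------------
# backends

def test_missing_external_tool_instructs_fallback(community_small):
    with pytest.raises(ev.ExternalToolError, match="fallback"):
        ev.detect_crispr_matches(
            community_small.phage_genomes, community_small.host_genomes,
            backend="external",
        )


def test_unknown_backend_rejected(community_small):
    with pytest.raises(ValueError):
        ev.call_genes(community_small.phage_genomes, backend="quantum")


def test_prodigal_adapter_runs(community_small):
    phage = dict(list(community_small.phage_genomes.items())[:1])
    catalog = ev.call_genes(phage, backend="external")
    assert set(catalog) >= set(phage)
    assert all(set(p) <= set("ACDEFGHIKLMNPQRSTVWYX*") for ps in catalog.values() for p in ps)


def test_blastn_adapter_agrees_on_planted_segment(community_small):
    pair = sorted(community_small.truth_interactions)[0]
    phage = {pair[0]: community_small.phage_genomes[pair[0]]}
    host = {pair[1]: community_small.host_genomes[pair[1]]}
    external = ev.blastn_pairs(phage, host, backend="external")
    fallback = ev.blastn_pairs(phage, host, backend="fallback")
    assert external and fallback
    assert external[0].value < 1e-10 and fallback[0].value < 1e-10


# ---------------------------------------------------------------------------
# channel-level soundness on a planted community

def test_channel_recall_and_spurious_rates(community_small, bundle_small):
    report = pipeline.evidence_recall_report(
        bundle_small.records(), community_small.planted_evidence
    )
    for channel, stats in report.items():
        if stats["planted"]:
            assert stats["recall"] >= 0.95, (channel, stats)
        assert stats["spurious_rate"] < 0.05, (channel, stats)
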