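import numpy as np
import pytest

from phagehostkg import evaluation, pipeline, training
from phagehostkg.synthetic import CommunitySpec, generate_community


@pytest.fixture(scope="session")
def community_small():
    """5 hosts x 6 phages with planted evidence in every channel."""
    return generate_community(CommunitySpec(n_hosts=5, n_phages=6, seed=7))


@pytest.fixture(scope="session")
def community_10x10():
    return generate_community(CommunitySpec(n_hosts=10, n_phages=10, seed=1))


@pytest.fixture(scope="session")
def bundle_small(community_small):
    return pipeline.extract_evidence(
        community_small.phage_genomes, community_small.host_genomes
    )


@pytest.fixture(scope="session")
def split_small(community_small):
    return evaluation.stratified_split(
        community_small.truth_interactions, community_small.taxonomy, frac=0.7, seed=3
    )


@pytest.fixture(scope="session")
def graph_small(community_small, bundle_small, split_small):
    train_pairs, test_pairs = split_small
    graph, report = pipeline.build_graph(
        community_small.phage_genomes,
        community_small.host_genomes,
        bundle_small,
        train_pairs,
        test_interactions=test_pairs,
    )
    return graph


@pytest.fixture(scope="session")
def tiny_graph():
    """Hand-built 5-node graph with random features (2 phages, 3 hosts)."""
    from phagehostkg.graph import PHKG
    from phagehostkg.kmer import FeatureMatrix

    phages = ["P0", "P1"]
    hosts = ["H0", "H1", "H2"]
    edges = {
        "pp": {("P0", "P1")},
        "hh": {("H0", "H1")},
        "ph": {("H0", "P0"), ("H2", "P1")},
    }
    rng = np.random.default_rng(0)
    X = rng.normal(size=(5, 6))
    feats = FeatureMatrix(phages + hosts, X, k=1)
    return PHKG(phages, hosts, edges, feats)
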