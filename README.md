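# phagehostkg

Predicting which prokaryote a bacteriophage infects, by link prediction on
a multimodal heterogeneous knowledge graph.

Host assignment is the bottleneck for interpreting uncultivated phages
from metagenomes: most sequenced phages have no known host. This package
implements a graph-based predictor for researchers in viral ecology and
microbiome analysis. It integrates five complementary similarity signals
between genomes — shared protein clusters, nucleotide-level alignment,
CRISPR spacer matches, receptor-binding-protein (RBP) homology and 16S
rRNA similarity — into one typed graph, learns node embeddings with a
graph attention network, and ranks candidate hosts for each phage.

## Model

**Graph.** Nodes are phages `p ∈ P` and hosts `h ∈ H` in `G = (V, E)`,
with three undirected edge types:

- phage–phage: `e(p_i, p_j) = 1` if `Q(N ≥ c) < τ₁` or BLASTN e-value `< τ₂`,
  where `Q(N ≥ c) = Σ_{i=c}^{min(x,y)} C(x,i)·C(n−x, y−i) / C(n,y)` is the
  hypergeometric tail probability that two phages share at least `c` of the
  `n` retained protein clusters (clusters from Markov Clustering of the
  protein alignment graph; singletons discarded);
- host–host: `e(h_i, h_j) = 1` if a 16S rRNA alignment exists or BLASTN
  e-value `< τ₂`;
- phage–host: `e(p_i, h_j) = 1` if a CRISPR spacer match, an RBP match, a
  nucleotide alignment below `τ₂`, or a known interaction from the
  *training* split exists.

Defaults `τ₁ = 1e−5`, `τ₂ = 1e−10`. Test-split interactions never become
edges (the construction is transductive: test phages contribute features
and sequence-derived edges only).

**Encoder.** Node features are forward-strand 4-mer frequency vectors
(256 dims, rows sum to 1). A two-layer, edge-type-aware GATv2 updates node
`i` per layer `k`:

    f_i^{k+1} = ELU( (1/M) Σ_m Σ_ω Σ_{j∈N_ω^i} α_ij^m W_ω^k f_j^k )

with `ω ∈ {pp, hh, ph}` (weights shared per edge type), `M = 4` heads
(averaged), self-inclusive neighborhoods `N_ω^i`, and GATv2 attention
`e_ij = a_ω^k · LeakyReLU(W_ω^k [f_i ‖ f_j])`, `α_ij = softmax_j(e_ij)`.

**Decoder and loss.** Interaction likelihood is the inner product
`Q_ph = f_pᵀ f_h`. Training minimizes the Bayesian Personalized Ranking
loss `−Σ ln σ(Q̂_ph − Q̂_ps)` with one uniformly sampled non-adjacent
negative host `s` per observed pair, optimized full-batch with Adam. The
encoder, backpropagation and optimizer are implemented in NumPy.

**Evaluation.** For each test phage all hosts are ranked; `hit@k` is the
fraction of phages whose true-host set meets the top-k predictions, and
taxonomic accuracy asks whether the top-1 host matches a true host at a
given rank (phylum … species). The train/test split is phage-level,
stratified 70/30 by host species.

Because full-scale training corpora (a Virus-Host DB-style interaction
table plus tens of thousands of RefSeq prokaryote genomes, and the
external alignment stack) are not shipped, the package includes a first-class synthetic-community
generator that plants recoverable signal in every evidence channel, and
built-in fallback detectors for all five channels. Adapters for the
external tools (prodigal, blastn, and tabular alignment output of the
others) are provided for real-data use.

## Worked example

```
$ phagehostkg simulate --hosts 10 --phages 20 --seed 1 --out work/fix
$ phagehostkg extract-evidence --phage-fasta work/fix/phages.fasta \
      --host-fasta work/fix/hosts.fasta --out work/evidence
$ phagehostkg build-graph --phage-fasta work/fix/phages.fasta \
      --host-fasta work/fix/hosts.fasta --evidence-dir work/evidence \
      --interactions work/fix/interactions.tsv --taxonomy work/fix/taxonomy.tsv \
      --seed 1 --out work/graph
$ phagehostkg train --graph-dir work/graph --seed 0 --out work/model
$ phagehostkg predict --graph-dir work/graph \
      --checkpoint work/model/checkpoint_0.npz \
      --checkpoint work/model/checkpoint_1.npz \
      --checkpoint work/model/checkpoint_2.npz --out work/predictions.tsv
$ phagehostkg evaluate --predictions work/predictions.tsv \
      --truth work/graph/test_interactions.tsv \
      --taxonomy work/fix/taxonomy.tsv --out work/metrics.json
```

On this 20-phage × 10-host community the build report shows every
training interaction plus the sequence-evidence edges
(`"edge_counts": {"pp": 0, "hh": 12, "ph": 33}`), and `metrics.json`
contains, for the 5 held-out test phages,

```
"hit_at_k": {"1": 1.0, "2": 1.0, ...},
"accuracy_by_level": {"order": 1.0, ..., "species": 1.0}
```

i.e. the top-ranked host is the true host for every held-out phage —
against a 0.1 uniform-random baseline — because the planted CRISPR/RBP/
prophage evidence gives each test phage informative graph edges and the
composition-matched 4-mer features identify the host among its relatives.

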