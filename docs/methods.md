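# Methods

## The prediction problem

Given phage genomes, prokaryote genomes, and a partial table of known
phage–host interactions, rank all candidate hosts for each phage. The
package treats this as link prediction on a heterogeneous knowledge graph
whose three edge types (phage–phage, host–host, phage–host) encode
complementary biological evidence, and whose node features are genome
composition signatures.

## Graph construction

Evidence enters as typed pairwise records and is thresholded into binary
edges with OR-semantics and strict inequalities:

| edge type | fires when |
|---|---|
| pp | shared-cluster tail `Q(N≥c) < τ₁` **or** nucleotide e-value `< τ₂` |
| hh | 16S rRNA link exists **or** nucleotide e-value `< τ₂` |
| ph | CRISPR spacer match **or** RBP match **or** e-value `< τ₂` **or** known *training* interaction |

`τ₁ = 1e−5`, `τ₂ = 1e−10` by default. Edges are unweighted and stored
canonically without self-loops; the encoder injects the self term. The
construction is transductive: test phages are graph nodes with features
and sequence-derived edges, but their interaction labels never become
edges — the builder has an explicit leakage guard that rejects any
training pair belonging to a declared test split.

**Shared protein clusters.** Phage proteins are aligned all-vs-all and
clustered with Markov Clustering (expansion 2, inflation 2.0, self-loop
weight 1, convergence tolerance 1e−6, max 100 iterations; clusters read
off as connected components of the thresholded converged matrix, labeled
by lowest-indexed member; singleton clusters are discarded). The chance of
two phages sharing at least `c` of the `n` retained clusters is the
hypergeometric tail `Q(N≥c) = Σ_{i=c}^{min(x,y)} C(x,i)·C(n−x,y−i)/C(n,y)`,
summed in log space (`gammaln`) for numerical safety; impossible terms
contribute nothing. The symbols `x, y` are read as the number of distinct
retained clusters each phage touches (clamped to `n`): reading them as raw
protein counts breaks the support of the distribution (`x, y ≤ n` can
fail). The literal protein-count reading remains available via
`phage_pair_stats(..., xy_mode="proteins")`.

## Evidence backends

Every channel has an `external` adapter (prodigal for gene calling,
blastn for nucleotide similarity, tabular outfmt-6 input for aligners;
CRISPR/RBP/16S external tools raise an instructive error when not
installed) and a deterministic built-in `fallback` detector with an
explicit contract:

- **genes** — all ORFs of ≥ 60 codons (any in-frame ATG to the next
  in-frame stop, six frames), standard-code translation; emitting every
  ATG guarantees a planted CDS is recovered verbatim;
- **protein links** — count of shared distinct 7-mer peptides, mapped
  through the monotone pseudo-e-value `10^(2 − 1.5·s)`; five shared
  7-mers cross the 1e−5 link threshold, which unrelated proteins
  essentially never reach;
- **CRISPR** — arrays found as ≥ 2 copies of a 20–40 bp direct repeat
  separated by 20–50 bp spacers; a spacer links a phage when it matches
  with ≤ 1 mismatch over ≥ 95% of its length (edlib);
- **RBP** — proteins carrying the fixed tag peptide are treated as
  receptor-binding proteins; a link requires an exact translated match of
  ≥ 25 aa in a host six-frame translation;
- **16S** — a sentinel-anchored 420 bp marker block; two hosts link at
  ≥ 97% full-length identity (the conventional species-level bound);
- **nucleotide** — longest exact shared substring via a suffix automaton,
  mapped through `e(L) = 10^(3 − L/20)`; calibrated so a ≥ 500 bp shared
  segment scores below 1e−10 while the ~25 bp chance LCS of unrelated
  50 kb genomes stays above 1e−3; pairs above a 1e−4 reporting floor are
  not emitted at all.

Pseudo-e-values are an internal convention: only the thresholded edge
decisions are meant to mirror the external-tool path, never the numbers.

## Node features

Forward-strand 4-mer frequencies (256 columns in lexicographic A<C<G<T
order), one row per genome; windows containing ambiguity codes are
skipped, multi-contig genomes pool per-contig counts without junction
windows, and rows sum to one. No reverse-complement canonicalization and
no log transform — the raw frequency spectrum keeps the feature
definition auditable.

## Encoder, decoder, training

Two GATv2 layers (256 → 64 → 32) with M = 4 heads and per-edge-type
weights; per layer, node `i` aggregates attention-weighted messages
`W_ω f_j` over each self-inclusive typed neighborhood, sums over the edge
types it participates in (phages: pp + ph; hosts: hh + ph — the
per-relation hidden states whose sum is the node embedding), averages
heads and applies ELU. Attention uses the GATv2 ordering
`e_ij = a·LeakyReLU(W[f_i‖f_j])` (slope 0.2), softmax-normalized with
max-subtraction; the message transform is the neighbor-side block of `W`.
The decoder is the inner product of final-layer embeddings.

Training minimizes the BPR loss `−Σ ln σ(Q̂_ph − Q̂_ps)` (stable softplus
form) over all training pairs full-batch, one uniformly drawn
non-ph-adjacent negative per positive, resampled each epoch, with Adam
(lr 1e−3) for 500 epochs. Forward, backward and optimizer are NumPy; the
analytic gradients are validated against numerical differentiation in the
test suite (agreement within 1e−4 relative error).

Choices that mattered at small scale, all fixed after ablation on a
four-seed design grid and kept as package defaults:

- **Input standardization.** Frequency rows share a dominant mean
  component that swamps the inner-product decoder; features are
  affine-standardized per column (fitted on all nodes — transductive —
  and stored in the checkpoint so prediction preprocesses identically).
- **Dropout 0.3** on layer inputs and attention coefficients during
  training, the GAT-family convention. Without it the model memorizes
  small training sets through feature idiosyncrasies instead of using
  graph structure.
- **Capacity.** 256→64→32 rather than wider layers; with tens of training
  pairs, wider models fit the loss to zero without generalizing.
- **Early stopping** on validation hit@1 (10% of training positives,
  patience 50) activates only when the validation slice has ≥ 5 pairs;
  below that the signal is noise and the model trains the full budget on
  all positives. Validation pairs always remain graph edges.
- **Restart ensemble.** Default prediction averages per-phage z-scored
  decoder scores of 3 independently initialized models — the same
  variance-damping argument as head averaging, applied across restarts.
  Single-model prediction remains available.
- Glorot-uniform initialization from an explicit seed; every random draw
  (init, negatives, dropout, splits) derives from one configured seed, so
  runs are bit-reproducible.

Degenerate inputs: a phage adjacent to every host has no negative and is
an error; a NaN/Inf loss aborts with diagnostics; nodes without edges of
some type aggregate only their self term for that type.

## Evaluation

Hosts are ranked by descending decoder score with ties broken by
ascending accession. `hit@k` counts a phage when its true-host set meets
the top-k. Taxonomic accuracy at rank L counts the top-1 host when its
taxon at L equals that of *any* true host (multi-host phages); an
`unknown` rank never matches. With one prediction per phage over all
candidate hosts, precision and recall coincide with accuracy, and hit@1
equals top-1 accuracy for single-host phages. The 70/30 split operates on
phages (all interactions of a phage travel together), stratified by host
species; classes of one or two phages go wholly to one side by simple
random draw.

## What the synthetic communities emulate — and what they don't

The generator plants, by construction: identical 16S marker blocks within
a host group; per-true-pair prophage-like shared segments (800 bp ≥ the
500 bp the nucleotide channel is calibrated for); phage-derived CRISPR
spacers copied into host arrays between fixed 25 bp direct repeats; a
tagged RBP coding block copied into each true host; and protein families
drawn from a shared pool. Background DNA follows a hierarchical base
composition (group-level Dirichlet α=12, per-host log-normal jitter
σ=0.10, phage composition matched to its primary host with σ=0.03),
emulating species-specific oligonucleotide signatures and phage–host
composition amelioration — the properties that make 4-mer features
informative on real genomes. The planted-evidence ledger enumerates every
implied sharing (including secondary ones such as identical family CDSs
between phages), so detector output is audited for ≥ 95% recall and < 5%
spurious records.

Not emulated: codon usage and gene structure beyond planted CDSs,
mutation and divergence (planted blocks are identical copies, so
detectors run at effectively infinite signal-to-noise), rearrangements,
contamination and incomplete assemblies, and the scale and class
imbalance of real interaction tables. Passing the recovery benchmark
therefore shows the pipeline is wired correctly and can exploit both
evidence edges and composition features; it does not certify accuracy on
real data, where every channel is noisier.

## Benchmark problem sizes

The recovery benchmark uses 20 phages × 10 hosts (3 host groups, ~33
interactions, 70/30 split) — large enough that held-out ranking is
non-trivial (10 candidate hosts, 0.1 random hit@1 baseline) and small
enough for exhaustive auditing of every planted signal. The exact
hypergeometric oracle enumerates all `(c, x, y, n)` with `n ≤ 30` in
rational arithmetic. Gradient checks run on a 5-node graph where
numerical differentiation is exact to first order.

## Known limitations

- The NumPy encoder is dense and desk-scale; thousands of nodes are fine,
  the 36k-genome regime of full host databases is not its target.
- Fallback detectors key on planted conventions (sentinel motif, RBP tag)
  and are not general annotation tools; real-data use should go through
  the external adapters.
- MCL is dense-matrix; protein graphs beyond ~10⁴ proteins need an
  external clusterer.
- Pseudo-e-values are ordinal stand-ins, not alignment statistics.
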