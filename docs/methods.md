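# Methods

## Problem setting

Datasets that mix full-length sequences with fragments (reads, contigs,
partially assembled genes) are hard to align: fragments distort guide
trees, dilute profiles, and attract spurious gaps.  `fragalign` implements
the two-stage strategy for this regime: (1) align a *backbone* of
full-length sequences with a divide-and-conquer aligner whose subset
alignments are merged through a weighted column graph, and (2) add every
remaining sequence by aligning it to an *ensemble of profile HMMs* built
from nested sub-alignments of the backbone.  Stage 2 never rewrites stage
1's columns, so backbone quality is preserved by construction — the
package asserts this contract on every run.

## Stage 1: backbone alignment

**Guide tree.** Pairwise distances are 1 − cosine similarity of k-mer
count vectors (default k = 8), fed to neighbor joining (scikit-bio).
Additive matrices are recovered exactly; beyond that the tree only steers
the merge order, and experiments with alternative tree sources changed
alignment error very little.

**Decomposition.** The guide tree is split recursively at its centroid
edge (the edge whose removal most nearly halves the leaves; ties go to
the first such edge in preorder) until every component has at most
`max_subset_size` leaves (default 50).

**Progressive subset alignment.** Each subset is aligned progressively up
its own NJ tree by profile–profile dynamic programming.  Columns are
represented by residue frequency vectors plus an occupancy (non-gap
fraction).  The column-pair score is the expected per-sequence-pair
score: `match` (+2) / `mismatch` (−1) over residue pairs and `gap_extend`
(−2) for residue–gap pairs.  Crucially, the cost of aligning a column
against a *new* gap also scales with that column's occupancy
(`gap_extend × occupancy`, plus a constant opening surcharge of −2, i.e.
a classic gap-open of −4 for ungapped sequences).  With a constant gap
cost instead, the penalty becomes negligible as profiles grow and the DP
objective detaches from the sum-of-pairs score it is meant to optimize —
in our development experiments that mismatch produced over-split columns
and roughly 1.7× higher alignment error, and made tree-partition
refinement *increase* error while "improving" the objective.  With the
occupancy-scaled costs the objective is consistent; refinement still did
not improve accuracy, so the package performs a single progressive pass.

**Graph merge.** Disjoint subset alignments are merged without
re-aligning them:

1. *Support alignments*: `support_count` (3) alignments, each built from
   `support_sample_size` (10) sequences sampled from every subset and
   aligned from scratch.  Their columns relate columns of different
   subsets.
2. *Alignment graph*: nodes are (subset, column) pairs; each support
   column adds 1 to the edge weight of every cross-subset residue pair it
   contains.  Same-subset columns are never adjacent.
3. *Markov clustering*: self-loops are set to each node's maximum
   incident weight; columns are normalized to a stochastic matrix;
   expansion (matrix squaring) alternates with inflation (entrywise power
   2.0, renormalization) until the matrix stabilizes (max entry change
   < 1e-8, at most 100 iterations; entries below 1e-12 are pruned to keep
   the matrix sparse).  Clusters are the connected components of the
   converged matrix's support (threshold 1e-6).
4. *Legality and ordering*: a cluster keeps at most one column per subset
   (the one with the highest total intra-cluster edge weight stays; ties
   keep the lower column index).  The precedence digraph induced by the
   subsets' column orders must be acyclic; while a cycle exists, the
   weakest-attached column in a multi-column cluster on the cycle is
   evicted to a singleton.  A topological sort with a deterministic
   tie-break (smallest (subset, column) member) fixes the output column
   order; each cluster becomes one merged column.

Because each output column holds at most one column per subset and subset
column order is preserved, restricting the merged alignment to one
subset's rows and dropping all-gap columns reproduces that subset's
alignment exactly; this is asserted after every merge.

## Stage 2: ensemble-of-HMMs placement

**Backbone tree.** NJ on pairwise p-distances of the backbone alignment
(sites where both rows hold residues; pairs with no comparable sites get
the maximum observed distance).  This replaces a maximum-likelihood tree;
the tree only guides the decomposition, where this substitution has
little effect on alignment error.

**Ensemble.** The backbone tree is decomposed by recursive centroid-edge
splits, retaining every intermediate subset, down to `min_subset_size`
(10) leaves.  A query can therefore match a broad shallow model or a
narrow deep one.

**Profile HMMs.** Standard match/insert/delete architecture over
{A,C,G,T}.  Match columns are those with gap fraction ≤ 0.5 (inclusive).
Match emissions are add-1 (pseudocount) smoothed column counts; insert
emissions are the uniform background; transitions are counted from each
training row's observed state path and smoothed with the same pseudocount
over the legal successor set (the full M/I/D × M/I/D topology, with no
delete state past the last match state).  Each HMM carries a map from
match state to backbone column.

**Assignment and placement.** Each query is scored against every ensemble
member by Viterbi decoding in log-odds form: log2 P(path, query | HMM) −
log2 P(query | uniform null).  No length-dependent bit-score adjustment
is applied; plain log-odds decides (a deliberate simplification —
see Limitations).  Ties go to the earlier member in the (size-descending,
then smallest-id) ensemble order.  The winning path maps match-state
residues to backbone columns; insert-state residues are anchored after
the preceding match column.  The transitive merge writes backbone columns
verbatim and gives every query's insertion run its own fresh columns —
insertions of different queries at the same anchor are *not* aligned to
each other, because an insert state asserts no homology.  Insertion
columns are flagged and written lowercase; evaluation excludes them from
homology pairs on both the reference and the estimated side.

## Fragmentation simulator

Fragmentation operates on a reference alignment so the truth survives:
`floor(n × fraction)` rows are chosen uniformly without replacement, and
each is masked down to a contiguous ungapped window whose length is drawn
from Normal(`length_ratio` × median length, sd 60), rounded, redrawn
while outside [1, source length).  The two standard conditions are HF
(fraction 0.5, ratio 0.25) and LF (fraction 0.25, ratio 0.5).  The start
position is uniform over valid starts (fragments model reads/contigs, so
contiguity is assumed).  Columns left all-gap are dropped.  The floor
rounding and both condition definitions reproduce the published fragment
counts for all reference dataset sizes (225/450 of 901, 69/139 of 278,
250/500 of 1000, 5000 of 10 000, 3161 of 6323, 3675 of 7350, 13 821 of
27 643).

## Benchmark simulator

`simdata` evolves sequences down a Yule (pure-birth, rate 1) tree from a
uniform random root: Jukes–Cantor substitutions (per-site change
probability `0.75·(1 − exp(−4/3·r·t))`), Poisson indel events (rate ×
branch length × sequence length) with geometric lengths (mean 3) and
uniform positions, insertion/deletion equally likely.  Homology is
tracked through global column bookkeeping, so the true alignment is exact
by construction.  Defaults for the benchmark study are 200 taxa, root
length 300, substitution rate 0.05 and indel rate 0.01 per site per unit
branch length — chosen to give an average p-distance near 0.32 and ~75%
gaps in the true alignment, matching moderately heterogeneous ribosomal
RNA reference datasets (e.g. ~0.36 average p-distance, ~78% gaps).  What
the simulator does *not* model: rate heterogeneity across sites,
structure-driven selection (rRNA stems/loops), sequencing error in
fragments, and GTR-style unequal base exchange rates.  Passing tests
therefore show the pipeline's behavior under a clean indel+substitution
process, not performance on real rRNA data.

## Evaluation

An alignment is its set of homologous residue pairs (two residues are
homologous iff they share a non-insertion column).  SPFN is the fraction
of reference pairs missing from the estimate, SPFP the fraction of
estimated pairs absent from the reference; the average error is their
mean.  Both are computed by column-wise counting, which the test suite
verifies against an explicit brute-force pair-set oracle; the duality
spfn(a, b) = spfp(b, a) is also tested.  p-distance ignores columns
where either row is gapped.  For very large alignments the dataset
statistics can p-distance-sample a seeded subset of row pairs.

## Determinism and numerics

One global seed derives per-stage seeds by SHA-256 of "seed:stage-name"
(all below 2^31); every subcommand is byte-reproducible from its
manifest.  DP tracebacks break ties deterministically (match state first)
and compare scores with a 1e-6 slack to absorb floating-point association
differences between the vectorized forward pass and the stepwise
traceback.  MCL stochastic columns are renormalized after every
inflation; degenerate inputs (single sequence, two taxa, subsets of one)
take explicit shortcut paths.

## Known limitations

- The progressive aligner is a single-pass profile method; it is the
  accuracy bottleneck on highly divergent backbones (no consistency
  scoring, no iterative refinement).
- Plain log-odds Viterbi scores are compared across HMMs of different
  lengths without the bit-score adjustment used by mature ensemble
  placement tools; very short queries can prefer small models.
- Protein alphabets, FASTQ/SAM inputs, and external aligner/HMM binaries
  are out of scope; 'U' is normalized to 'T' so RNA and DNA share one
  alphabet.
- The fragmentation model draws no sequencing errors; fragments are exact
  substrings.
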