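# Methods

`modprio` ranks candidate genes for diseases on a heterogeneous network of
gene–gene interactions (a protein–protein interaction network read as a gene
graph), disease–gene associations, and protein complexes used as module
annotations. The pipeline has five stages: graph augmentation, walk-based
embedding, candidate generation, graph-neural refinement, and re-ranking.
This note records the model, the numerical choices, and what the synthetic
test-bench does and does not establish.

## Graph augmentation on the L3 principle

Interactomes are incomplete, and missing interactions weaken every
downstream step. Triadic closure (length-2 paths) is a poor predictor for
protein binding because interaction requires complementary, not similar,
interfaces; proteins connected by many length-3 paths are the better
candidates. For a candidate pair (x, y) with binary adjacency a and degrees
k, three scores are computed:

    CN(x,y) = Σ_{u,v} a_xu a_uv a_vy
    RA(x,y) = Σ_{u,v} a_xu a_uv a_vy (1/k_u + 1/k_v)
    AA(x,y) = Σ_{u,v} a_xu a_uv a_vy (1/log k_u + 1/log k_v)

For every source node x the top `l` positive-scoring non-neighbors under
each variant are selected and x is joined to the union of the three sets.
All scores are computed once on the input graph (a single pass); the default
depth is `l = 10`.

Numerical and convention choices:

- **Log base in AA.** Natural log, the Adamic–Adar convention; configurable.
  A degree-1 intermediate cannot sit inside an L3 path, so the guard for
  k ≤ 1 (where 1/log k is undefined or infinite) contributes 0 and is purely
  defensive.
- **Tie-break at rank l.** Score descending, then lexicographic node id.
  Scores are compared after rounding to 9 decimal places: accumulated
  floating-point sums can differ from their mathematically equal
  counterparts in the last bits depending on summation order, and the
  rounding makes exact ties land on the deterministic id-order branch.
- **Zero scores never qualify.** If fewer than l candidates have positive
  score, the selection is short; an edge with no path evidence would be
  noise by construction.
- Scoring uses sparse two-hop frontier expansion from each source; the test
  suite checks it against a dense tensor-contraction oracle on random
  graphs.

## Heterogeneous module network

Nodes are diseases V_d and genes V_g (disjoint namespaces; a shared id is a
hard error); edges are associations E_dg and interactions E_gg. Modules are
named gene sets riding alongside the graph. Genes that appear only in
associations or complexes are kept as isolated gene nodes — dropping them
would silently shrink the label space.

## Walk embedding with module substitution

Second-order biased random walks (the node2vec scheme) start from every
node: unnormalized transition weights are 1/p to return to the previous
node, 1 to a common neighbor, and 1/q to an outward node. Defaults follow
the full-scale configuration: 10 walks per node, walk length 64, window 5,
in–out parameter q = 0.3, embedding size 128, 10 skip-gram epochs. The
return parameter p is not part of that configuration and defaults to 1.

Each node walk has a parallel module walk in which every gene token that
belongs to a complex is replaced by its module id. A gene in several
complexes is assigned once, before walking, to its lexicographically
smallest module id, so the module corpus is deterministic (a seeded
per-occurrence choice is available). Two independent skip-gram models embed
the two corpora; a gene takes its module's vector as its module embedding,
and any node without a module (all diseases included) reuses its node
embedding — so H⁰ = [node ‖ module] always has dimension 2·d.

The skip-gram trainer is a compact SGNS implementation: 5 negatives from
the unigram^0.75 distribution, linearly decaying SGD, fixed symmetric
window, no frequent-word subsampling (walk corpora over networks this size
have no stopword-like extremes). Updates are applied in vectorized
minibatches (default 256 pairs); the accumulated gradient of each token is
divided by its occurrence count in the batch, because summed stale updates
for hub tokens grow multiplicatively and diverge. Determinism follows from
the single-threaded seeded generator.

Candidate generation computes the cosine between each disease's node vector
and every gene's node vector, excludes the disease's training genes, and
keeps the top k (default k = 100, a value that has to be chosen here; it is
not part of the published configuration). Prediction later scores *only*
these pairs — the candidate step is what keeps scoring complexity linear in
the number of diseases.

## Graph neural network

One multi-head graph-attention layer runs over the full heterogeneous edge
set; from its output, two degree-normalized graph-convolution layers run on
the gene–gene subgraph in parallel with two GraphSAGE (mean-aggregator)
layers on the disease–gene subgraph, and the branches are aggregated.

    GAT   e_ij = LeakyReLU(a^T[W H_i ‖ W H_j]),  α_ij = softmax_j(e_ij)
          H_i' = Σ_j α_ij W H_j                  (2 heads, averaged)
    GCN   H_i' = ReLU(Σ_j H_j W / (√|N_j| √|N_i|) + b)
    SAGE  H_i' = ReLU(W [H_i ‖ mean_{j∈N_i'} H_j])

Interpretation and defaults, where the printed configuration
(GAT "(256, 128)" with 2 heads and one layer; branch widths "(128, 64, 8)")
leaves room:

- **GAT widths.** "(256, 128)" is read as attention-input width 256 and
  layer output width 128: with per-head output F = 128 the attention vector
  a acts on the 2F = 256-dimensional concatenation [W H_i ‖ W H_j]. Heads
  are averaged, so the single attention layer outputs 128 features, which is
  exactly the branch input width — no extra projection matrix is needed.
- **Branch widths.** "(128, 64, 8)" for "two layers" is read as
  input 128 → 64 → 8 for both branches.
- **Branch aggregation.** Elementwise sum, keeping the printed output width
  (8). The GCN branch is defined on gene nodes only (its equations involve
  gene–gene degrees); disease nodes therefore receive the SAGE branch alone,
  i.e. a zero GCN contribution. A literal "pass through unchanged" for
  disease rows is dimensionally impossible once the branch narrows from 128
  to 8.
- **Output normalization.** The aggregated output is row-wise L2-normalized,
  the GraphSAGE convention. This matters twice: it keeps |H| commensurate
  with the walk embedding it is concatenated with at scoring time, and it
  prevents the vanishing-gradient attractor in which |H| grows freely while
  every cosine-based gradient shrinks as 1/|H|. Disable with
  `GnnConfig(normalize_output=False)`.
- **Isolated nodes.** In the attention layer they attend to themselves
  (α_ii = 1); an isolated node in a GCN layer outputs ReLU(b); a node with
  no association edges aggregates a zero vector in SAGE.
- **Sampling.** The SAGE neighbor fraction defaults to 1.0 (no published
  proportion); when below 1, ⌈fraction·|N_i|⌉ neighbors are drawn without
  replacement from a seeded generator.
- **Activations.** ReLU in GCN (stated) and SAGE (chosen for consistency);
  LeakyReLU slope 0.2 in attention scores (the usual default).
- The GCN update is implemented literally, without a self term;
  `gcn_self_loops=True` adds self-edges and counts them in the degrees.

All layers are built on a small reverse-mode automatic-differentiation
engine over numpy arrays (`modprio.autodiff`), whose every operation is
checked against central finite differences in the test suite.

## Training and prediction

A pair (d, g) is scored by the cosine of H̃ = [H ‖ H^node] — the GNN output
concatenated with the walk-based node embedding. Positives are the training
associations; negatives are sampled uniformly from unconnected disease–gene
pairs, p = 50 per positive at full scale, and **resampled every epoch** so
the model sees more of the large negative space. The loss is the margin
hinge max(0, 1 − y·ŷ) with margin 1. Negatives are labeled y = −1: a 0/1
encoding makes the hinge identically 1 for every negative pair and provides
no gradient, so the standard margin convention is used. Optimization is
full-batch Adam at the published learning rate 0.0009 for 10 epochs (full
scale); training aborts on a non-finite loss. At prediction time each
disease's candidate list — and nothing else — is re-scored with the trained
embeddings and sorted (score descending, id ascending).

## Evaluation

Top@i precision/recall/F1 macro-average over diseases that have at least
one true test gene and a non-empty prediction list; the precision
denominator is the actual |P_i(d)|, which can be smaller than i.
Association precision micro-averages hits at a per-disease cut
k_d = min(|T(d)|, 10). AUC is the rank statistic (ties one half) over all
scored candidate pairs labeled by held-out truth — the pair population must
be defined somehow, and "scored candidates" is the choice consistent with
the candidate-restricted prediction phase; it is configurable by passing
any (score, label) list to `auc`. Cross-validation splits associations (not
diseases) into seeded near-equal folds; each fold rebuilds the network from
the training associations only and may additionally be scored against an
external association set using the same predictions.

Ablation variants: `GNN` (no augmentation, no modules — the module corpus
is unused and H⁰ duplicates the node embedding to preserve dimensions),
`GNN-M` (modules only), `GNN*` (augmentation only), `GNN*-M` (the full
method).

## Synthetic test-bench

The generator plants the structure the method exploits: disjoint dense
modules (intra-module edge probability 0.6, sizes 8–15) on a degree-biased
background (each gene attaches to 2 partners with probability ∝ degree+1,
giving a heavy-tailed degree distribution), 20% of true edges hidden
uniformly at random (the augmentation-recoverable ground truth), and 20
diseases with 8 associations each, 80% drawn from one causal module per
disease, split 60/40 into train/held-out. Defaults: 200 genes, 10 modules.

What it does not emulate: overlapping complexes, noisy or spurious
interactions, disease–disease similarity structure, and the four-orders-of-
magnitude larger scale of curated association databases. Passing the
end-to-end test therefore shows the pipeline recovers planted
module-correlated signal under incomplete observation — not that it matches
any particular benchmark number on real data.

### Small-network profile

`PipelineConfig.small()` is the profile used by the tests and synthetic
studies, chosen as proportionate to a network of a few hundred nodes:
embedding size 32, walk length 20, GAT width 32, branch widths (16, 8),
30 training epochs, 10 negatives per positive. Full-batch training on a
small graph takes few gradient steps per epoch, hence the higher epoch
count than the full-scale configuration. `PipelineConfig.published()`
carries the full-scale values.

## Known limitations

- Full-batch training holds the whole graph in memory; there is no
  minibatching over subgraphs, so very large networks are out of reach.
- The skip-gram and GNN trainers are single-threaded by design (exact
  reproducibility over speed).
- Negative sampling enumerates the unconnected-pair pool; fine up to ~10⁶
  disease×gene combinations.
- The L3 augmentation treats the graph as unweighted; interaction
  confidence scores are ignored.
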