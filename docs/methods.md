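# Methods

## Model and procedure

`hetrank` treats circRNA–cancer and drug–cancer association prediction as
one problem on a tri-partite heterogeneous network: nodes are circRNAs,
drugs and cancers; edges fall into three undirected relation classes
(circRNA–cancer, drug–cancer, circRNA–drug). Only nodes incident to at
least one edge exist in the network. For a chosen query type (circRNA or
drug) the candidate set is the full Cartesian product of query nodes ×
cancers; observed associations are the positive class, everything else is
unobserved (not confirmed-negative — the usual open-world assumption of
association databases).

The pipeline has four stages.

**1. Sensitivity edges (optional).** circRNA–drug edges can be derived
from a circRNA-expression × sample matrix and a drug-response × sample
matrix: samples are split at the median circRNA expression, drug
responses of the low/high groups are compared with a two-sided Wilcoxon
rank-sum test (exact enumeration when both groups have ≤ 8 untied values,
normal approximation with tie correction otherwise), and p-values are
Benjamini–Hochberg adjusted across all tested (circRNA, drug) pairs; an
edge is emitted iff FDR < α (default 0.05). The median split and the
two-sided alternative are package choices — the upstream protocol this
mirrors states only that expression is correlated with sensitivity.

**2. Attribute features.** Each node type receives a Gaussian interaction
profile (GIP) kernel similarity matrix over its binary interaction
profiles, `K(i,j) = exp(−γ‖IP(i)−IP(j)‖²)`, `γ = 1 / mean_i‖IP(i)‖²`
(γ := 1 when all profiles are empty — similarity degenerates to 1, which
only happens for degenerate inputs). circRNAs profile against cancers,
drugs against cancers, and cancers against the task's query type; an
option concatenates every relation a type participates in. External
similarity sources (disease semantic, circRNA functional, drug chemical)
plug in as precomputed matrices and fuse with GIP by an element-wise mean
where defined; no ontology or fingerprint computation is built in. A
node's feature vector is its row of its type's fused matrix.

**3. Searched message-passing edge embeddings.** Node features are
linearly projected (no bias) to a common hidden width and refined by a
two-layer message-passing network. Per layer: neighbour messages
`W_neigh H_u` are aggregated by `∅_A ∈ {sum, max, mean}` (empty
neighbourhoods aggregate to the zero vector), combined with the node's
own transformed state by `∅_AC ∈ {sum, concat}` (the concat branch is
projected back to the hidden width), and activated by
`∅_C ∈ {ReLU, PReLU}` — combine-then-activate, since the activation is
unary. Consecutive layers are connected by
`∅_con ∈ {stack, skip_sum, skip_concat}` and layer outputs aggregated by
`∅_agg ∈ {last, concat, max, none}` (`none` aliases `last`). The edge
embedding of a candidate pair pools the two endpoint states with
`σ ∈ {sum, max, concat}` (query first for concat); pooling is over the
two endpoints only, not an enclosing subgraph. `W_neigh` is shared across
relation classes; only self vs. neighbour is distinguished.

Every named operation is a search decision. During search the discrete
choices are relaxed with Gumbel-softmax samples
`ε_o ∝ exp((log w_o − log(−log U_o))/τ)`; each decision's output is the
ε-weighted sum of its candidate branches, and branches whose natural
width differs (concat layer aggregation, concat pooling) are projected to
the common width by dedicated mixing maps that exist only to make the
relaxation well-typed — the final discrete model uses true concatenation.
Architecture log-weights and model weights are optimised jointly
(single-level, Adam, full-batch) on a link-prediction binary
cross-entropy: all observed task-relation edges against an equal-size
uniform sample of unobserved pairs drawn fresh each epoch, scored by a
linear head on the edge embedding. τ anneals linearly 1.0 → 0.1; the
relaxed loss is noisy by construction (near-one-hot sampling at low τ),
which is expected. Afterwards each decision is fixed by argmax and the
weights are retrained from scratch under the discrete architecture.

Two regularisers matter at small scale and are on by default:
edge dropout (each adjacency entry hidden with probability 0.25 per
epoch), which discourages the network from memorising observed links, and
the full-universe graph convention — when cross-validation masks edges,
profiles and message passing run over the *full* node set with
training-fold adjacency, so a node whose only task edges are held out
keeps a degree-0 slot and an informative feature row instead of vanishing.
Gradients come from a minimal reverse-mode autodiff tape on numpy
(`_tensor.py`), checked op-by-op against central finite differences.

**4. Learning to rank.** Candidate cancers are ranked per query by
LambdaMART: gradient-boosted regression trees fitted to LambdaRank
statistics — for each (relevant, non-relevant) pair within a query,
pairwise logistic gradients (steepness 1) weighted by the |ΔNDCG| of
swapping the pair (binary gain `2^label − 1`, discount `1/log2(rank+1)`,
full-list truncation) — with Newton-step leaf values, best-first leaf
growth, equal-frequency threshold candidates computed once before
boosting, and a minimum leaf support. All unobserved pairs of a query
enter its candidate list with label 0; there is no negative subsampling
at ranking time. Score ties are broken by candidate id. Datasets
round-trip exactly through the SVMlight/RankLib text dialect
(`<label> qid:<q> 1:<v1> ... # did=<d>`; full-precision floats).

## Tunable parameters

| parameter | default | notes |
|---|---|---|
| hidden width d | 64 | conventional GNN width; memory/CPU scale with d² |
| layers L | 2 | deeper stacks over-smooth on networks this small |
| search / train epochs | 150 / 200 | full-batch Adam, lr 0.01 |
| τ schedule | 1.0 → 0.1 linear | colder τ → closer to one-hot samples |
| edge dropout | 0.25 | 0 disables; higher starves sparse nodes |
| LambdaMART | 1000 trees, lr 0.1, 256 thresholds, min leaf 1, 10 leaves | ranker defaults |
| Wilcoxon α | 0.05 | FDR level for sensitivity edges |
| folds | 5 | both protocols; seeds are mandatory everywhere |

## Evaluation

AUC is the tie-corrected Mann–Whitney statistic; AUPR the step-integrated
precision–recall area; NDCG uses binary gain with the log2 discount and
returns 0 for queries with no relevant item; MRR and MAP are macro means
over queries. ROCk truncates each query's ranked list at rank k, builds
the ROC with TPR/FPR normalised by the query's total positives/negatives,
normalises the area by the best achievable area at that truncation
(queries where that maximum is zero contribute 0) and macro-averages;
with k ≥ list length it equals the per-query AUC. Headline AUC/AUPR are
pooled over all test pairs; macro (per-query) views are reported
alongside, plus a per-cancer AUC table with its median.

Two protocols: *novel-query* (queries partitioned into folds; train and
test query ids never intersect) and *known-query* (samples partitioned,
stratified per query so fold sizes within a query differ by ≤ 1; a
`stratify=False` switch restores plain random splitting). Masking removes
the test fold's observed query–cancer edges from feature computation and
training; cross-type edges are retained, which is what keeps novel
queries connected to the network.

## Synthetic data

The generator emulates the tri-partite association data the pipeline is
built for. Nodes belong to a small number of clusters whose centres are
axis-aligned and well separated (norm 1.5) in a rank-4 latent space —
separated centres are what makes the planted structure identifiable from
sparse binary profiles; isotropic random centres concentrate probability
in blocks that node popularity already explains. A pair's association
probability is a logistic function of the scaled inner product of its
endpoint factors, with the intercept calibrated per relation so the mean
probability hits the target density. Observed edges are Bernoulli draws;
a true association then goes *unobserved* with probability `noise`
(default 0.05) — one-sided dropout, the signature of annotation
incompleteness; symmetric label flipping would instead plant
perfectly-inverted false positives that no method (not even the
generating probabilities) could rank correctly. Isolated nodes are
re-wired by adding their highest-probability edge in their primary
relation.

Two presets: *desk* (60 circRNAs / 12 drugs / 15 cancers; densities
0.10 / 0.20 / 0.45 chosen to preserve the real data's expected positives
per query at the reduced candidate-set size) and *published-scale*
(407/24/46 nodes with exact edge counts 614/1197/523, sampled without
replacement by probability weight, with count-preserving re-wiring).
The ranking-data generator shifts relevant documents' first two feature
means by a separation parameter; at separation 5 a single threshold on
feature 1 ranks perfectly, at 0 the data are unrankable.

What the synthetic data do **not** emulate: ontology-structured disease
similarity, chemical-structure similarity, transcriptomic covariance,
database ascertainment bias, and the extreme degree skew of literature-
curated networks. Passing the synthetic suite therefore demonstrates
implementation correctness and end-to-end learnability under planted
structure — not performance on curated biological databases.

## Numerical choices and degenerate inputs

Gumbel uniforms are clipped to (1e-12, 1−1e-12); sigmoid/softplus inputs
to ±60. Elementwise-max gradients route to the first argument on ties;
neighbour-max gradients to the argmax entry. Tree split gains use an
ε = 1e-10 guard; leaves with zero Hessian mass get value 0. An empty tree
ensemble scores everything 0 and ranks by candidate id. Zero-variance
edge embeddings make Pearson similarity undefined and raise. Duplicate
edge rows collapse with a warning; self-loop rows are rejected.

## Design choices where the design was open

- The intra-layer cell applies combine before the unary activation.
- Layer-connect candidates are unified as {stack, skip_sum, skip_concat};
  layer-aggregation `none` aliases `last`.
- The GNN training loss (never pinned upstream) is link-prediction BCE
  with 1:1 resampled negatives and a linear scoring head; a dot-product
  head was evaluated and did not generalise better on the synthetic
  benchmark.
- Search is single-level joint optimisation (SNAS-style) rather than
  bilevel; the argmax architecture is retrained from scratch.
- Known-query splits are stratified per query by default to avoid empty
  test lists for small queries.
- Exact metric and similarity formulas not printed upstream (ROCk
  normalisation, GIP bandwidth convention, fusion rule) follow the field-
  standard definitions stated above so results are reproducible.

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` run the full pipeline on the
desk preset with one cross-validation fold per seed over three seeds
(default GNN and LambdaMART settings), LambdaMART on 30 training / 10
held-out queries of 40 documents, and oracle comparisons on instances of
up to 200 items. These sizes are the package's chosen benchmark scale.

## Known limitations

- At desk scale the supervision is extremely sparse (≈1.5 positives per
  query); measured against an idealised mixture of all observable
  information channels, held-out AUC around 0.8 is close to the
  information ceiling of those conditions, and per-seed variance is
  large. Macro NDCG/MRR/MAP are dominated by queries with no held-out
  positive (scored 0) and should be read against the degree baseline.
- The searched space covers the printed candidate sets only; no
  attention aggregators, no per-relation weight matrices, no more than
  two layers.
- Per-edge hidden states (an alternative reading of "explicit link
  information") are not maintained; edge embeddings are endpoint
  poolings.
- The LambdaMART implementation is CPU-oriented and unpruned (no
  early-stop validation split).
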