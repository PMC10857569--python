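# hetrank

Cancer-centred association ranking on a tri-partite heterogeneous network
of circRNAs, drugs and cancers.

Circular RNAs (circRNAs) are covalently closed transcripts whose expression
patterns track cancer progression, making them candidate biomarkers;
repositioning approved drugs against new cancer indications shortcuts the
cost of de-novo drug development. Both problems reduce to link prediction
on one network: given experimentally supported circRNA–cancer,
drug–cancer and circRNA–drug associations, rank the candidate cancers for
a query circRNA or drug. `hetrank` is aimed at computational biologists
who want a self-contained, CPU-scale implementation of this pipeline with
every stage testable against synthetic data.

## Method

1. **Network assembly** — three typed edge lists are merged into a graph
   `G = (V, E)` with node sets `R` (circRNAs), `D` (drugs), `C` (cancers)
   and three undirected relation classes; isolated nodes are pruned.
   circRNA–drug edges can also be derived from expression × drug-response
   matrices by a median-split two-sided Wilcoxon rank-sum test with
   Benjamini–Hochberg control (edge iff FDR < 0.05).
2. **Attribute features** — each node type gets a Gaussian interaction
   profile (GIP) kernel similarity matrix,
   `K(i,j) = exp(−γ‖IP(i)−IP(j)‖²)` with `γ = 1 / mean‖IP‖²`, optionally
   fused (element-wise mean) with an external similarity source; a node's
   feature vector is its row of the fused matrix.
3. **Edge embeddings** — a two-layer message-passing network computes
   `X_v = ∅_A({W_neigh H_u : u ∈ N(v)})`,
   `H_v = ∅_C(∅_AC(W_self H_v, X_v))`, with inter-layer connection
   `∅_con` and layer aggregation `∅_agg`, and pools the two endpoint
   states into an edge embedding `H_e = σ(H_query, H_cancer)`. Every
   operation (`∅_A ∈ {sum,max,mean}`, `∅_AC ∈ {sum,concat}`,
   `∅_C ∈ {ReLU,PReLU}`, `∅_con ∈ {stack,skip_sum,skip_concat}`,
   `∅_agg ∈ {last,concat,max,none}`, `σ ∈ {sum,max,concat}`) is chosen by
   stochastic differentiable architecture search: Gumbel-softmax samples
   `ε_o ∝ exp((log w_o − log(−log U_o))/τ)` relax the choices, the
   temperature `τ` anneals 1.0 → 0.1, and the argmax architecture is
   retrained from scratch.
4. **Ranking** — LambdaMART (gradient-boosted trees on LambdaRank
   gradients, |ΔNDCG|-weighted pairwise logistic λ, Newton leaf values)
   ranks each query's candidate cancers from the `[label, qid, features]`
   samples; datasets round-trip bit-exactly through the RankLib text
   dialect. Defaults: 1000 trees, learning rate 0.1, 256 threshold
   candidates, minimum leaf support 1.

Evaluation covers AUC, AUPR, NDCG, NDCG@k, MRR, MAP and ROCk (the ROC
area restricted to each query's top-k candidates), under two
cross-validation protocols: query-grouped folds for novel queries and
within-query stratified folds for known queries, with test edges masked
from feature computation and GNN training.

## Worked example

```sh
hetrank run-all --preset desk --scenario known --query-type circrna \
    --seed 201 --only-fold 0 --out metrics.json
```

generates a desk-scale synthetic network (60 circRNAs / 12 drugs /
15 cancers with planted cluster structure), runs the full pipeline on one
fold of the known-query protocol and prints:

```
{"AUC": 0.8286868686868687, "AUPR": 0.28215345129311514,
 "MAP": 0.2, "MRR": 0.20555555555555557,
 "NDCG": 0.20565735963827292, "NDCG@10": 0.20565735963827292}
```

AUC/AUPR are pooled over all held-out (query, cancer) pairs — 0.83 here
means observed test associations score well above unobserved ones. The
NDCG@10/MRR/MAP values are macro-averages over the 60 per-query ranked
lists; most queries have no held-out positive in a single fold (those
lists score 0 by convention), which is why the macro numbers sit far
below 1 even for a good ranker — compare them against the degree-baseline
values in `metrics.json` rather than against 1.

The same library surface is importable from Python (`hetrank.run_pipeline`,
`hetrank.search`, `hetrank.train_lambdamart`, ...).

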