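# Methods

## Scope and data model

`scgraphae` operates on a dense cells × genes matrix. Counts are filtered
(genes detected in < `min_cells_frac`·N cells removed first, then cells with
< `min_genes_per_cell` detected genes), library-size scaled to
`log(1 + c·x/libsize)` with c = 10,000 (natural log; zeros stay zero), and
reduced to the `n_top_genes` = 2,000 genes of largest standard deviation
(computed after the log transform by default; `rank_genes_before_log`
switches to raw-count sd). Filtering thresholds follow common scRNA-seq QC
practice (`min_cells_frac` = 0.01, `min_genes_per_cell` = 200) and are
configurable; ties in the sd ranking keep original file order so runs are
deterministic.

## LTMG: censored mixture as a loss weight

Each selected gene is modeled as a k-component Gaussian mixture in which
values at or below the truncation point Zcut (default 0 in log space, i.e.
observed zeros) are left-censored: they contribute the mixture mass
Σᵢ αᵢΦ((Zcut−μᵢ)/σᵢ) to the likelihood instead of a density. EM uses the
standard censored-data construction — censored responsibilities proportional
to component mass below Zcut, M-step moments from the left-truncated normal
— with quantile-spaced mean initialization, pooled-sd start, uniform
weights, tol 1e-6 on relative log-likelihood, 200 iterations max, and a σ
floor of 1e-3. This EM is exact, so the observed-data log-likelihood is
non-decreasing (a property the tests assert on every fixture gene). k is
chosen by BIC = −2·loglik + (3k−1)·log(M) over k = 1..5, M the number of
uncensored observations. Genes with no uncensored values get a flagged
degenerate single-component fit.

Each entry's TRS label is the argmax of αᵢφ(x; μᵢ, σᵢ), ties to the
lower-mean component. The loss weight derived from the labels is binary by
default (label > 1 → 1, else 0): the TRS term then counts reconstruction
error only where the gene is inferred "on". The raw integer label is
available as an alternative weighting (`trs_weight_mode="label"`); which
multiplier the loss intends is genuinely underdetermined, and the binary
reading is the conservative one.

## Cell graph

KNN with k = max(5, round(N/10)) (scales the neighborhood with dataset
size), Euclidean, OR-symmetrized, unweighted. Pruning removes, per node,
incident edges longer than the `prune_quantile` = 0.9 quantile of that
node's edge lengths; an edge survives if either endpoint keeps it, and a
node that would be isolated retains its single shortest edge. Normalization
is the symmetric D̃^(−1/2)(A+I)D̃^(−1/2) with self-loops added before the
degree — self-loops guarantee positive degrees and a spectral radius ≤ 1.
From the second round on, the propagation matrix is
Ã = μ·L₀ + (1−μ)·RowNorm(A) with μ = 0.5, L₀ the first round's normalized
pruned graph, and RowNorm the row-stochastic scaling of the current pruned
adjacency (zero rows fall back to uniform over their L₀ neighbors).

## Networks

All networks are NumPy MLPs/graph layers with hand-derived gradients and
full-batch Adam (lr 1e-3 everywhere; the graph encoder's gradient was
verified against finite differences to 1e-10). Defaults: feature and
imputation autoencoders G→512→128→512→G, ReLU hidden, linear output, 500
epochs; graph autoencoder →32→16, 200 epochs. Epoch counts are
conventional for this model family; the full-scale architecture is kept
even on small inputs.

Graph attention: per head, scores e_ij = (W h_i)·(W h_j) on the
self-loop-augmented neighborhood mask, row-softmaxed, and the head outputs
are averaged (not concatenated). K = 0 replaces attention by plain
propagation σ(ÃHW). Three numerical choices matter in practice and are
deliberate deviations from the most literal reading:

- the second (embedding) layer is linear, not ReLU: a nonnegative embedding
  feeding the sigmoid inner-product decoder cannot push non-edge logits
  below zero, and in practice the whole layer dies (loss pinned at log 2);
- encoder input features are z-scored per column, otherwise the decoder
  saturates at initialization and training collapses for most seeds;
- k-means runs on L2-row-normalized embeddings: an inner-product decoder
  encodes cluster identity as direction, and raw-magnitude k-means is
  unreliable for K ≥ 3 heads.

The GAE reconstruction target is the pruned adjacency with self-loops,
binarized; Â entries are clamped to [1e-7, 1−1e-7] inside the cross
entropy.

## Clustering and the outer iteration

The number of clusters comes from Louvain modularity (resolution 1.0,
igraph, seeded through Python's `random`) on the GAE's thresholded
reconstructed graph (Â > 0.5, diagonal cleared): that graph is dense within
cell types, so modularity does not over-split the way it does on KNN graphs
of tightly embedded clusters. Without the GAE, Louvain runs on the pruned
KNN graph. Communities smaller than `min_cluster_size` = 10 merge into the
nearest larger community by mean embedding distance. Cells are then
assigned by k-means (k-means++, n_init = 10, fixed seed) and labels are
canonicalized by descending cluster size, which makes identical partitions
serialize identically. B_ij = 1 iff labels match.

Each round: feature AE on the current input (round 1: the pretreated
matrix; later: the cluster-AE reconstruction) → KNN build + prune on the
feature embedding → propagation blend → GAE → Louvain k → k-means →
per-cluster AEs (clusters below `min_cluster_size` pass through
untrained). The iteration stops when the clustering result no longer
changes (consecutive-label ARI > 0.99) or the propagation matrix stabilizes
(relative Frobenius change < 1e-3), capped at `max_rounds` = 10 with a
warning. Requiring both simultaneously is not meaningful here: the graph is
rebuilt from freshly trained embeddings every round, so its Frobenius drift
stays O(0.1) even when the biology has stabilized. Building the KNN graph
from the graph-autoencoder embedding instead of the feature embedding is
available (`knn_on_gae_embedding`) but is not the default: that embedding
collapses each type to near-coincident points, making neighbor identity
arbitrary and the cluster count unstable.

The imputation autoencoder trains once, on the original pretreated matrix,
with the final pruned adjacency and B. The γ regularizers are read
per-cell: Σᵢⱼ Aᵢⱼ‖(X−X̂)ᵢ‖² (and likewise for B), which reduces to an
element-weighted squared error with row weight
(1−α) + α·TRS + γ₁·deg(A)ᵢ + γ₂·|cluster(i)|, so the weighted-MSE training
core is reused exactly; the alternative pairwise-smoothness reading
Σᵢⱼ Aᵢⱼ‖X̂ᵢ−X̂ⱼ‖² is implemented in `imputation_loss(graph_mode="pairwise")`
for comparison. The L1 term β·Σ|w| enters the gradient as β·sign(W).
Defaults α = β = 0.5, γ₁ = γ₂ = 0.1. The default output replaces only
observed zeros with reconstructed values; `--full-reconstruction` writes X̂
wholesale.

## Synthetic data

The generator plants `n_clusters` = 3 balanced clusters over
`n_cells` = 200 × `n_genes` = 300. Each gene has a baseline natural-log
mean uniform on [0.5, 2.5] (roughly 1.6–12 expected counts);
`de_frac` = 20% of genes per cluster are shifted by +1.5 log units. Counts
are gamma–Poisson (negative binomial) with dispersion 0.3; technical
dropout zeroes entries with probability sigmoid(dropout_mid −
dropout_slope·logμ) (defaults 0 and 1: ~38% dropout for the weakest genes,
~8% for the strongest), yielding ~20–25% total zeros. These sizes and rates
are a small but realistic regime for a droplet-protocol experiment with a
handful of well-separated cell types.

What the simulator does *not* emulate: library-size variation between
cells, batch effects, gene–gene correlation beyond the cluster means,
ambient RNA, or doublets. Passing the planted-structure tests therefore
shows the machinery recovers clean modular structure and beats an all-zero
baseline at masked-entry recovery; it does not certify performance on real
tissue.

## Evaluation metrics

All scores are computed from first principles and cross-checked in the test
suite against scikit-learn and brute-force pair/entropy counting on ≥100
random instances: ARI and Fowlkes–Mallows from the contingency table; MI,
NMI (mean-entropy normalization), AMI (hypergeometric expected MI),
homogeneity = 1 − H(true|pred)/H(true), completeness = 1 − H(pred|true)/H(pred),
V-measure their harmonic mean, with the usual score-1 conventions for
zero-entropy corners; silhouette (b−a)/max(a,b) with singletons scoring 0;
Davies–Bouldin as the mean worst (Sᵢ+Sⱼ)/Mᵢⱼ centroid ratio. Imputation
statistics are evaluated on exactly the masked entries (per-entry |x−y|
mean/median/max, RMSE, and per-cell cosine over masked positions; zero-norm
rows are skipped and an all-skipped comparison reports cosine 0). Row
vectors are per-cell by default; `axis="genes"` transposes.

## Problem sizes and schedules used by the tests

The acceptance tests and `scripts/acceptance.py` run the 200×300 study
dataset with a shortened training schedule (feature/imputation AEs 200–300
epochs, GAE 100 epochs) — the package's choice of problem size for its own
verification; architecture, graph parameters, and the simulation regime are
the defaults throughout. The ablation comparison (with/without GAE, 5
seeds; head counts 0/1/3/5/8) additionally caps the loop at 2 rounds. At
these sizes the full pipeline converges in 2 rounds in well under a
minute.

## Known limitations

- Dense N×N graphs and full-batch training cap practical size at a few
  thousand cells; there is no approximate-NN or minibatch path.
- Imputation quality is modest at high dropout (30%): the imputation loss
  still scores reconstruction of the zeros it is meant to fill, so recovery
  relies on the bottleneck's implicit low-rank bias; the method reliably
  beats the zero baseline but is far from oracle recovery.
- The censored EM fits each gene independently; no information is shared
  across genes.
- Louvain's resolution is fixed (1.0); the cluster count inherits its
  biases on graphs with nested structure.
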