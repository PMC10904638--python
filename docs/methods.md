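# Methods

## Model

`ddifusion` predicts drug–drug interactions transductively: every drug node
is present in the graphs at training time and only pair labels are held
out.  The model assumes (i) drugs that interact tend to be feature-similar,
so a cosine-KNN graph over node features adds plausible links the observed
DDI topology is missing; and (ii) the per-layer outputs of a GCN carry
complementary information — shallow layers local detail, deep layers
higher-order structure — so all layers are fused rather than only the last.

Forward path per view `y ∈ {adj, knn}`:

1. `Ã = D̂^{-1/2}(A + I)D̂^{-1/2}` with `D̂` the degree matrix of `A + I`.
   Adding self-loops before computing degrees keeps isolated nodes
   well-defined (degree ≥ 1) and matches standard GCN renormalization; a
   literal reading of the normalization with degrees of `A` alone would
   divide by zero on isolated nodes, so the self-loop form is used.
2. `Z^l = σ(Ã Z^{l-1} W^l)`, `Z^0 = X`, `σ = ReLU` (configurable); no
   dropout or batch norm inside the GCN.
3. Attention over scales: `Att_y = l2(softmax(LeakyReLU(linear(Ẑ_y))))`
   with `Ẑ_y = Z^1‖…‖Z^L`.  The softmax is across the L scales per node;
   the subsequent l2 step is a row-wise (per-node) normalization applied
   after the softmax, implemented literally in that order.  After l2 the
   factors no longer sum to 1; both stages are exposed
   (`AttentionFactors.softmax_factors` / `.factors`) and both are strictly
   positive.
4. `E_y = (a^1 ⊙ Z^1)‖…‖(a^L ⊙ Z^L)`; `E_drug = E_adj + E_knn`.  The two
   views share layer dimensions (required by the summation) but never
   parameters — separate weights subsume the shared case.
5. Pair combination: concatenation (2d), average (d) or Hadamard (d).
   Pairs are canonicalized lower-index-first so concatenation is invariant
   to pair orientation.
6. DNN head: hidden layers with batch normalization, ReLU and dropout 0.3,
   then sigmoid (binary) or softmax over R event types.

Losses are the summed binary/categorical cross-entropies (sums, not means,
over the batch; the per-sample mean is reported for logging).  Predictions
inside logs are clamped to `[1e-7, 1 - 1e-7]`.  The optimizer is Adam —
the DNN-alignment convention of the baseline family this protocol follows —
which is also insensitive to the sum-vs-mean loss scaling.

## Numerical implementation

The whole trainable path runs on an in-package reverse-mode autodiff tape
over numpy arrays (`ddifusion.autodiff`), so inference and gradients share
one implementation of each formula.  Composite layers (softmax, row-l2,
batch norm) are composed from primitives and inherit exact gradients;
correctness is pinned by central-finite-difference checks on a 10-drug toy
problem (relative tolerance 1e-4 at h = 1e-6) and by brute-force forward
oracles for every equation.  All arithmetic is float64.  Weight
initialization is fan-based uniform (Glorot-style) from the run's seeded
generator; one `numpy` generator per training run drives initialization,
shuffling, dropout and negative sampling, so identical config + seed gives
bit-identical loss histories and metrics documents.

Batch normalization uses batch statistics in training and exponential
running averages (momentum 0.9) at inference.  KNN rank ties are broken by
lowest node index; `k ≥ n` clamps to `n - 1` with a warning.  Zero-norm
feature rows and empty descriptor sets have similarity 0 to everything
(0/0 is defined as "no evidence of similarity").

## Defaults and presets

| Parameter | Default | Why |
|---|---|---|
| GCN depth L | 3 | deeper stacks over-smooth; 3 is the sweet spot the protocol targets |
| layer dims | (256, 128, 64, 32, 16)[:L] | decreasing widths, high-detail shallow scales |
| KNN k | 10 | beyond ~10 neighbors, low-similarity links add noise |
| LeakyReLU slope | 0.2 | common default (unspecified upstream) |
| DNN hidden | (512, 256), dropout 0.3 | benchmark-scale head |
| binary threshold | 0.5 | standard |
| ε in logs | 1e-7 | numerical necessity |

Named presets carry the published protocol settings: `ddimdl-multiclass`
(batch 1000, 100 epochs, lr 1e-3), `deepddi-multiclass` (512, 50, 1e-3),
`ddimdl-binary`/`deepddi-binary` (1000, 50, 1e-4).  The `synthetic-*`
presets are sized proportionately for the bundled generator's 200-drug
graphs: GCN dims (64, 32, 16), DNN hidden (64, 32), Hadamard combination,
full-batch Adam at lr 5e-3 for 40 epochs.  These sizes were fixed once as
reasonable for a 200-node problem; desk-scale runs finish in minutes on one
CPU.

## Evaluation protocol

The CV unit is the labeled pair (cold-start drug splits are out of scope).
Folds are near-equal (±1) and label-stratified where counts permit; rare
labels are dealt cyclically so stratification degrades gracefully.  For the
binary task, unconnected pairs are sampled uniformly at ratio 1:1 once per
run before folding, keeping folds disjoint in pairs.  Each fold rebuilds
the topology view from training pairs only.  Multi-class metrics: accuracy,
macro precision/recall/F1 over labels present in the test fold (absent
labels are skipped, avoiding 0/0), micro AUC/AUPR over flattened
one-vs-rest scores, and per-class AUPR/F1.  In single-label multi-class
prediction micro precision = recall = F1 = accuracy; this identity is
asserted in the tests.  Metrics undefined for a fold's label set (e.g. AUC
with one class) are reported as explicit nulls and skipped in fold means.

Ablation variants reuse the identical protocol: `without_multiscale`
classifies on `Z^L` alone, `without_topology_view` / `without_feature_view`
keep the single remaining view, `scale_only_n` uses layer n's
attention-free output (so `scale_only_L` coincides with
`without_multiscale`).

## Synthetic data: what it emulates and what it does not

The generator plants `n_clusters` equal-sized latent drug clusters.  Each
cluster owns random binary prototypes (bit density 0.3) per feature type;
drugs copy their cluster's prototypes with per-bit flip probability β
(default 0.05).  Pair interaction probability is logistic in the clusters'
prototype Jaccard similarity with slope γ (default 12) and an intercept
solved by root-finding so the expected edge count is density × C(n, 2)
(default 0.1).  Event types are a deterministic function of the unordered
cluster pair, with cluster pairs greedily packed onto R types (default 5)
to balance expected label counts.  γ = 0 severs the feature–interaction
link and yields an unlearnable null dataset, which the tests use as a
negative control.

This emulates exactly the assumption the model exploits — interacting
pairs are feature-similar — plus learnable multi-class structure.  It does
*not* reproduce real pharmacology: no mechanistic event semantics, no
long-tailed label frequencies, no correlated descriptor noise, no
scale-free interaction topology, and cluster separability is far cleaner
than in curated DDI databases.  Passing the desk-scale benchmarks
therefore demonstrates that the implementation learns the planted signal
and that each architectural component behaves as designed — not that the
model attains any particular accuracy on real datasets.  At the reference
conditions the multi-class task is nearly saturated (accuracy ≈ 0.999), so
ablation comparisons there mostly tie; the binary task sits at a data
ceiling set by within-cluster non-edges (accuracy ≈ 0.95), where the
over-smoothing direction (scale-1 above scale-3) remains visible.

## Known limitations

* No multi-label events, no early stopping or lr schedules, no cold-start
  evaluation, no per-type adjacency stacks — all outside the protocol.
* The numpy training loop targets desk-scale graphs (hundreds to a few
  thousand drugs); benchmark-scale datasets train, but slowly, on one core.
* Checkpoints store parameters and config but not the graphs; re-attach
  views before predicting from a restored model.
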