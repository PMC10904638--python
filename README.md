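# ddifusion

Drug–drug interaction (DDI) prediction with a **dual-view, multi-scale GCN
fusion model**, for computational pharmacology researchers who want to
predict whether two drugs interact (binary task) and which pharmacological
event the interaction produces (multi-class task).

## The model

Drugs are described by binary descriptor sets per feature type (chemical
substructures, enzymes, targets).  Raw descriptor vectors are sparse and
high-dimensional, so the node features are the rows of the per-type
drug-by-drug Jaccard similarity matrices, spliced horizontally:

    J(d_i, d_j) = |d_i ∩ d_j| / |d_i ∪ d_j|,        X = [J_sub ‖ J_enz ‖ J_tar]

Two graph views over the same drug nodes feed the encoder:

* **topology view** `G_adj` — edges are the known DDIs (training folds only,
  so held-out labels never leak into message passing);
* **feature view** `G_knn` — each drug linked to its top-K most
  cosine-similar drugs, supplying plausible but unobserved links.

Each view runs an L-layer GCN over the renormalized adjacency
`Ã = D̂^{-1/2}(A+I)D̂^{-1/2}`,

    Z^l = σ(Ã Z^{l-1} W^l),   Z^0 = X,

and *all* per-layer outputs are kept: shallow scales carry local
high-dimensional detail, deep scales higher-order semantics.  Per view, the
spliced stack `Ẑ = Z^1‖…‖Z^L` feeds a linear map producing one attention
logit per scale and node; after LeakyReLU, a softmax across scales and a
row-wise l2 normalization, the factor `a^l` rescales the node's `Z^l` block:

    E_y = (a^1 ⊙ Z^1) ‖ … ‖ (a^L ⊙ Z^L),      E_drug = E_adj + E_knn.

Pair vectors (concatenation, average or Hadamard of the two drug
embeddings) are scored by a DNN head — batch norm, ReLU and dropout per
hidden layer, sigmoid or softmax output — and everything is trained jointly
with Adam on the summed cross-entropy.  The package includes the matching
evaluation protocol (5-fold CV over pairs, 1:1 negative sampling for the
binary task, macro/micro multi-class metrics) and the ablation variants
(single view, last-layer-only, single-scale).

The training stack is pure numpy on a small in-package reverse-mode
autodiff tape (`ddifusion.autodiff`); gradients are pinned by
finite-difference checks in the test suite.

## Worked example

A synthetic dataset with planted drug clusters drives both the descriptors
and the interactions, so every stage is runnable without downloads:

```python
import ddifusion as df

# 1. simulate a 120-drug dataset with 4 planted clusters
cfg = df.SynthConfig(n_drugs=120, n_clusters=4, n_types=4,
                     flip_noise=0.25, signal=6.0, seed=42)
synth = df.generate(cfg)
print(f"{synth.interactions.n_pairs} interactions over {cfg.n_drugs} drugs, "
      f"{cfg.n_types} event types")

# 2. featurize: per-type Jaccard blocks spliced into X
features = df.features_from_descriptors(synth.descriptors)
print("feature matrix:", features.values.shape)

# 3. 5-fold cross-validated event-type prediction
train_cfg = df.TrainConfig.from_preset("synthetic-multiclass", seed=42, epochs=25)
report = df.cross_validate(synth.interactions, features, train_cfg, n_folds=5)
for key in ("ACC", "F1_macro", "AUCPR_micro"):
    print(f"{key}: {report.overall[key]:.3f}")
```

prints

```
709 interactions over 120 drugs, 4 event types
feature matrix: (120, 360)
ACC: 0.987
F1_macro: 0.987
AUCPR_micro: 0.999
```

i.e. with noisy descriptors (25% bit flips) the cross-validated event-type
accuracy is 98.7%, because the planted cluster structure that generates the
interaction types is recoverable from the fused feature + topology views.

The same pipeline is scriptable from the shell:

```bash
ddifusion simulate --n-drugs 200 --clusters 5 --types 5 --seed 1 --out data/
ddifusion evaluate --descriptors data/descriptors.csv \
    --interactions data/interactions.csv \
    --task multiclass --preset synthetic-multiclass --seed 1 --out metrics.json
ddifusion ablate --variant without_multiscale ... # same flags
```

Real datasets in the same delimited formats (one row per drug/feature-type
with `|`-separated descriptor ids; one row per interacting pair with an
integer event label) load through `read_descriptors` / `read_interactions`.
Paper-scale hyper-parameter presets (`ddimdl-multiclass`,
`deepddi-multiclass`, `ddimdl-binary`, `deepddi-binary`) are built in.

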