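# dvmetric — the Data Value Metric

`dvmetric` quantifies how much *useful* information a dataset carries for a
specific inferential task. Accuracy tells you how well a model did; it does
not tell you whether collecting more samples, adding features, or switching
models would help. The Data Value Metric (DVM) addresses that question with
a single score that couples an information-theoretic measure of task
usefulness with the computational cost of the inference method — a tool for
biostatisticians and data scientists deciding whether to expand, prune, or
re-instrument a study dataset.

## The metric

For a dataset D and an inference method g,

```
DVM(D) = F(D) − λ · R(D)
```

**Fidelity** F is a normalized information-bottleneck ratio. Over M random
train/test splits, g is fitted on the training part and its held-out
representation T̃ (predicted labels by default) is scored against the true
held-out labels Ỹ:

```
F = (1/M) Σᵢ [ I(T̃ᵢ; Ỹᵢ) − β · I(X̃ᵢ; T̃ᵢ | Ỹᵢ) ] / I(X; Y)
```

I(·;·) is mutual information and I(X̃;T̃|Ỹ) penalizes representation
complexity that is irrelevant to the label. The denominator I(X;Y) — the
total task information in the data — bounds the fidelity above by 1:
F ≈ 1 means the method extracts essentially everything the data can say
about the task; F ≈ 0 means the data (or the method) carries no usable
signal. For unsupervised clustering the same ratio is applied to two
clusterings fitted on disjoint halves and applied to common held-out
points, so F measures cluster *stability*, invariant to label
permutations.

**Regularizer** R is the method's training-cost Big-O formula (e.g.
n²·p·k_trees for a random forest) evaluated at the dataset's size and
log-normalized to [0, 1]; λ (default 0.01) sets the exchange rate between
information and computation.

Mutual information is estimated by a plug-in estimator (discrete data), a
KSG k-nearest-neighbour estimator (continuous data), or a hash/binning
ensemble estimator that quantizes (optionally PCA-reduced) continuous
coordinates at several resolutions and combines bias-corrected plug-in
estimates — the workhorse for mixed and high-dimensional data.

## Worked example

```python
from dvmetric import DataValueModel, make_blobs_dataset

ds = make_blobs_dataset(n=600, p=100, cluster_std=20.0, seed=0)
res = DataValueModel(ds, model="random_forest").fit(seed=0)
print(res.summary())
```

```
Data Value Metric
========================================
Model                      random_forest
n samples / p features     600 / 100
Splits (M)                 10
Fidelity F                 0.3953
95% CI                     [0.3559, 0.4347]
Regularizer R              1.0000
lambda                     0.01
DVM = F - lambda*R         0.3853
I(X;Y) denominator (nats)  1.3730
Held-out accuracy          0.7111
```

At 600 samples and 100 features this 5-class problem yields 71% held-out
accuracy, but the DVM of 0.39 says the forest is extracting well under
half of the task information the data contains — more samples should help.
Rerunning at `n=2000, p=800` drives the accuracy toward 0.98 and the DVM
above 0.9: the dataset is then close to saturated for this method, and
further collection buys little.

`DVMResult` also exposes the per-split fidelities, a 95% t-interval, and
JSON serialization; `compute_surface` sweeps DVM and paired accuracy over
an (n, p) subsampling grid, and `select_features` runs greedy forward
feature selection by DVM gain.

## Command line

Every operation is also available as a config-driven CLI:

```
dvmetric simulate        --config cfg.yaml --output-dir out   # dataset + sidecar
dvmetric dvm             --config cfg.yaml --output-dir out   # single DVM -> JSON
dvmetric surface         --config cfg.yaml --output-dir out   # grid -> CSV + JSON
dvmetric select-features --config cfg.yaml --output-dir out   # trace -> CSV + JSON
```

See `docs/methods.md` for the YAML schema, estimator details, parameter
defaults, and the design rationale.

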