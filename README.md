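# hirand

Semi-supervised **Hi**erarchical graph **RAND**om neural networks for
predicting a binary response (e.g. drug sensitivity vs resistance) from a
transcriptome matrix when only a handful of samples carry labels.

Collecting drug-response labels for cell lines or patients is slow and
expensive, so a typical cohort has hundreds of expression profiles but only
a few labeled ones. `hirand` attacks this low-label regime with two graphs
and a consistency objective:

- a **gene interaction graph** A⁽ᵍ⁾ (e.g. a PPI edge list) masks a
  trainable weight in a graph-convolution layer
  H¹ = σ(X (A⁽ᵍ⁾ ⊙ W⁽⁰⁾)), and the normalised |W⁽⁰⁾| mass per gene,
  Iⱼ = Σᵢ A⁽ᵍ⁾ᵢⱼ|W⁽⁰⁾ᵢⱼ| / ΣᵢΣⱼ A⁽ᵍ⁾ᵢⱼ|W⁽⁰⁾ᵢⱼ|, ranks genes by how much
  the model uses them;
- a **kNN sample-similarity graph** with a locally scaled kernel
  Sim(p,q) = exp(−ρ²ₚq/(µεₚq)) on cosine distance supports *DropNode
  random propagation*: S stochastic views are made by zeroing whole sample
  rows with Bernoulli(1−δ) masks and diffusing the rest with the
  mixed-order operator Ā = (1/(K+1)) Σₖ Âᵏ;
- an MLP head turns each view into class probabilities Z̃⁽ˢ⁾, and training
  minimises L = L_lab + λ·L_unlab — cross-entropy on the labeled samples
  plus the squared distance of every view from the temperature-sharpened
  mean prediction Z̄′ ∝ Z̄^(1/T), so unlabeled samples supervise the model
  through prediction consistency.

The package also ships the benchmark's synthetic-data generator
(scale-free feature graph → Σᵢⱼ = 0.7^{Dᵢⱼ} covariance → multivariate
Gaussian expression → sparse nonlinear-link outcome thresholded at its
median), a labeled-size sweep harness with supervised baselines and paired
Win/Tie/Loss calls, and a CLI. Everything runs from generated data; no
downloads.

## Worked example

```python
import numpy as np
from hirand import SimulationSpec, simulate_dataset, HiRANDClassifier, compute_metrics

ds = simulate_dataset(SimulationSpec(g=200, n=120, n_true=10, seed=7))
X, y = ds.X.values, ds.y

# reveal 10 labels per class; everything else is unlabeled (-1)
rng = np.random.default_rng(0)
y_semi = np.full(y.size, -1)
for cls in (0, 1):
    y_semi[rng.choice(np.flatnonzero(y == cls), 10, replace=False)] = cls

clf = HiRANDClassifier(gene_adjacency=ds.feature_graph, random_state=0)
clf.fit(X, y_semi)

auc, acc, f1 = compute_metrics(y, clf.predict_proba(X)[:, 1])
print(f"transductive AUC={auc:.3f} accuracy={acc:.3f} F1={f1:.3f}")
print("top genes by importance:", clf.importance_.top(5))
```

prints

```
transductive AUC=0.760 accuracy=0.717 F1=0.721
top genes by importance: ['gene_0017', 'gene_0003', 'gene_0008', 'gene_0002', 'gene_0034']
```

i.e. with 20 of 120 labels the fitted model ranks the full cohort at AUC
0.76, and the gene layer's importance vector (sums to 1) names the genes
whose incident weights carry the most mass. The estimator follows the
scikit-learn API (`get_params`/`set_params`, `-1` = unlabeled as in label
propagation) and composes with sklearn tooling; `predict_proba` on unseen
samples rebuilds the similarity graph over fitted + new rows.

From the shell:

```bash
hirand simulate --g 200 --n 120 --n-true 10 --seed 7 --out-dir data/
hirand train --expr data/expression.csv --genes data/gene_graph.tsv \
             --labels data/labels.csv --out run/
hirand sweep --expr data/expression.csv --labels data/labels.csv \
             --grid 4,6,10 --out sweep/
```

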