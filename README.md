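# rgcfate

Tools for asking how a class of postmitotic neuronal precursors diversifies
into discrete transcriptomic types, from time-stamped single-cell RNA-seq
snapshots. The motivating system is the developing mouse retinal ganglion
cell (RGC) class — sampled at E13, E14, E16, P0, P5 and P56 (days 0, 1, 3,
6, 11, 20) and resolving into ~45 adult types — but every component works on
any time course of counts with age and batch labels.

The package bundles:

* **synthetic data with planted truth** (`rgcfate.synthdata`): a binary fate
  tree over terminal types (subclasses as clades), per-cell fate vectors
  that restrict progressively and asynchronously after each tree node's
  decouple time, Gamma-Poisson counts with library-size variation, batch
  structure, a fading fate-orthogonal maturation continuum, and an optional
  ipsilateral/contralateral gene module — so every estimator below can be
  validated against a known ground truth;
* **preprocessing** (`rgcfate.preprocess`): cell/gene filtering, median
  library normalization with log transform, Gamma-Poisson highly-variable-
  gene (HVG) selection (null CV √(1/μ + 1/α), selection d > mean + 0.8 sd),
  marker-based class annotation with cluster-level doublet flagging;
* **clustering** (`rgcfate.cluster`): Tracy-Widom (random-matrix) choice of
  latent dimension, PCA or batch-integrative NMF embedding with quantile-
  normalized loadings, 30-NN/Jaccard/Louvain graph clustering, Wilcoxon DE
  with the size-balanced log-fold-change criterion (|logFC| > 0.5, FDR
  p < 1e-5), and dendrogram-guided merging of indistinct clusters;
* **diversity & distinctiveness** (`rgcfate.diversity`): Rao, Shannon and
  Simpson indices; gradient-boosted-tree classifier error; relative cluster
  diameter r_C/d_C in standardized PC space;
* **cross-age correspondence** (`rgcfate.xmap`): the supervised mapping
  protocol (60%/max-300 sampling, 10%-error retraining with upsampling,
  top-500 information-gain feature intersection) with ARI, normalized
  conditional entropy (NCE) and per-label occupancy fractions;
* **optimal transport** (`rgcfate.transport`): a log-domain entropic
  unbalanced Sinkhorn solver (ε = 0.005, KL-relaxed marginals λ₁ = 1,
  λ₂ = 50, growth-rescaled source), map composition, per-cell fate vectors
  f over terminal clusters, ancestor/descendant distributions, and the
  multipotency potential P = 1/Σ f² ∈ [1, n_types];
* **fate couplings & specification** (`rgcfate.fates`): pairwise Pearson
  fate couplings with a within-cell randomization null, network edge-list
  export, logistic decay fits C(t) = 1/(1+e^{β₀+β₁t}), the localization
  score, and specification times τ_sp (earliest crossing of
  0.95·(1−1/N(t)));
* **laterality** (`rgcfate.laterality`): ipsi/contra signature scores
  (Zic2/Zic1/Igfbp5 vs Isl2/Fgf12/Igf1), 1.5-SD calls, propagation of
  I-cells through composed maps, and the I-vs-rest DE contrast (fold
  change > 1.5, Bonferroni p < 5e-5).

`rgcfate.pipeline` wires the stages end to end, `rgcfate.benchmarks` packages
the planted-truth recovery experiments, and a thin `rgcfate` CLI exposes the
stages for shell use.

## Worked example

```python
from rgcfate import pipeline, synthdata
from rgcfate.benchmarks import desk_config

truth, counts = synthdata.simulate_dataset(
    n_types=10, n_subclasses=3, n_cells_per_age=400, n_genes=700, seed=3
)
config = desk_config()
_, em, hvg = pipeline.preprocess_stage(counts, config)
hvg_em, _, partitions = pipeline.cluster_stage(em, hvg, config, seed=0)
maps, fates, potential = pipeline.transport_stage(hvg_em, partitions, config, seed=0)
for age, value in sorted(potential.items()):
    print(f"{age:10.0f} | {value:8.2f}")
```

prints

```
         0 |     4.28
         1 |     3.49
         3 |     2.52
         6 |     1.72
        11 |     1.21
        20 |     1.00
```

i.e. the mean inferred potential falls monotonically from ~4 of 10 possible
fates at the first age to 1 (full commitment) at the terminal age — the
transport chain recovers the planted progressive fate restriction. The
scripts in `examples/` walk through each capability the same way (simulation,
clustering and diversity, cross-age mapping, fate inference, couplings and
specification times, laterality).

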