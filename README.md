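# sctemporal

Cross-timepoint analysis of single-cell RNA sequencing data: supervised
cell-type annotation across timepoints, detection of novel cell types that
emerge over time, visualization of cell-population evolution, and screening
for temporal differentially expressed genes (tDEGs).

## Who this is for

Multi-timepoint scRNA-seq designs — a patient sampled before and after
treatment, an infection time course — are usually analyzed with
cross-sectional tools that ignore the time axis. `sctemporal` treats the
earlier timepoint as labeled reference data and borrows that information
forward, while guarding against the failure mode every closed-set classifier
has: a cell type present only at later timepoints gets silently mislabeled.

## The methods

**Annotation.** Given a labeled initial timepoint with expression matrix
X₀ (p genes × n₀ cells) and labels Y₀, counts are min-max normalized per
gene, the 2000 most variable genes are selected, and a feed-forward network
(hidden layers 256/128/64, ReLU, softmax output over the K types; MSE loss
on one-hot targets; Adam with mini-batches, dropout 0.4, early stopping on a
stratified validation split) maps later-timepoint cells X₁ to class
probabilities. If t₀ is unlabeled, Louvain communities on a kNN graph of a
20-dimensional UMAP embedding serve as training classes. A stepwise mode
re-trains on t₀ plus the freshly labeled t₁ before annotating t₂.

**Novel cell types.** For each known type k: embed t₀ into 20 dimensions
with UMAP and project t₁ into the same space; form the type centroid
m^k = mean of the type's t₀ embeddings; compute each predicted-type-k cell's
Pearson correlation r with m^k; bisect the type's cells into two Louvain
communities (sweeping the resolution until exactly two appear); Welch-test
the two groups' correlations. A significant minority group with the lower
mean correlation is flagged, and flagged groups across types are pooled
under a reserved novel label.

**tDEGs.** Each gene's counts follow a negative binomial with mean μᵢ and
dispersion ω (variance μᵢ + μᵢ²/ω) under the log-linear model

    log μᵢ = β₀ + β₁·timeᵢ + β₂·strataᵢ + β₃·timeᵢ·strataᵢ

with (β, ω) estimated by maximum likelihood and per-term Wald tests. A tDEG
is a gene whose interaction p-value survives the Bonferroni correction: its
temporal trend differs between strata (e.g. rises in responders, falls in
non-responders).

A synthetic-data generator reproduces the study designs (three composition
scenarios across t₀/t₁/t₂, and a 2000-gene × 900-cell spike-in with 300
tDEGs at weak/medium/strong effect) with full ground truth, so every stage
is testable end to end.

## Worked example

```bash
python examples/02_novel_type_detection.py
```

```
true novel cells   : 72
flagged as novel   : 66  (recall 0.917, precision 1.000)
classifier only    : accuracy 0.820
with detection     : accuracy 0.985
```

Scenario 3 at example scale (400 cells/timepoint, 500 genes): a fifth cell
type appears at t₁. The closed-set classifier's accuracy is capped at
1 − (novel fraction) ≈ 0.82 because it cannot name an unseen type; the
detection step flags 66 of the 72 novel cells with no false positives,
lifting accuracy to 0.985. The other examples cover annotation
(`01`), the tDEG screen (`03`, printing the true discovery rate against the
spike-in truth) and fish-plot visualization of population evolution (`04`).

The same pipeline is scriptable from the shell:

```bash
sctemporal simulate --mode scenario --scenario 3 --seed 1 --outdir sim/
sctemporal run-full --scenario 3 --stepwise --seed 1 --outdir out/
sctemporal tdeg --matrix counts.csv --meta meta.csv --outdir out/
```

## Layout

- `src/sctemporal/` — `io` (MTX triplet / CSV / metadata), `preprocess`
  (scaling, HVGs), `annotate` (classifier + unsupervised fallback +
  stepwise merge), `novel` (detection pipeline), `tdeg` (NB GLM screen),
  `metrics`, `simulate` (generator), `viz` (fish/embedding plots), `cli`
- `examples/` — one short narrative script per capability
- `docs/methods.md` — model details, defaults, numerical choices, limitations
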