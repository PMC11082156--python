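# Methods

## Overview

`sctemporal` analyzes scRNA-seq experiments sampled at two or more
timepoints (t₀, t₁, t₂, …) in three stages: (1) supervised cross-timepoint
annotation with a neural-network classifier trained on the labeled initial
timepoint, (2) detection of cell types absent from t₀ that emerge later,
and (3) a per-gene negative-binomial GLM screen for genes whose temporal
trend differs between strata (tDEGs). A synthetic-data generator with
complete ground truth backs the test suite and the acceptance script.

## Preprocessing

Counts are min-max normalized per gene across cells, x ↦ (x − min)/(max −
min); constant genes map to zero (0/0 := 0 — an uninformative feature
should carry no signal). Normalization precedes feature selection: the 2000
genes with largest variance on the normalized scale are kept (ties broken
by input gene order, so selection is deterministic and invariant to cell
order). The per-gene min/max of the *training* matrix is stored and applied
to later timepoints, clipping to [0, 1]: classifier inputs must share the
training feature scale, and a later timepoint's own range would silently
shift features. Training genes missing from a test matrix are zero-filled
(logged); more than 50% missing is treated as incompatible feature spaces.

## Annotation classifier

A feed-forward network with three ReLU hidden layers (256, 128, 64 units)
and a softmax output over the K types, implemented directly on numpy
arrays. Training minimizes the mean squared error between the softmax
probabilities and one-hot targets — MSE rather than the conventional
cross-entropy is the pipeline's stated design and the default; a
`loss="cross_entropy"` switch exists. Optimization is Adam (lr 1e-3,
β=0.9/0.999) on mini-batches of 128, dropout 0.4 on every hidden layer
(inverted scaling), for at most 200 epochs with early stopping: a 20%
class-stratified validation split is monitored and training stops after 10
epochs without improvement, restoring the best weights. Glorot-uniform
initialization. One user-visible seed drives weight init, the validation
split, batch shuffling and dropout, so runs are bit-reproducible.

Classes with a single cell are rejected (no stratified split is possible);
a rarest class below 1% of cells triggers a warning but no reweighting.

When t₀ arrives unlabeled, Louvain communities on a kNN graph (k = 15) of a
20-dimensional UMAP embedding of the normalized HVG matrix become the
training classes ("cluster_1" … "cluster_K"). The default Louvain
resolution is 0.3, deliberately coarse: these labels stand in for cell
*types*, and modularity at resolution 1 fragments small homogeneous
populations into neighborhoods.

For the t₁→t₂ transition, the stepwise mode concatenates t₀ with the
labeled t₁ (gene-set intersection, overlapping barcodes
suffix-disambiguated) and retrains. This also propagates a novel type
discovered at t₁ into the t₂ reference classes.

## Novel-type detection

A classifier restricted to t₀'s label alphabet must mislabel any type that
first appears later. The detection pipeline, run per predicted type k on an
annotated later timepoint:

1. **Embedding.** One 20-dimensional UMAP is fitted on all t₀ cells
   (normalized HVG matrix) and the later cells are projected into the same
   space with transform semantics. A shared space is required for step 3 —
   correlations between independently fitted embeddings are meaningless —
   and a single global fit avoids degenerate per-type refits on small types.
2. **Centroid.** m^k = coordinate-wise mean of the type's t₀ embeddings.
3. **Correlation.** Pearson correlation across the 20 coordinates between
   each predicted-type-k cell's embedding and m^k. Zero-variance vectors
   yield missing values and are excluded from testing (logged).
4. **Bisection.** The type's cells are split into exactly two Louvain
   communities on a kNN graph (k = 15) of their normalized HVG expression
   vectors, sweeping the resolution over 0.05…2.0 in steps of 0.05 until
   exactly two communities appear; if none does, the smallest resolution
   giving ≥2 is used and all but the largest community are merged.
   Bisection runs in gene space rather than on the projected embedding:
   UMAP's transform compresses cells unlike anything in the training data
   onto the nearest reference cluster, which can hide an admixed novel
   population, whereas the expression vectors keep it separable.
5. **Test.** Welch's two-sample t-test on the two groups' correlations at
   α = 0.05 (per type, no cross-type correction). If significant, the group
   with the smaller mean correlation is the candidate novel population —
   but only when it holds at most half the type's cells. Novel cells
   misassigned into a known type form a minority of it; a *majority* with
   marginally lower correlation is within-type structure. Without this
   guard the test is anticonservative — the groups are chosen by
   clustering, so the t-test's nominal level does not hold, and marginal
   p-values (0.01–0.05) on homogeneous types would flag large groups.
6. **Relabeling.** Flagged groups across all types are pooled under one
   reserved label (default `novel`, suffixed if the name is taken). All
   other labels are preserved bit-for-bit. The report carries per-cell
   correlations, groups and flags, the per-type test table, and a separate
   2-d UMAP for the dual diagnostic plots (type-colored and
   correlation-colored).

Types with fewer than 20 predicted cells are never flagged (graph
clustering and the t-test are unstable below that). Multiple novel types
are pooled under the single reserved label; the correlation-colored
embedding lets a user recognize distinct novel populations, and naming them
is out of scope.

**Known limitations.** (i) A novel population transcriptomically close to a
known type produces correlations too similar to flag. (ii) A novel
population that has grown into the *majority* of some predicted type — e.g.
a dominant clone at a late timepoint, annotated directly from t₀ — is
suppressed by the minority guard; the stepwise workflow (retrain on t₀ +
labeled t₁ before annotating t₂) handles this case and is the recommended
path for late timepoints.

## tDEG screen

Counts follow NB2: p(y) = Γ(y+ω)/(y! Γ(ω)) · (ω/(ω+μ))^ω · (μ/(ω+μ))^y,
with mean μ and variance μ + μ²/ω, under the log link

log μᵢ = β₀ + β₁·timeᵢ + β₂·strataᵢ + β₃·timeᵢ·strataᵢ.

Time may be numeric (treated as linear) or an ordered factor encoded
0, 1, …; strata must be binary. No library-size offset is used by default.
(β, ω) are joint maximum-likelihood estimates. The fitter alternates IRLS
updates of β given ω (working weights μ/(1+μ/ω)) with Newton steps on
log ω given β, vectorized across all genes sharing the design matrix, until
each gene's log-likelihood changes by less than 1e-8 (at most 100 outer
iterations; converged genes leave the working set). Where the profile
likelihood in ω is non-concave it rises monotonically toward the Poisson
boundary, so the update strides instead; genes pinned at the dispersion cap
(1e6) are boundary MLEs of Poisson-like data and are treated as converged.
Trigamma is evaluated via the recurrence plus asymptotic series (accurate
to ~1e-10) rather than scipy's Hurwitz-zeta route, which dominates runtime
otherwise. Fits agree with an independent joint-MLE implementation
(statsmodels `NegativeBinomial`) to ~1e-3 in coefficients and dispersion.

Per-term two-sided Wald tests use standard errors from (XᵀWX)⁻¹ at the
MLE. Genes are prefiltered to those expressed in ≥ 10 cells (configurable);
all-zero and non-converged genes are excluded from testing and from the
Bonferroni denominator m — untested hypotheses should not inflate the
correction. A tDEG call is min(1, m·p_interaction) < α, default α = 0.05.
The interaction p-value is invariant to which stratum is coded 0 (β₃ flips
sign in combination with β₁).

## Synthetic-data generator

The generator draws from a parametric NB world with marker-block structure
instead of subsampling a real PBMC dataset, keeping the repository
self-contained.

**Composition scenarios.** Defaults: 2000 genes, 1500 cells per timepoint,
K = 5 types. Per-gene base means are Gamma(shape 2, scale 0.5) (mean 1,
floored at 0.05); each type up-shifts its own disjoint 10% block of marker
genes by e^1.0; counts are NB with dispersion ω = 2. Scenario 1 keeps all
five types with shifted proportions; scenario 2 drops one type after t₀;
scenario 3 withholds one type from t₀ and introduces it at t₁/t₂ (novel
markers get an extra e^0.5 shift, making the emerging type distinct from
every reference). Per-timepoint type counts are multinomial draws from the
target compositions; t₀ carries labels, t₁/t₂ labels live only in the
emitted truth.

**tDEG spike-in.** 2000 genes × 900 cells over three timepoints
(time = 0, 1, 2), strata A/B at 50/50 (both strata forced present at every
timepoint). 300 spiked genes drift by +δ per unit time in stratum A and −δ
in stratum B — a pure interaction with true β₁ = δ, β₃ = −2δ under A = 0
coding. δ is 0.1/0.25/0.5 for weak/medium/strong, spanning near-null to
easily detected regimes.

**What it does not emulate:** library-size variation, zero inflation beyond
NB, batch effects, correlated genes within programs, continuous
differentiation trajectories, or within-subject correlation across
timepoints. Passing tests therefore demonstrate correctness of the
machinery under the stated generative model, not performance on real data.

## Evaluation metrics

Accuracy is exact label-string agreement (the reserved novel label counts
as correct only against truly novel cells). ARI is the chance-corrected
pair-counting index (tested against an exhaustive all-pairs oracle for
n ≤ 12). TDR = |called ∩ true|/|called| = 1 − FDR; undefined (error) for an
empty call set. In multi-replicate summaries TDR is pooled: total true
calls over total calls, which keeps replicates with zero calls from
dropping out.

## Determinism and problem sizes

Every stochastic stage — simulation, weight initialization, validation
split, dropout, UMAP (seeded runs force single-threading), kNN graphs,
Louvain (seeded igraph RNG) — derives from explicit integer seeds; repeated
runs are byte-identical. The test suite and the acceptance script run the
composition scenarios at 1500 cells/timepoint × 2000 genes, the tDEG power
study at 2000 × 900 with 50 replicates per effect level (pooled TDR), and
the null calibration at 500 × 400 with 200 replicates (100 in the script);
these sizes give stable estimates while keeping a full run in the
minutes range on one CPU.
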