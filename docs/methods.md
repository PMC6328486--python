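# Methods

## Problem and overall design

`gliameta` asks whether a target gene — by default *Oprm1* (mouse/rat) /
*OPRM1* (human), the mu opioid receptor — is expressed in purified microglia,
using two independent lines of evidence:

1. a **meta-analysis of already-normalized transcriptomes** of purified
   microglia (microarray intensities, bulk RNA-seq quantifications, and
   Mars-seq-like single-cell aggregates with limited gene detection),
   organized into tissue groups (whole brain, cortex/hippocampus/striatum,
   spinal cord, human cortex); and
2. the **colocalization statistics** of a double-reporter mouse line, where
   the fraction of reporter-positive microglia that also express the target
   receptor is counted on microscopic fields.

No download clients are included; matrices are consumed as files, and a
synthetic-data generator emulates whole collections with planted ground
truth, so every stage is testable end to end without external data.

## Detection calls

Each dataset is transformed elementwise as log2(1 + x); adding one keeps
zero counts at exactly zero. All gene x sample log2 values of a dataset are
pooled and the 25th/50th/75th percentiles of the pool are the dataset's
landmarks (the values drawn on the violin plots). Quantiles use linear
interpolation between order statistics (R type 7, the numpy default); the
convention is a parameter of every landmark computation.

The dataset-level target value is the **mean over samples of the per-sample
log2 values**. It is classified as

* `above_median` if value ≥ median,
* `between_q25_and_median` if Q1 ≤ value < median,
* `below_q25` if value < Q1,
* `not_detected` if the gene is absent from the matrix (the Mars-seq
  situation) or is exactly zero in every sample.

Ties at a landmark resolve upward (a value exactly at the median counts as
above it): detectability is the privileged reading. Group summaries count
datasets per bin and report "N out of M" detected.

Two pooling conventions are implemented because the choice is genuinely
open: `pooled` (default; one pool per dataset, matching one violin per
dataset) and `per_sample` (landmarks per sample, then averaged). Both are
order-respecting; they differ only for strongly heterogeneous samples.

**Known limitation.** Because the multi-sample target value is a mean of
log2 values, a *nonlinear* strictly increasing transform of all values
shifts the mean differently from the landmarks, so bin assignments are
guaranteed transform-invariant only for single-sample datasets; for linear
transforms and for per-value classification the invariance is exact.

## Module scores

A gene module is a curated set of genes characterizing a cell type or
activation state. Eleven modules in three categories ship by default
(myeloid: Microglia, Macrophage, Neutrophil_Monocyte; activation:
Interferon, Proliferation, LPS, Neurodegeneration; neuron/astrocyte:
Neuron, Excitatory, GABAergic, Astrocyte), built from representative,
widely used marker genes with mouse/rat/human spellings. They are
deliberately replaceable: reproducing a specific published analysis
requires that analysis' exact curated lists, supplied by the user as a
TSV/JSON module file. An exclusivity filter removes module genes flagged by
a user-editable cross-expression table as expressed in any other cell type,
logging every removal.

The score of a module in a sample is the arithmetic mean of the module
genes' log2 values **over the genes present in the matrix**; platform
panels differ, and imputing zeros for absent genes would bias microarray
against RNA-seq datasets. Coverage (present/total) is reported and scores
under 50% coverage are flagged, never silently dropped; a score over zero
present genes is absent, not zero. The dataset-level score is the mean of
per-sample scores. The target-gene column of the score table reuses the
identical dataset-level value the detection call is made on.

## Cross-dataset correlation

Within a tissue group the dataset x (modules + target) score matrix is
standardized per column to z-scores with the sample (n−1) standard
deviation — conventional for the 5–17 datasets per group. Datasets flagged
`include_in_correlation=false` in the registry (the declared "varied
substantially from all other datasets" exclusions) are removed and logged;
a dataset whose Microglia z exceeds |z| > 2.5 receives an advisory flag but
is never removed automatically — exclusion is a registry decision. Fewer
than three retained datasets is an error.

Spearman's rho is the Pearson correlation of mid-ranks (average ranks for
ties). Two-sided p-values:

* **exact permutation** for n ≤ the exact threshold (default 8,
  configurable): the p-value is the fraction of permutations of one
  vector's ranks with |rho| at least the observed |rho|. Without ties the
  null distribution of the rank cross-product T = Σ rᵢ·sᵢ is computed by a
  dynamic program over rank subsets, which reproduces full enumeration
  exactly (verified against brute force for every n ≤ 7) while remaining
  cheap up to n ≈ 13; with ties the observed tied ranks are permuted
  outright (conditional null), feasible to n = 9, beyond which the t
  approximation is used and logged;
* **t approximation** otherwise: t = rho·√((n−2)/(1−rho²)) on n−2 degrees
  of freedom.

Since ranks are invariant under any strictly increasing transform, the
z-score step is provably neutral for rho and p; the suite asserts this. No
multiple-testing correction is applied to the per-module results (mirroring
per-comparison reporting at α = 0.05 inclusive); a clearly-labelled
Holm-adjusted column is emitted alongside for users who want family-wise
control. Significance stars follow * ≤0.05, ** ≤0.01, *** ≤0.001,
**** ≤0.0001.

## Colocalization statistics

Counts are consumed as given (no image analysis). The replication unit
defaults to the **animal**: fields within an animal are pseudo-replicates,
and the animal percentage pools counts (Σ double / Σ marker × 100), which
always lies between that animal's field percentages. A field-level mode is
available since the unit of published SEMs is often unstated. Summaries are
mean ± SEM (sd/√n, sample sd); a single unit yields a mean with an absent
SEM rather than zero. Fields with no marker-positive cells are skipped with
a log entry.

Sex comparison is normality-gated: Shapiro-Wilk at α = 0.05 on each group
(groups under 3 units cannot be assessed and fail the gate); both pass →
two-sided unpaired Student's t-test, otherwise two-sided Mann-Whitney with
mid-rank ties (exact null when sample sizes allow). The t-test uses
**pooled variance by default**: at the two-to-three animals per sex typical
of these cohorts, Welch's degrees-of-freedom approximation is measurably
conservative (null rejection ≈0.034 at nominal 0.05 under exact normality
at n=3/sex, dragging the gated procedure to ≈0.026), whereas the pooled
test holds its level (≈0.048, gated ≈0.043 — the Mann-Whitney fallback can
never reject at n=3/sex, so the procedure stays slightly conservative).
Welch remains available via `equal_var=False`.

## Synthetic data

The generator emulates the study conditions of a dataset collection, not
any specific public accession:

* **Collection shape**: 12 datasets per group by default (5–17 supported),
  12,000 genes, 1–6 samples each, alternating microarray/RNA-seq platforms.
* **Baseline abundance**: per-gene log2 means ~ Normal(4, 2), clipped at 0.
* **Module structure**: module genes are shifted in log2 mean — Microglia
  +3 (dominant, as in purified microglia), other modules 0 to +1 — plus an
  independent per-(dataset, module) effect (sd 0.5 log2) that creates
  cross-dataset variation.
* **Platform noise**: microarray samples are log-normal around the gene
  mean (sd 0.25 log2); RNA-seq counts are negative binomial with the gene's
  linear mean and dispersion 0.3 (var = μ + 0.3 μ², typical bulk
  overdispersion); Mars-seq-like data are RNA-seq counts with **gene-level
  dropout** — the lowest-abundance 70% of genes are removed from the gene
  list entirely, reproducing "not in the dataset" rather than zeros.
* **Target planting**: either a detection bin — the target row is placed at
  a pooled-quantile position inside the requested bin (0.75 / 0.375 / 0.10;
  `not_detected` via dropout on sc-like platforms or an all-zero row
  elsewhere) — or a cross-dataset Spearman ρ\* with a named module, planted
  through a Gaussian copula on per-dataset latent effects (Pearson latent
  correlation 2·sin(πρ\*/6), latent sd 1.5 log2) so the rank correlation is
  controlled directly. Requesting both is an error.
* **Colocalization**: per field, reporter-positive cells ~ Poisson(40) and
  double-positives ~ Binomial(cells, fraction), with per-(region, sex) true
  fractions defaulting to the 0.35–0.52 brain and 0.37–0.42 cord ranges and
  a planted female<male gap in the VTA; 3 animals/sex × 10 fields.

One integer seed makes the whole collection byte-reproducible (per-dataset
generators are spawned from the master seed). The generator does **not**
emulate batch effects, platform-specific probe biases, inter-gene
correlation beyond module structure, or real accessions' value
distributions — passing recovery tests shows the pipeline's logic is
correct under known truth, not that any specific public dataset would
reproduce.

## Validation studies and problem sizes

The package validates itself with fixed-seed studies sized to run on a
single CPU in about a minute (the same studies are re-run by
`scripts/acceptance.py`):

* landmark and Spearman primitives against independent brute-force oracles
  (1,000 random vectors / pairs; full n! enumeration for n ≤ 7);
* exact-p null calibration on 1,000 microarray-only collections of 12
  datasets × 400 genes — microarray intensities are continuous, so
  dataset-level values are tie-free and the exact permutation path is the
  one exercised (count platforms produce exact ties, which would divert
  small-n cases to the conditional-enumeration or t path);
* ρ\* recovery at 0.3/0.6/0.9 (200 collections each, n=12 × 400 genes);
  finite-gene and count noise attenuate the planted rank correlation
  slightly (median recovered rho ≈ ρ\* − 0.1 at 0.9);
* detection-bin recovery (20 low-noise datasets per bin, 500 genes) and
  Microglia dominance (200 datasets);
* colocalization null calibration (1,000 experiments) and power of the
  35% vs 50% sex shift at 2-point within-sex sd, n=3/sex.

Gene counts in these studies (400–500) are deliberately smaller than the
12,000-gene default: the pooled-quantile and mean-score statistics converge
quickly in the number of genes, and the studies probe calibration and
recovery, not genome-scale throughput.
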