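# gliameta

Cross-dataset meta-analysis of a target gene's expression in purified
microglia transcriptomes — plus the statistics layer for reporter-mouse
colocalization counts.

## The problem

Whether microglia — the resident immune cells of the central nervous
system — express the mu opioid receptor gene (*Oprm1* in mouse and rat,
*OPRM1* in human) is hard to settle from any single experiment: expression
is low, platforms disagree, and single-cell protocols with shallow gene
detection can miss the transcript entirely. `gliameta` implements the
desk-analysis that combines many already-normalized purified-microglia
datasets into one answer, for computational biologists and neuroimmunology
labs who have a registry of expression matrices (or want to prototype on
synthetic ones):

1. **Detection calls.** Each dataset is log2(1+x)-transformed; the pooled
   distribution of all gene × sample values gives the dataset's quartile
   landmarks (Q1, median, Q3). The target's dataset-level value (mean of
   per-sample log2 values) is binned as *above median*, *between Q1 and
   median*, *below Q1*, or *not detected* (gene absent from the matrix or
   all-zero), and groups are summarized as "N out of M datasets".
2. **Module scores.** Curated gene modules (Microglia, Macrophage,
   Neutrophil/Monocyte; Interferon, Proliferation, LPS, Neurodegeneration;
   Neuron, Excitatory, GABAergic, Astrocyte) are scored per dataset as the
   mean log2 of their member genes, with coverage tracking across platforms
   and an exclusivity filter against genes expressed by other cell types.
3. **Correlation.** Within a tissue group, dataset-level scores are
   z-scored ((x − x̄)/s, sample sd), declared outlier datasets are excluded,
   and Spearman's ρ between the target and each module is computed with
   exact permutation p-values at small n (full-enumeration-equivalent
   dynamic program; two-sided) and the t approximation
   t = ρ√((n−2)/(1−ρ²)) otherwise.
4. **Colocalization.** From per-field counts of reporter-positive microglia
   and double-positive cells, percent positive per animal is summarized as
   mean ± SEM and sexes are compared with a normality-gated test
   (Shapiro-Wilk → Student's t or Mann-Whitney).

A first-class synthetic-data module generates whole dataset collections
with planted truth (detection bins, module shifts, cross-dataset ρ via a
Gaussian copula, Mars-seq-like gene dropout, binomial colocalization
counts), so the full pipeline runs and is validated without any downloads.
See `docs/methods.md` for the model details and design choices.

## Worked example

Generate a 12-dataset whole-brain-style collection with a planted
target–Microglia rank correlation of 0.9, then run the full pipeline:

```python
import gliameta as g
from gliameta.pipeline import PipelineConfig, run

coll = g.generate_collection(g.SyntheticCollectionConfig(
    seed=11, n_datasets=12, n_genes=2000, target_rho=0.9))
coll.write("demo")

bundle = run(PipelineConfig(registry="demo/registry.yaml", outdir="demo/out"))
print(bundle.summaries[0].sentence)
print(bundle.correlations.sort_values("p")
      [["module", "n", "rho", "p", "stars"]].head(2).to_string(index=False))
```

Output:

```
12 out of 12
   module  n       rho        p stars
Microglia 12  0.923077 0.000019  ****
   Neuron 12 -0.482517 0.112109
```

The target was detected in all 12 datasets (here 3 above the median, 3
between median and Q1, 6 below Q1 — the planted correlation varies the
target's level across datasets, not its bin), and the estimated
target–Microglia Spearman rho of 0.92 recovers the planted 0.9; no other
module correlates significantly. `demo/out/` holds the full TSV tables
(detection_calls, detection_summary, module_scores, zscores, correlations,
exclusions) plus a `run.json` with the reproducible config hash.

The same analysis is available from the shell:

```bash
gliameta simulate collection --seed 11 --out demo
gliameta call --registry demo/registry.yaml
gliameta run --config pipeline.yaml     # registry/target/options in YAML
```

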