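# coexmod

Differential co-expression module discovery and prognostic evaluation for
two-state transcriptome studies.

Many disease transcriptome analyses stop at differentially expressed genes
(DEGs). `coexmod` targets the next layer: gene **modules** whose members are
densely co-expressed in the diseased state but lose that coordination in
healthy tissue. Such differentially co-expressed modules are candidate
"systems biomarkers" — in the motivating setting, epithelial ovarian
carcinoma versus healthy ovarian surface epithelium, an 84-gene module of
this kind stratified patients into groups with a roughly two-fold difference
in death rate. The package is for computational biologists who want that
whole analysis as a tested, scriptable pipeline rather than a chain of GUI
tools, plus a synthetic-data generator with planted ground truth so every
stage can be validated at desk scale.

## The method

Given several independent gene × sample log2 expression datasets, each with
diseased and healthy samples:

1. **Differential expression, per dataset.** For gene *g* with pooled
   two-sample variance s²_g on d_g degrees of freedom, an empirical-Bayes
   moderated t-statistic shrinks variances toward a prior s₀² with d₀ prior
   df (estimated from all genes by matching the mean and variance of
   log s²_g to the scaled-F prior predictive):

   s̃²_g = (d₀s₀² + d_g s²_g) / (d₀ + d_g),  t_g = Δm̄_g / (s̃_g·√(1/n₁+1/n₂)),

   with p-values from t on d₀+d_g df, Benjamini–Hochberg adjustment, and a
   gene called DE when p_adj < 0.01 and fold change > 2 or < 0.5.
2. **Mutual DEGs.** The direction-agnostic intersection of the per-dataset
   DEG sets.
3. **State-wise networks.** Samples are pooled by state and quantile
   renormalized; the Pearson correlation r_ij is computed for every mutual
   DEG pair. The pairwise correlations are approximately normal, so the
   edge cutoff is the empirical two-sided α = 0.05 bound μ̂ + z₀.₉₇₅·σ̂
   (mirrored for negative correlations). Genes with no super-threshold
   partner are dropped.
4. **Modules.** MCODE-style clustering: each vertex is weighted by
   k\*·density of the highest k-core of its closed neighborhood; complexes
   grow from the highest-weight seeds; complexes without a 2-core are
   discarded and haircut trims degree-1 vertices. Modules are ranked by
   average connectivity (edges per gene) and kept when they have ≥ 10
   genes, average connectivity ≥ 10 and density ≥ 0.80.
5. **Differential co-expression.** The selected module is projected onto
   both state networks; its density (denominator: all module gene pairs) and
   clustering coefficient are compared, and a state-label permutation test —
   recomputing the data-derived cutoff inside every shuffle — gives
   p = (1 + #{T_perm ≥ T_obs})/(n_perm + 1) for T = density_diseased −
   density_healthy.
6. **Prognosis.** Diseased samples are projected onto the first three
   principal components of the module expression (genes z-scored), split
   into two clusters by k-means, and compared by Kaplan–Meier curves, the
   two-group log-rank test and a binary-covariate Cox proportional-hazards
   model (Breslow ties, Newton–Raphson), reporting the hazard ratio with its
   95% CI.
7. **Regulators and specificity.** TF/miRNA target tables give per-gene
   regulator counts, top-regulator coverage of the module and Venn-style
   co-regulation counts; per-condition DEG tables from other diseases give
   the module's cross-condition coverage and recurrently DE genes;
   hypergeometric enrichment against GMT gene sets replaces web-service
   lookups.

The synthetic generator plants all of this structure — a correlated gene
block (single latent factor, loading √r), a shared DEG core, exponential
survival whose hazard follows the latent sample cluster, and TF/miRNA maps —
with defaults mirroring the motivating study's conditions (6 datasets,
140 + 51 samples, 84-gene block at r = 0.9, true hazard ratio 2.36).

## Worked example

```python
import coexmod as cm

syn = cm.SyntheticConfig(seed=1)                # the default study conditions
datasets, truth = cm.generate_two_state_dataset(syn)
survival = cm.generate_survival(syn, truth.cluster_labels)
result = cm.run_pipeline(datasets, cm.PipelineConfig(rng_seed=1),
                         survival=survival)

top = result.top_module
rec = cm.recovery_metrics(top, truth)
print(f"mutual DEGs: {len(result.mutual_degs)}")
print(f"top module: {top.n_nodes} genes, density {top.density:.3f}, "
      f"avg connectivity {top.avg_connectivity:.1f}")
print(f"recovered {rec['recovered_fraction']:.0%} of planted genes, "
      f"{rec['intruder_fraction']:.0%} intruders")
r = result.dc_report
print(f"module density diseased -> healthy: "
      f"{r.density_diseased:.3f} -> {r.density_healthy:.3f}, "
      f"permutation p = {r.p_value:.3f}")
print(f"hazard ratio between expression clusters: "
      f"{result.survival_result.hazard_ratio:.2f}")
```

Output:

```
mutual DEGs: 200
top module: 84 genes, density 1.000, avg connectivity 41.5
recovered 100% of planted genes, 0% intruders
module density diseased -> healthy: 1.000 -> 0.055, permutation p = 0.005
hazard ratio between expression clusters: 2.29
```

The 84-gene planted block is recovered exactly; its co-expression collapses
in the healthy state (density 1.000 → 0.055, the residual being the ~5%
false-positive edge rate built into the empirical cutoff); the permutation p
is the minimum attainable with 199 shuffles; and the Cox hazard ratio
estimate is near the planted 2.36 (the sign of the cluster labelling is
arbitrary, so a seed may report the reciprocal).

The same pipeline is scriptable from the shell:

```bash
coexmod simulate --out study/ --seed 1
coexmod run-all  --out run/   --seed 1     # writes run/report.json
```

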