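# Methods

This note documents the models and procedures implemented in `coexmod`, the
assumptions behind them, the defaults and why they were chosen, what the
synthetic generator does and does not emulate, and the numerical choices a
maintainer would want written down.

## Differential expression

Each dataset is analyzed independently with a two-group moderated
t-statistic. The model assumes log2 expression values that are
approximately Gaussian within each state and a gene-wise variance σ²_g
drawn from a scaled inverse-chi-square prior with hyperparameters (d₀, s₀²).
The posterior variance s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g) replaces the
pooled variance in the t-statistic, and the null reference is t with
d₀ + d_g degrees of freedom.

The hyperparameters are estimated by matching the empirical mean and
variance of log s²_g to the scaled-F prior predictive: with
e_g = log s²_g − ψ(d_g/2) + log(d_g/2), the excess variance
var(log s²) − mean ψ′(d_g/2) equals ψ′(d₀/2); d₀ comes from inverting the
trigamma (bracketed Brent on [1e-8, 1e8]) and s₀² from the bias-corrected
mean of e_g. When the excess is non-positive — the gene variances are no
more dispersed than sampling alone explains — d₀ = +∞ and s₀² is the
df-weighted mean variance, so the degenerate identical-variance case returns
the common variance exactly. Zero-variance genes are excluded from the fit
with a warning; a gene with zero variance and zero mean difference gets
t = 0, p = 1 rather than an error.

P-values are adjusted by Benjamini–Hochberg step-up (delegated to
`statsmodels.multipletests`; an independent brute-force implementation backs
the tests). A gene is DE when p_adj < 0.01 and its linear fold change
2^(Δ log2 mean) is > 2.0 or < 0.5. Fold change is computed from the log-scale
mean difference, the standard convention for summarized microarray data.
The mutual-DEG intersection across datasets deliberately ignores direction:
regulation patterns can disagree between cohorts while the same genes keep
being called.

## Network construction

Samples are pooled by state across datasets and quantile normalized over
the **full** shared gene universe — renormalization acts on whole arrays,
as array-level summarization does — and only then restricted to the mutual
DEGs. Normalizing after restricting to a few hundred genes injects rank
granularity noise of order 1/√G that visibly attenuates strong
correlations; at array scale (tens of thousands of probes) the same step is
innocuous. Tied values within a sample share the mean of their target
quantiles.

Edges connect gene pairs whose Pearson correlation exceeds a cutoff derived
from the empirical PCC distribution: fit (μ̂, σ̂) by moments and set
high = μ̂ + z₀.₉₇₅σ̂, low = −high. The mirrored negative cutoff matches the
reference analysis' symmetric bounds; the asymmetric μ̂ − zσ̂ variant is
available via `symmetric=False`. Applied to the reference distribution
(mean 0.05, SD 0.39) the formula gives 0.8144, i.e. 0.814 at three decimals,
a 0.001 discrepancy from the printed 0.815 whose exact derivation is not
stated; the formula, not the constant, is implemented, and the discrepancy
is asserted in the test suite. Note the cutoff marks the extreme ~α of
*whatever* pair population it is fed: if a planted module dominates the
pair population, the cutoff chases the block itself. The procedure assumes
co-expressed modules are a small minority of all gene pairs (in the
reference data: C(84,2) of C(698,2) ≈ 1.4%).

Genes with no super-threshold partner are dropped from the network (the
reference node counts imply the same). Topology metrics: density
2m/(n(n−1)); mean local clustering with degree<2 nodes contributing 0;
unnormalized Brandes betweenness; scale-free fit as R² of log10 frequency on
log10 degree over distinct positive degrees (raw frequencies, no log
binning); dual-metric hubs as the union of top-5 by degree and top-5 by
betweenness with rank-5 ties included.

## Module detection (MCODE)

Stage 1 weights each vertex by k\*·density of the highest k-core of its
closed neighborhood (vertices under the degree cutoff, or whose
neighborhood has no 2-core, weigh 0). Stage 2 grows a complex from the
highest-weight unvisited seed, admitting neighbors with weight ≥
(1 − node_score_cutoff)·w(seed), breadth-first, each vertex in at most one
complex. Stage 3 discards complexes lacking a 2-core; haircut iteratively
removes degree-1 vertices; fluff (off by default) adds boundary vertices
with dense closed neighborhoods. Parameters default to the published MCODE
defaults (degree cutoff 2, node score cutoff 0.2, k-core 2, haircut on,
fluff off, max depth 100) since the reference analysis does not report its
settings. All tie-breaks (seeding, neighbor order, ranking) are
lexicographic by gene symbol, making results order-independent.

Modules are ranked by **average connectivity = edges/nodes**: the reference
module's printed score satisfies 3078/84 = 36.6 exactly under this
convention. The classical MCODE score (density × n) is computed and
reported alongside. Selection keeps modules with ≥ 10 nodes, average
connectivity ≥ 10 and density ≥ 0.80.

One property worth knowing: the top module's density can fall below the
whole graph's. If the highest-weight vertex's neighbors all miss the score
threshold, its singleton complex is discarded by the 2-core filter but the
vertex stays consumed, and the runner-up complex may be sparser than the
graph (smallest example: a 4-wheel-like graph on 5 nodes). This is inherent
to the algorithm, not a defect of this implementation; the property test
documents the exception.

## Differential co-expression

The selected module is projected onto both state networks **keeping all
module genes** — densities use n = module size in both states. This is the
convention that reproduces the reference healthy-state density
(100 edges over C(84,2) pairs = 0.029, not 100/C(48,2)).

Significance: the qualitative claim "topology significantly altered" is
operationalized — this package's own addition — as a state-label
permutation test on T = density_diseased − density_healthy, with the PCC
cutoff recomputed inside every shuffle because the cutoff is data-derived
and therefore belongs inside the null. p = (1 + #{T_perm ≥ T_obs})/(n_perm+1)
with n_perm ≥ 99 (default 199). A module is classified differentially
co-expressed when Δdensity ≥ 0.5 **and** p ≤ 0.05 (both configurable; the
effect-size floor keeps trivially small but "significant" changes out).
Because T is a scaled integer (edge-count difference), exact ties make the
permutation test conservative on very small designs; the calibration test
uses a 60-gene universe with a 20-gene module, where tie mass no longer
dominates and the type-I error sits at the nominal 5%.

## Prognosis

Module-gene expression of the diseased samples is z-scored per gene
(raw-centered mode available), decomposed by SVD, and each component's sign
fixed by making its largest-magnitude loading positive (removes the SVD sign
indeterminacy, so repeated runs are bit-identical). Samples are clustered on
the first three components by k-means (Lloyd, Euclidean, 50 seeded random
restarts, best within-cluster SS kept); labels are canonicalized so cluster 1
contains the lexicographically smallest sample id — which means the
**orientation** of the reported hazard ratio is arbitrary (a run may report
HR or 1/HR; the acceptance script aligns against the planted clusters before
reporting).

Survival: product-limit Kaplan–Meier per cluster; the standard two-group
log-rank test (hypergeometric variance, χ² with 1 df; zero events ⇒ p = 1
with warning); Cox proportional hazards with the cluster indicator as the
single covariate, Breslow tie handling, Newton–Raphson to |Δβ| < 1e-8,
Wald CI and p. Breslow (not Efron) because the group-indicator model with
few ties is insensitive to the choice and Breslow is verifiable by hand;
the test suite cross-checks against lifelines on tie-free data. Monotone
likelihoods (all events in one arm, |β| > 15) raise an error recommending
exact or penalized methods.

## Regulators, screening, enrichment

Per-gene TF and miRNA counts are exact tallies. Top regulators are ranked
by module-target count (ties lexicographic); coverage is the fraction of
module genes hit by the union of the top-k target sets. Venn region counts
for 2–4 regulators are exclusive and sum to the union. Cross-condition
coverage always uses the full module size as denominator. Recurrently DE
genes (≥ 3 conditions by default) carry each condition's own direction and
linear fold-change magnitude; no cross-condition consistency is enforced.
Gene-set enrichment is the one-sided hypergeometric upper tail
P(X ≥ overlap) — identical to the one-sided Fisher exact test on the 2×2
table, hence a single exact code path — with BH across sets and a 0.05
adjusted-p flag.

## Synthetic data generator

What it emulates: (i) several datasets sharing one gene universe and one
core of truly differential genes (log2 shift ±2, residual SD 0.5); (ii) a
planted block of genes driven by a single latent factor per diseased sample
with loading √r, giving within-block pairwise PCC = r (default 0.9) in the
diseased state and independent noise (r = 0) in the healthy state; (iii)
survival times that are exponential with hazard 1/60 per month in latent
cluster 1 and 2.36-fold higher in cluster 2, where the latent cluster is
the **sign of the module factor z** — so the planted prognosis signal is
exactly the module's expression level, and PCA + k-means can recover it;
(iv) administrative censoring at the empirical 70% quantile of event times
(censoring_rate 0.30); (v) regulator tables in which six TFs co-regulate a
shared pool of ⌈0.89·84⌉ module genes while 40 miRNAs target small random
subsets (1–8 genes).

Defaults mirror the motivating study where stated: 6 datasets, 140 diseased
+ 51 healthy samples in total (split as evenly as possible across datasets),
an 84-gene block, hazard ratio 2.36. Where the study gives no number, one
desk-scale choice was made: 4,000 genes with a 5% shared DEG core
(200 genes — proportionally consistent with 698 mutual DEGs out of a ~20k
genome; per-dataset-specific DEGs are not modeled because the intersection
removes them anyway); baseline log2 intensities uniform on (4, 14), with
DEG-core baselines drawn from the central sub-range so shifted genes stay
inside the globally dense intensity region (on real arrays DE genes move
within the bounded intensity range; without this, quantile renormalization
flattens the profiles of genes stranded in sparse tails). Defining the
latent cluster as sign(z) rather than adding a bimodal factor keeps the
within-block PCC equal to r (a two-component factor would inflate it).

What it does **not** emulate: probe-level effects, intensity-dependent
noise, saturation, array outliers, correlated background modules, overlap
between module and non-module co-expression, or dataset-specific DEG sets
(a per-dataset batch shift is available but off by default). Passing tests
therefore show the pipeline recovers the planted structure under clean
factor-model conditions at study-scale sample sizes — not that it would
recover modules from arbitrary real microarray data.

## Problem sizes used in verification

The test suite and acceptance script run at the generator defaults
(4,000 genes × 191 samples, 20 seeds for the recovery and null-control
sweeps), 500 replicates for permutation type-I error and Cox CI coverage,
2,000 replicates (or 2,000 null genes) for log-rank and moderated-t
calibration, exhaustive graph enumeration up to 5 nodes plus seeded random
graphs on 6–8 nodes for the brute-force oracle checks, and full enumeration
up to a 12-gene universe for the hypergeometric oracle. These sizes were
chosen so every check carries statistical weight while the whole suite runs
in about two minutes.

## Known limitations

- The empirical cutoff assumes near-normal PCC values and a small
  co-expressed minority; both can fail on heavily structured data.
- Mutual DEGs require presence in **every** dataset; one discordant cohort
  empties the intersection (a warning, not an error).
- The moderated-t model has no covariates, pairing or multi-factor designs.
- Cox inference is asymptotic Wald; small-sample or separated data need
  exact/penalized methods the package intentionally does not provide.
- Reproducing the motivating study's dataset-level numbers (698 mutual
  DEGs, network sizes, HR 2.36 on clinical data, 74.8% PCA variance)
  requires its microarray accessions, which are not shipped; the package
  reproduces the method and its printed worked-example statistics, and
  validates recovery on synthetic ground truth instead.
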