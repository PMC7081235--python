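# Methods

`stressregulon` analyses multi-genotype, multi-stress RNA-seq time courses of
the kind used to dissect transcriptional co-regulators: a wild type and
several regulator mutants, each exposed to three stress experiments sampled
at a control, an early and a late time-point, with biological replicates.
This note describes the statistical model of every stage, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions.

## Differential expression

Counts for gene *g* in sample *i* are modelled as negative binomial,

> y_gi ~ NB(mean μ_gi, dispersion α_g),  μ_gi = s_i · exp(β_g(i)),

with s_i a per-sample size factor and one β level per contrast group (log
link with offset log s_i). Because a two-group design is saturated, the GLM
decomposes into two independent one-parameter MLE problems, solved by a
vectorized Newton iteration per group. The Wald statistic for the log
fold-change is

> z = (β_B − β_A) / sqrt(1/I_A + 1/I_B),  I = Σ_i μ_i / (1 + α μ_i),

referred to the standard normal, two-sided. This parametrization makes
swapping the contrast sides an *exact* sign flip in floating point — a
property the test suite asserts bitwise.

**Dispersions** are method-of-moments estimates on size-factor-normalized
counts, α̂ = (s² − μ̄)/μ̄² with s² the pooled within-condition variance,
floored, shrunk halfway in log space toward a trend α(μ) = a₀ + a₁/μ fitted
across genes by least squares, and clipped to [1e-4, 10]. The 50/50
log-space shrinkage stabilizes 4-replicate estimates without a full
empirical-Bayes machinery; the acceptance surface is calibration (type-I
error at nominal 0.05 within [0.03, 0.07] under the global null with known
dispersion) and recovery, not bit-compatibility with any reference package.
No fold-change shrinkage, no independent filtering beyond the detection
rule, and no outlier replacement are applied — they add nondeterminism
without changing what the tests measure.

**DEG calls** use BH-adjusted p ≤ 0.01 and |log2FC| ≥ 0.5, both boundaries
inclusive. Genes failing the detection filter (≥ 2 reads in ≥ 2 samples)
never enter testing.

## Preprocessing

Size factors are median-of-ratios over genes with all-positive counts,
rescaled to geometric mean 1. The variance-stabilizing transform is the
shifted log, log2(count/sf + 1): its contract here is the stabilization
property (per-gene SD approximately independent of mean on NB data, checked
as a ≥ 5-fold slope reduction), not the bit-level values of the
fitted-dispersion VST in reference DE packages. PCA operates on the
sample × gene matrix with genes centered but not scaled — the VST already
equalizes variances, and scaling would double-correct. Row z-scores use the
sample SD (ddof = 1); constant rows are dropped with a warning rather than
erroring, since they carry no clustering signal.

## Regulons and clustering

Per stress and phase, the wild type's phase-vs-control DEG sets are built;
the common regulon of a phase × direction is the three-way intersection
across stresses (EARLY UP, EARLY DOWN, LATE UP, LATE DOWN), with all seven
Venn region counts reported per direction. Regulons are built from the wild
type only; mutant data enter only through the response stage.
Co-expression clustering is agglomerative Ward/Euclidean on z-scored
expression, cut at k = 5; genes are sorted lexicographically before linkage
so the partition is independent of input order. Boxplot summaries use
linear-interpolation (type-7) quantiles with whiskers at the most extreme
point within 1.5 × IQR.

## Non-responsiveness and its mechanism

A regulon gene is **non-responsive** in a mutant when it fails the full DEG
criterion (significance AND magnitude AND direction) in the mutant's own
early-vs-control contrast for that stress — reusing the single DEG
definition rather than inventing a second threshold. Non-responsive genes
are split by the mutant-vs-wild-type contrast at the control time-point of
the same growth system:

* **LR, loss of repression** — already significantly shifted in the
  regulon's direction before stress (the gene is de-repressed and has
  nowhere left to go);
* **LA, loss of activation** — wild-type-like pre-stress level, but the
  stress induction fails.

LR and LA partition the non-responsive set by construction. Overlap
percentages in the antagonism tables are rounded half-up to integers.

## Enrichment

The inclusive upper hypergeometric tail P(X ≥ x) is the over-representation
p-value for annotation/TFBS screens (term targets intersected with the
background first). Against a genome-scale background the significance
threshold is raw p < 0.01; for small backgrounds (testing non-responsive
sets against their own regulon) a permutation null is used instead:
overlaps with uniform query-sized subsets of the background, 10,000
permutations by default, add-one estimator p = (1 + #{perm ≥ obs})/(1 + n),
ties counted as exceeding (conservative), significance at p < 0.05.

Per-family summaries count significant terms over tested terms; the wave
grouping labels each family early-only / early-and-late / late-only within
the UP contexts and, independently, within the DOWN contexts.

The **module co-occurrence test** asks whether a gene set (e.g. a mutant's
non-responsive genes) concentrates in a network module *within* a reference
population (e.g. the EARLY UP regulon): per module,
p_adj = min(1, m · tail(x; K, n, N)) with N the population size, K the
module's genes inside the population, n the query size, x the overlap, and
m the Bonferroni batch size (all gene-set × module combinations tested
together). Two tail conventions are exposed: the inclusive tail (library
default — it never degenerates) and the exceedance tail P(X > x), the upper
tail of R's `phyper` without the off-by-one shift, which is the convention
of the established batch workflow this pipeline reproduces; the exceedance
tail is 0 when the overlap saturates, so it is only meaningful inside a
Bonferroni batch. `focus_modules` keeps modules with p ≤ 1e-5 and ≥ 50
genes. A deliberately simple module detector (thresholded |Spearman|
correlation components) is provided as plumbing only; real module
assignments from a consensus-network/community-detection pipeline are
consumed as an input table.

## Synthetic data

The generator emulates the study design: 5 genotypes (wild type + 4
mutants), 3 stress experiments × (control, early, late), 4 replicates, NB
counts with per-gene log-normal baselines and dispersions, and library size
factors uniform in ×[0.7, 1.3] to exercise size-factor estimation. Planted
structure: four 50-gene common regulons carrying |log2FC| = 2 in all three
stresses at their phase; 30 stress-specific early responders per stress (so
the cross-stress intersection is a real filter); per-mutant non-responsive
fractions of the EARLY UP regulon {med9 0.30, med16 0.50, med18 0.25,
cdk8 0.30} with LR shares {med16 0.50, others 0.12}, making med16 the
LR-dominant genotype; TF target maps concentrated (0.8) in family-designated
regulons; and a gene → module partition concentrating each regulon in one
module (0.8). LR genes are de-repressed at control by the planted effect
and sit at the wild-type stressed level under stress (early/control ratio
1); LA genes simply lose the induction.

Defaults (the small preset): 2,000 genes at a mean depth of 2,500 reads per
gene (5e6 total), dispersions log-normal with median 0.04 and log-SD 1.0
clipped to [0.01, 1] — the center of gene-wise dispersion estimates typical
for replicated bulk RNA-seq, with a tail of noisy genes. One global seed
feeds independent named substreams per stage, so fixtures are bit-
reproducible and single stages can be varied in isolation. A paper-scale
preset (24,000 genes, realistic library sizes, regulon sizes in the
hundreds) exists for heavier experiments; the tests and the reproduction
script all run at the small preset.

**What the generator does not emulate:** batch effects and growth-system
differences, time-autocorrelation beyond the three-level time factor,
gene–gene correlation beyond the planted block structure, stress-specific
LATE responders, per-stress variation in a mutant's non-responsive set
(mechanisms are planted per mutant, not per mutant × stress), and
compositional/length biases. Passing recovery tests therefore demonstrates
that the pipeline's inference is correct under its own model assumptions at
realistic signal-to-noise — not that real tissue data would behave this
cleanly.

## Numerical conventions and degenerate inputs

Result TSVs serialize floats at 6 significant digits; a JSON manifest
records the seed and a config hash so reruns are bit-identical. Group means
with zero total counts get a deterministic half-count pseudo-fit (keeps the
Wald statistic finite); genes all-zero in both groups report log2FC 0,
p = 1. BH inputs containing NaN raise. Hypergeometric arguments are
validated as feasible integers. Permutation p-values can never be 0 by the
add-one estimator. Cluster ids and module ids are renumbered by
lexicographically smallest member so outputs are order-independent.

## Known limitations

* The NB test is a plain Wald test: at very small counts it can be mildly
  anticonservative, and no fold-change shrinkage means noisy log2FCs for
  weakly expressed genes.
* The shifted-log VST under-corrects genes with very large dispersion.
* The dispersion trend a₀ + a₁/μ is fitted by unweighted least squares and
  can be pulled by outliers in small gene sets.
* The permutation test currently permutes gene labels uniformly; it does
  not stratify by expression level or gene length.
* The simple correlation module detector is plumbing, not a substitute for
  consensus-network community detection.
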