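# Methods

This note documents the statistical models, the synthetic data generator,
the numerical choices and the known limitations of `communitylens`.

## Experimental design model

The unit of analysis is a **condition**: a nonempty membership set over the
species roster (default B, F, P), a producer genotype (`WT` or `dkec`, the
antibiotic-cluster deletion), and a producer inoculum level (`standard` or
`low`). The default design covers the seven wild-type membership sets, the
four producer-containing sets with the `dkec` genotype, and the
low-inoculum producer–receiver pair (`FP_PLI`), each with 4 biological
replicates. Per-species gene × sample integer count matrices are the input;
reads are assumed already partitioned and counted per genome upstream.

## Low-expression filter

For each focal species, genes are screened over its four wild-type core
conditions (alone, two pairwise, community). Two readings of "at least 10
reads across all conditions" are implemented:

* `sum` (default for DE): total count over all core-condition samples ≥ 10.
  The weaker filter; the exact count test downstream models low counts
  directly, so marginal genes cost little and maximize power.
* `each`: per-condition totals must each reach 10. Used by the
  ratio/additivity analysis (below), where log-ratio comparisons are only
  meaningful for genes quantifiable in every condition compared.

The filter is idempotent and order-preserving; library sizes are computed
after filtering, on the matrix the DE engine sees.

## Normalization

`cpm_normalize` is plain counts-per-million (each column sums to 1e6)
with an optional per-sample normalization-factor hook. The pipeline
supplies median-of-ratios factors by default (`median_of_ratios_factors`):
for each sample, the median over always-positive genes of the ratio of the
gene's count share to its geometric-mean share across samples, rescaled to
geometric mean 1. Rationale: when 10–20% of genes respond with 3–16× fold
changes, the total transcript output of a condition shifts by tens of
percent; under plain cpm every unresponsive gene's share then shifts by the
same factor, and the DE test flags null genes wholesale (composition bias —
the problem TMM-type normalization exists to solve). Median-of-ratios
anchors the scale on the unresponsive majority; with fewer than 10
always-positive genes the factors fall back to 1. Setting
`normalization="total"` restores plain cpm.

## Differential expression

Counts for gene *g* are modeled NB(μ, φ) with variance μ + φμ²;
per-sample counts are scaled to the geometric-mean effective library size.

**Dispersion.** Per gene, a method-of-moments estimate pooled over groups
((s² − m)/m², weighted by residual df), shrunk toward the all-gene median
with `prior_weight` = 20 pseudo-observations and clipped at 0. Groups need
≥ 2 replicates unless `common_only` is set, in which case all genes receive
the common value. The weight 20 makes single-comparison estimates stable at
n = 4 while leaving genuinely high-dispersion genes above the median.

**Exact test.** The within-group sums of n iid NB(μ, φ) variables are
NB(nμ, φ/n). Conditional on the two-group total T, the null split is
beta-binomial with shape parameters n₁/φ and n₂/φ — free of μ — and as
φ → 0 it reduces to Binomial(T, n₁/(n₁+n₂)), so the test reduces to the
exact binomial test (verified to < 1e-6 against `scipy.stats.binomtest` on
all totals ≤ 50). The two-sided p-value sums the probabilities of all
splits no more probable than the observed one (ties included, relative
tolerance 1e-9). A zero total gives p = 1. Scaled group sums are rounded to
the nearest integer before conditioning.

**Fold change.** log2FC = log2((mean cpm treatment + 0.5) / (mean cpm
baseline + 0.5)); positive means higher in the more complex condition. The
pseudo-count 0.5 cpm guards against zero means and is configurable.
Swapping baseline and treatment negates every log2FC and leaves p-values
unchanged (the conditional null is mirror-symmetric).

**FDR.** Benjamini–Hochberg step-up per comparison (statsmodels), verified
against hand-computed fixtures.

## Classification and higher-order regulation

From the two category-I tables (no fold-change cutoff, following the global
scatter analysis of the source design): significant in exactly one →
partner-only up/down; in both → dual-same (signs agree) or dual-opposite;
neither → none. The classes partition the tested universe. "Regulated"
gene sets for downstream analyses apply the additional |log2FC| > 1 cutoff
with strict inequality. Dual classes require significance in *both*
comparisons — the stricter of the two possible readings, stated rather than
guessed. Higher-order (third-member) regulation is category-II significance
of partner-specific genes with no fold-change cutoff, to capture subtle
effects. Community-specific genes are the named query: no category-I
significance, category-II significance in ≥ 1 comparison, and >2-fold
category-III regulation.

## Additive ("Sum") null

Per gene, expression ratios to monoculture are pseudo-counted condition
means: r = (mean cpm + 0.5)/(mean cpm alone + 0.5). The additive prediction
is the product of the two pairwise ratios (log-scale sum); the typeset
source formula is ambiguous, and the product reading is the only
dimensionally coherent one. Community-vs-pairwise and community-vs-Sum
contrasts use an exact paired Wilcoxon signed-rank test: zero differences
dropped (Wilcoxon's original convention), average ranks for ties, full
enumeration of the signed-rank distribution via dynamic programming for
n ≤ 25 (doubled ranks are integers), normal approximation with continuity
and tie corrections above; two-sided p = 2·min(P(W ≤ w), P(W ≥ w)) capped
at 1. Bonferroni correction is over the contrasts in one report panel by
default, with a `family_size` override for bespoke families.

Two design points matter for calibration, both found empirically during
development and adopted as package policy:

1. **Quantifiability.** Compound-regulated genes (e.g. down 1.5–4 log2
   with *each* partner, hence up to 8 log2 in an additive community) fall
   to near-zero counts at the receiver's suppressed coculture depth; there
   the pseudo-counted log ratio of a mean of a few counts is biased toward
   zero and the measured community level departs from the Sum even when
   the community response is exactly additive. The additivity analysis
   therefore runs on the per-condition (`each`) filter so every gene is
   quantifiable in all four conditions. Simpler corrections (evaluating
   the prediction through the same pseudo-count floor; parametric-bootstrap
   per-gene null offsets) were tested and found to over- or under-correct,
   so the quantifiability requirement — standard practice for ratio
   analyses — was preferred.
2. **Directional panels.** Up- and down-regulated dual gene sets are
   tested as separate panels. Under a dominant-partner community rule the
   departures from Sum of up- and down-regulated genes have opposite
   signs; pooling them cancels in a signed-rank test and hides real
   non-additivity.

## Mutant-reversal attribution

For a receiver X, `fc_wt` is the category-I fold change X vs X+P(WT) and
the mutant contrast is oriented **baseline = wild-type pairwise, treatment
= mutant pairwise**, i.e. `fc_mut = log2(XP_dkec / XP_wt)`. With this
orientation a gene whose wild-type regulation disappears in the mutant
coculture shows `fc_mut ≈ −fc_wt`: reversal appears as sign opposition and
the two vectors are strongly anticorrelated. Sign conventions are the main
foot-gun of this analysis, so the orientation is stated everywhere it
matters. A gene is antibiotic-dependent when |fc_wt| > 1 at fdr < 0.05
*and* the mutant contrast is significant (fdr < 0.05, no fold-change
cutoff) with opposite sign; the attributable fraction's denominator is the
eligible (>2-fold, significant) set. Spearman ρ uses average ranks
(scipy), cross-checked against a rank-then-Pearson oracle.

## Enrichment

The enrichment index of a COG category in a gene set is (category
frequency in set)/(category frequency in genome); multi-letter genes count
once toward each letter, genes without letters form the first-class
pseudo-category `none` (unannotated genes are a headline result in this
kind of analysis, not a nuisance). Significance is a two-sided Fisher exact
test (switchable sidedness) on the 2×2 in-set × in-category table, with
Bonferroni over the categories tested. Shared-annotation tables normalize
names (case-fold, whitespace-collapse) and join multiple genes with "; ";
the Jaccard similarity uses gene-set sizes with the shared-annotation count
as intersection — the convention pinned by reproducing both published
overlap values (0.025 and 0.024) from their printed counts.

## qRT-PCR

One-pass two-sided Grubbs test on technical replicates (G = max|x − x̄|/s
against the t-based critical value, any n ≥ 3; no iterative re-testing —
re-testing a quadruplicate's remaining triplet is statistically fragile),
then 2^−ΔΔCt against the sample's reference gene and a control sample.
Grubbs α defaults to 0.05. No amplification-efficiency correction.

## Synthetic community generator

`simulate_community(cfg, seed)` emulates the study design the analysis
assumes; the same seed gives bit-identical output.

* **Baseline expression:** per gene, log-normal(0, σ = 1.6) relative
  abundance; a fraction `expressed_fraction` = 0.78 of genes is expressed,
  the rest are scaled by 2e-4 so they (almost always) fail the 10-read
  filter. The σ and scale are realism choices: they give a median
  expressed gene ~100–300 cpm with a heavy high tail, and a filter pass
  rate tracking the expressed fraction within ±3%.
* **Planted classes:** per gene, multinomial over none (0.85),
  partner-specific up/down (0.025 × 4), dual-same up/down (0.02 × 2),
  dual-opposite (0.01) — 15% responders. Effect magnitudes are uniform on
  [1.5, 4] log2, drawn once per gene/partner and reused across conditions
  so community rules are well defined.
* **Community rule per gene:** additive (0.6), dominant-partner (0.3, the
  producer for receivers), muted (0.1). Pairwise effects apply whenever the
  partner is present; with both partners present the rule decides.
* **Antibiotic dependence:** 80% of producer-responsive receiver genes are
  koreenceine-dependent; under `dkec` their producer effect is nulled
  (default) or sign-reversed. Eleven producer marker genes, drawn from the
  above-median-expression stratum (the cluster is actively transcribed in
  monoculture), are forced to ~zero counts under `dkec` and down-scaled
  12.5-fold under low inoculum.
* **Inoculum gating:** the producer's planted responses to the receiver F
  are active only at low inoculum, except for a 1% always-on subset —
  reproducing a ~100-fold jump in the producer's DEG count when it starts
  as a minority.
* **Depth coupling:** expected mapped reads per species per condition
  mirror the design's numerical-dominance pattern — receivers deep in
  monoculture (B 4.0M, F 1.7M, P 2.3M), the producer dominant in coculture
  (17.5M), B at 2.9M, and F suppressed to 0.4M wherever the wild-type
  producer is present at standard inoculum. Condition means are rescaled so
  expected column sums hit the depth target; realized library sizes land
  within ~20%. Depth is modeled at the library level, not by simulating
  read competition. A global `depth_scale` supports scaled-down designs
  with matched per-gene coverage.
* **Noise:** counts are NB with dispersion φ = 0.1 (Poisson at φ = 0);
  mean/variance follow the NB contract within 2%/10% at 10⁴ draws.
* **Truth table:** per gene — planted class, per-partner effects, community
  rule, dependence and gating flags, plus `class_catI`, the class
  recoverable from wild-type standard pairwise contrasts (gated effects
  removed), which is what recovery scoring compares against.

What the generator does **not** emulate: read-level artifacts (mapping
ambiguity, positional bias), correlated gene programs (effects are
independent across genes), growth dynamics (abundance enters only through
depth), and batch structure. Passing recovery tests therefore demonstrate
the statistical machinery under the design's count structure, not
robustness to upstream artifacts.

## Problem sizes and determinism

The validation suite uses the full default genome sizes (6155/5207/5854
genes) for the main recovery scenario, 2000-gene × 20-replicate all-null
simulations for FDR control, and 20 four-condition replicates for the
Sum-test consistency checks; smaller scaled designs (via `depth_scale`)
cover I/O, CLI and determinism. Pipeline outputs are a pure function of
(inputs, config): rerunning with the same seed and config reproduces every
output file byte for byte, and each output directory carries the config
hash.

## Known limitations

* The NB exact test conditions on rounded rescaled totals; with very
  unequal library sizes the rounding can shift a p-value slightly (the
  swap-symmetry and binomial-limit properties still hold).
* Dispersion moderation with weight 20 over-shrinks genes whose true
  dispersion is far from the median when replication is minimal; this
  trades a small power loss for stable null behavior.
* The attributable-fraction estimator is slightly conservative (~3–5
  points below the planted fraction at default settings) because
  dependence requires significance in the mutant contrast; its power is
  bounded by the mutant-condition depth.
* Median-of-ratios factors assume a majority of unregulated genes per
  sample; designs where most of the transcriptome responds violate this.
* The Sum analysis inherits the pseudo-count's compression of extreme
  fold changes; fold-change summaries of strongly regulated small gene
  sets (e.g. the antibiotic locus) are typically 10–20% below the planted
  magnitude.
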