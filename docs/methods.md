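# Methods

This note documents the models behind `leukotype`, the choices made where
the design was genuinely open, and what the synthetic-data validation does
and does not establish about real data.

## Synthetic cohort model

The generator produces every input the pipeline consumes, with ground
truth attached to each record.

**Counts.** Gene counts are negative binomial in the mean/dispersion
parameterization, Var = μ + αμ², drawn as a gamma–Poisson mixture with a
single cohort-wide dispersion α (default 0.1, a typical bulk RNA-seq
value). Per-gene relative abundances are log-normal; per-sample library
sizes are uniform on 80–130 million read pairs (the depth range of a
modern total-RNA diagnostic run) scaled by `depth_scale` (default 1/1000)
so matrices stay desk-sized. Subgroup signatures shift `n_signature_genes`
(default 200) by ±`signature_log2fc` (default 1.5; the DUX4-like
expression-defined subtype uses 2.0), half up and half down so that
library composition stays balanced.

**Blast dilution.** A sample's observed profile is the mixture
`blast_fraction × leukemic + (1 − blast_fraction) × baseline`; fusion read
support scales linearly in blast fraction and depth. This is the simplest
mixture consistent with bulk sequencing of a partially leukemic marrow
sample and makes expected fusion support monotone in both drivers, which
the low-blast sensitivity property tests exploit (blast fractions 0.07,
0.2, 0.33, 1.0).

**Fusion calls.** True fusions receive Poisson support with expectation
`fusion_support_per_100m × (library / 100e6) × blast_fraction` (default 60
reads at full blasts and 100M pairs, in the range observed for expressed
diagnostic fusions); calls drawn at zero support are not emitted —
"undetected". Spurious chimeras (default 2 per sample) carry 1 + Poisson(2)
reads and are drawn from the non-driver gene background by default:
whitelist genes are curated precisely because artifact chimeras involving
them are rare, and a uniform noise model would plant artifacts on curated
genes at a rate no curated list would tolerate. `noise_gene_pool="all"`
restores the uniform model for stress testing.

**Variants.** Hotspot drivers are constructed to pass the full filter
cascade; passengers look pathogenic; each planted artifact violates
exactly one named filter rule (recorded in the truth table), with
cohort-recurrent artifacts planted in exactly
⌈`artifact_cooccurrence_fraction` × n⌉ samples so the recurrence rule is
deterministically triggered. A-to-I editing variants (default 30 per
sample, reflecting the dominance of editing in RNA-derived call sets) are
strand-balanced T>C / A>G events that survive the caller-level filters
(AF drawn in (0.1, 0.6]) but mostly look benign to the strict annotation
stage (silent/intronic classes, low CADD).

**What the generator does not emulate:** read-level artifacts, alignment
and quantification noise, splice-graph-realistic breakpoints, correlated
gene–gene expression structure, germline contamination of allele
fractions, or enhancer-hijacking fusions at untranscribed loci (e.g. *IGH*
partners), which RNA-seq genuinely misses. Passing tests therefore show
the pipeline's logic and statistics are sound under its stated model, not
that a real cohort would reach the same accuracy.

## Differential expression

The test is a log-link negative-binomial Wald test fitted by vectorized
IRLS over all genes simultaneously, with median-of-ratios size factors as
offsets (genes with any zero excluded from the geometric-mean reference).
It is deliberately an approximation in the DESeq2 family rather than a
re-implementation: its acceptance surface is simulation calibration —
type-I error of the null in [0.02, 0.08], BH false-discovery proportion
under planted balanced effects, and effect-size recovery — not equality
with any package.

Dispersion is a leverage-corrected method-of-moments estimate from the
fitted means, `α̂ = Σ[(y − μ̂)² − (1 − h)μ̂]/μ̂² / (n − p)` with hat-matrix
leverages h; without the (1 − h) correction the estimate is badly biased
downward whenever p/n is large (the paired design has 7 parameters for 12
samples) and the test becomes anticonservative. Per-gene estimates are
shrunk (geometric mean in log space) toward a robust parametric trend
α(μ) = a₀ + a₁/μ. The Wald statistic is referred to a t distribution with
n − p degrees of freedom, slightly conservative relative to the normal
reference at small n.

The paired tube model adds free per-patient intercepts and one condition
coefficient, so any patient-level multiplicative offset is absorbed
exactly; fold changes are reported PAXgene vs EDTA by default. Genes enter
only with mean raw count strictly above 10.

## Normalization

GC normalization is within-sample: a lowess fit (span 0.5) of
log(count + 0.5) on gene GC fraction is subtracted and the sample's mean
log signal re-added, then values return to the count scale. The anchoring
makes the operation a pure trend removal — per-sample mean log signal is
preserved to machine precision. Variance stabilization is
log2(count/size-factor + 1); exact invariance of a sample's transformed
values under depth doubling holds only up to the 1/n log2 drift introduced
through the shared geometric-mean reference, and the tests assert that
bound rather than idealized equality.

## Panel sweep and co-clustering

The DEG union uses subgroup-vs-rest comparisons for subgroups with at
least three labeled samples; unlabeled samples remain in the background of
every comparison. Union genes are ranked by median absolute deviation of
variance-stabilized expression across **all** samples (labeled and
unlabeled), the sweep evaluates sizes 300…3000 in steps of 50 (55 sizes),
truncating at the union size and always including the full union as a
candidate, and "best separation" — a visual judgement in practice — is
scored as the mean silhouette of labeled samples in the 2-D embedding.
Ties go to the smallest panel. t-SNE runs at perplexity 20 (reduced with a
warning when n is small); the pinned 50,000-iteration default is overkill
for cohorts of tens of samples, so the bundled workflows and tests run
1,000 iterations, which is converged at that scale.

Unknown samples are classified by k = 10 nearest labeled neighbors under
correlation distance (1 − Pearson r) on the panel matrix; Euclidean
distance is reserved for silhouette in embedding space. A majority
fraction ≥ 0.5 assigns, with the fraction reported as confidence; ties
between labels break lexicographically for determinism. Evidence
integration is strict precedence — fusion, then hotspot, then
co-clustering — with lower-tier disagreements recorded but never
overriding.

## Isoform usage

The usage test is a two-sample overdispersed proportion comparison on
aggregated counts: group proportions are gene-total-weighted, the pooled
variance is inflated by a Pearson-residual overdispersion factor (floored
at 1), and the statistic is referred to t with n − 2 degrees of freedom.
It responds to usage shifts and, by construction, not to pure gene-level
expression changes. Concordance between two result tables counts isoforms
present in both at q below a loose threshold (default 1.0, i.e. "reported
at any q"), with significance at q < 0.05 in both, and an undefined — not
zero — concordance when nothing is shared.

## Pre-ranked enrichment

Enrichment scores are the weighted Kolmogorov–Smirnov running-sum maximum
deviation with weight exponent 1 on |score|; the ranking orders by score
descending with lexicographic tie-breaks so results are total-order
deterministic. The null permutes gene labels (random same-size subsets,
cached per set size, seeded); p-values are one-sided within the observed
sign against same-sign nulls with a +1 floor, NES divides ES by the mean
|null ES| of matching sign, and FDR follows the standard pre-ranked
scheme: the sign-matched tail fraction of the pooled normalized null NES
divided by the observed tail fraction. Sets outside 15–500 members after
intersection with the ranking universe are skipped and listed.

## Numerical and degenerate-input choices

- IRLS: 50 iterations max, convergence at 1e-8 max coefficient change,
  linear predictor clipped at ±30, ridge jitter 1e-10 on normal equations.
- Rank score log₂FC × (−log₁₀ q) clamps q = 0 to the smallest positive
  float with a warning (the score would otherwise be infinite).
- All-zero samples make size factors undefined and raise, naming the
  sample; constant GC makes GC normalization a warned no-op; constant
  expression in the decay comparison yields NaN correlations rather than
  an error.
- Both members of an indel pair within 20 bp (inclusive) are removed — the
  rule targets alignment artifacts and keeping either member is
  unjustified. The cohort-recurrence fraction is computed on the raw input
  cohort so the four caller-level rules commute.
- Missing deleteriousness predictor labels never count as
  benign/tolerated/neutral; the three predictors are read predictor-wise
  (PolyPhen benign OR SIFT tolerated OR Condel neutral removes).
- Population-AF retention requires pop AF ≤ 1e-4 (removal strictly above
  "0.01%").

## Problem sizes used in tests and the acceptance script

Default study cohort: 60 samples, 5 subgroups (two fusion-defined, one
hotspot-defined, two expression-only), 2,000 genes, 200 signature genes
per subgroup; calibration simulations use 2,000 genes with 20-vs-40 and
6-patient paired designs; enrichment nulls use 100 random 30-gene sets
against a 1,000-gene ranking at 500 permutations; low-blast sensitivity
uses 100 replicates per blast fraction. These sizes were chosen as the
smallest at which the measured quantities are stable to within the
tolerances asserted.

## Known limitations

- The co-clustering rule assumes every unknown sample belongs to one of
  the labeled subtypes; genuinely novel subtypes are (correctly) left
  unassigned only when their neighbors disagree.
- The NB tests use plug-in dispersions; for designs with very few residual
  degrees of freedom the t reference is a partial, not exact, correction.
- The isoform test aggregates counts and does not model per-sample random
  effects; strongly patient-correlated usage would inflate its
  overdispersion factor rather than be modeled explicitly.
- The shipped whitelist, known-fusion list, subtype map and hotspot table
  are illustrative defaults and user-overridable; a clinical deployment
  would substitute curated versions.
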