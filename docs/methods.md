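# Methods

This note records the models implemented in `panelvar`, the parameter
choices that matter, what the synthetic data do and do not emulate, and the
numerical conventions used where the underlying design was genuinely open.

## Substitution calling

Each pileup site carries strand-resolved counts of the four nucleotides.
Conditional on a mutant allele fraction F, a sequenced base derives from
the reference allele with probability 1−F and the mutant allele with
probability F; a sequencing error replaces the true base by each of the
other three alleles with probability e/3. The four observed counts are then
multinomial with per-allele probabilities
p_i = q_i(1−e) + (1−q_i)(e/3), and the posterior that a mutation is present
is normalised over a discrete grid of candidate fractions (defaults: 50
log-spaced points in [0.005, 1]), with prior mass P(F=0) on the null and
(1−P(F=0))/|G| on each grid point. The grid-based normalisation makes the
posterior a proper probability without committing to a continuous prior
density on F; the allele-fraction estimate is the likelihood argmax on the
grid, so its resolution is the grid's (≈ 11% relative spacing — ample for
rounding to the nearest percent at any depth the panel produces).

Priors. P(F=0) defaults: 0.999 (ordinary site), 0.99 (tissue-elevated,
i.e. known-somatic but not recurrent), 0.9 (hotspot). The magnitudes are
configurable; the operative contract is the ordering, which gives hotspot
sites strictly higher sensitivity at identical counts. With the hotspot
prior, a 1% mutant fraction at depth 10,000 and e = 0.001 is called with
posterior ≈ 1.

Calling rule: posterior ≥ 0.99 and ≥ 3 variant reads. The read-support
floor prevents single-read calls at extreme depth, where even a tiny
posterior error rate would otherwise generate artifacts.

Error rate. The per-base substitution error defaults to 0.001 (0.1%/base),
a typical post-filtering Illumina value; it is a parameter everywhere it
enters (caller and simulator alike).

Filters. Strand bias: Fisher's exact test on the 2×2 allele × strand
table; a site fails only when p < 1e−3 *and* the variant reads are
effectively one-stranded (minor strand < 5% of variant reads); sites with
depth < 10 or fewer than 2 variant reads never fail (no power to assess
bias). Read-location bias works from summary statistics (mean and variance
of the variant base's fractional offset within its reads): fail when the
mean sits within 10% of either read end with dispersion < 0.01 — the
signature of an alignment artifact; a missing summary passes with a
warning flag. Classification precedence: known-somatic annotation beats the
germline list (a site recurrently somatic in tumors is never discarded as
germline merely because it also segregates in populations); otherwise
germline-listed sites are filtered; truncating/frameshift consequences are
labelled likely-functional; the rest are unknown.

## Indel assembly

Per exon window (the panel exon ± flank), reads are decomposed into k-mers
(default k = 21, one retry at k = 31 if the graph is unanchored or cyclic)
and assembled into a de Bruijn graph whose source/sink anchors are the
window's first and last reference k-mers. The reference k-mer skeleton is
kept in the graph with its own (possibly zero) read support so the
reference haplotype always remains representable and anchors can never be
pruned away.

Pruning: absolute support ≥ 2 removes singleton error k-mers; in the
calling path a *relative* rule additionally drops a branch edge whose
support is below 5% of its best sibling edge. The relative rule is what
controls coincident-error bubbles at high depth: two reads sharing the same
error create k-mers that pass any fixed absolute threshold, but they stay
far below local coverage, whereas a real variant branch at ≥ 20% allele
fraction sits well above 5% of its sibling.

Haplotypes are anchored source→sink paths (no node revisits, so
repeat-induced cycles terminate), ranked by minimum edge support; each is
aligned globally to the reference window with affine gaps (match +1,
mismatch −2, gap open −5, gap extend −1; a gap of length L costs
open + (L−1)·extend), and alignment gaps become anchored, left-normalised
indel calls. Each candidate is re-scored by exact read-consistency
counting: reads that are exact substrings of exactly one haplotype vote for
it, and reference votes are restricted to reads whose match overlaps the
event interval — otherwise distant reference reads dilute the supporting
fraction of long deletions. Calls require a supporting fraction ≥ 0.10.

At fold-coverage 100, read length 50, base error ≤ 1% and variant fraction
≥ 0.2, indels of length 1–15 are recovered in ≥ 95% of seeded replicates
(the residual misses are genuine junction-coverage dropouts).

## Copy number

The specimen is a two-component mixture: fraction p of tumor cells with
integer copies C at a locus, 1−p normal diploid cells. Expected
log-ratio and SNP minor-allele fraction are

    E[lr] = log2[(p·C + 2(1−p)) / (p·τ + 2(1−p))],
    E[BAF] = (p·m + (1−p)) / (p·C + 2(1−p)),

with τ the tumor ploidy and m ≤ C/2 the minor-allele copies. At C = 0 and
p = 1 the log-ratio is floored at −8 in place of −∞.

Log-ratios are log2(tumor/normal) per exon, median-centred (whole-sample
scaling is not copy-number signal); exons with normal coverage < 10 are
dropped. Segmentation is penalised least-squares binary segmentation on
exon order; the default penalty 3·σ̂²·log(n) (σ̂ from the median absolute
first difference) leaves a flat sd-0.1 profile of several thousand exons
as a single segment while detecting copy-level steps spanning a handful of
exons.

The fit is an exhaustive grid search (purity 0.05–1.00 step 0.01, ploidy
1.2–6.0 step 0.05), profiling out each segment's integer C — and m, where
SNP allele fractions overlap the segment — by Gaussian residual
minimisation; the BAF term enters with equal weight by default
(configurable) and per-SNP phase is handled by scoring each fraction
against both e and 1−e. The per-exon noise sd is estimated from
within-segment residuals unless supplied.

Identifiability. The likelihood surface carries near-exact ridges: halving
purity (p → p/(2−p)) while doubling ploidy and every segment's copies
reproduces both expectations exactly. Candidates within 3 log-likelihood
units of the optimum are therefore treated as an equivalence set resolved
toward the lower integer ploidy band, then higher purity, then likelihood,
and the winner is walked down the doubling ridge while the halved
representative stays within that margin. A profile statistically
indistinguishable from flat is flagged unidentifiable and reports no
purity. A single aberrant segment without SNP data remains genuinely
under-determined (the family p·(C−2) = const fits exactly); recovery
guarantees (purity ±0.05, ploidy ±0.2, exact C) hold for multi-state
profiles with BAFs, as in the bundled tests.

Calling: per gene, the modal segment copy number over its exons (ties
toward the more extreme value, matching the focal-event intent);
amplification at ≥ 6 copies, homozygous deletion at 0, and no calls at all
from samples at purity ≤ 20% or unidentifiable fits.

## Viral classification

Per-virus aligned read-pair counts are normalised to reads per million
total sequenced pairs (the denominator is configurable between reads and
pairs; pairs is the default). Status: ≥ 5 rpm positive, ≤ 2 rpm negative,
the open interval in between an explicit `indeterminate` — borderline
samples are surfaced rather than forced to a side. Both thresholds are
closed, so 5.0 is positive and 2.0 is negative exactly.

## Cohort statistics

The alteration matrix reduces per-sample calls to gene-level categories
(mutation / amplification / deletion / multiple / none). Enrichment between
the two strata uses Pearson's chi-squared without Yates correction
(correction available by flag), tested only for genes altered in ≥ 1
sample, with Benjamini–Hochberg q-values across the tested set. Degenerate
tables (zero margins) return p = 1. Wilcoxon rank-sum uses mid-ranks for
ties with an exact enumeration null for n+m ≤ 12 and a tie-corrected
normal approximation otherwise; ordinal clinical covariates are coded
never=0 < occasional=1 < heavy=2. Age enters through a single-covariate
logistic regression (Wald test on the slope; perfect separation is flagged
and the p suppressed). Fisher's exact test is two-sided by hypergeometric
tail summation. All tests are two-sided.

Clustering binarises the matrix (any alteration vs none) and clusters with
Ward linkage on Hamming distances by default. Jaccard + average linkage —
the other common convention, available via arguments — detaches samples
with empty alteration profiles (their Jaccard distance to everything is
~1) and cuts them off as their own cluster; on a sparse panel the shared
absence of alterations is informative, and Ward's variance criterion
absorbs sparse samples into the nearest biological group. On synthetic
cohorts with disjoint group alteration profiles the two-group cut is 100%
pure; on cohorts drawn from the bundled study-like prevalence template it
averages ≥ 90% purity over 20 seeds.

Design power: for a chi-squared test with effect size w (Cohen),
power = P[χ²_df(ncp = N·w²) > χ²_df,1−α]. At w = 0.5, α = 0.05, N = 40,
df = 1 this evaluates to 0.8854 — the "just under 90%" regime the two-group
design targets.

## Synthetic cohorts

The generator produces, per sample: pileups at true-variant and error-only
sites (multinomial, with errors spread uniformly over non-reference
alleles and strand assigned Bernoulli(strand balance) independently of
allele unless a bias is requested); exon log-ratio profiles under the
mixture expectation plus Gaussian noise; heterozygous-SNP allele fractions
(binomial around the expected BAF, random phase); reads uniformly tiling
exon windows with injected indels (`depth` is mean fold-coverage, matching
the pileup convention); and viral read counts (Poisson around a group-
specific reads-per-million level). Observed mutant fractions are purity-
scaled: a clonal variant on one of C copies has expected MAF
p/(p·C + 2(1−p)). Variant read-position summaries are recorded as the mean
and variance of uniform offsets — the sufficient statistics for the
location-bias filter — rather than full per-read data.

Default study-like conditions: two groups of 20, purity uniform in
[0.4, 0.9], diploid background, depth mean 500, base error 0.001, log-ratio
noise sd 0.15, and a prevalence template in which TP53 mutation occurs in
all of group B (the HPV-negative stratum) and ~6% of group A, CCND1
amplification in 55% and CDKN2A/B deletion in 40% of group B only, with
PI3K-pathway alterations enriched in group A. (The deletion prevalence is
reported inconsistently in the source material — ~40% in one place, ~55%
in another; the template uses 40%.)

What the generator does not emulate: FFPE damage and strand-specific
artifact spectra, GC/mappability coverage waves, alignment errors and
mapping ambiguity, subclonal copy number, or real linkage between panel
sites. Passing tests therefore demonstrate correctness of the inference
under the stated generative model, not robustness to every artifact of
real libraries — the filters exist for those artifacts, but only the
simulated forms of them are exercised.

## Numerical conventions and limitations

* All likelihood work is in log space (`logsumexp`); the posterior matches
  an arbitrary-precision re-evaluation to 1e−6 across 1,000 random count
  configurations.
* Coordinates: BED input is 0-based half-open; VCF output is 1-based with
  anchored, left-normalised indel alleles. Left-normalisation is
  idempotent and reports homopolymer indels at the leftmost position.
* Multi-allelic sites emit the best-supported alternate only; indels are
  the assembly module's job, never the substitution caller's.
* Every stochastic routine takes an explicit seed (or Generator); the
  pipeline log records the resolved parameter set, and identical configs
  reproduce byte-identical outputs.
* Problem sizes in the test-suite simulations (300 bp windows, fold-
  coverage 100–300, cohorts of 8–40, 20-replicate recovery suites) are
  chosen to exercise the stated operating points of each method at
  desk scale.
* Rearrangement detection, GC correction, subclonal copy states and
  cross-exon assembly are out of scope by design.
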