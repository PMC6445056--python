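# Methods

## Window statistics

The scan operates on per-population allele frequencies at bi-allelic SNVs.
Missing genotypes shrink the frequency denominator (no imputation); sites
that are multi-allelic or not SNVs are dropped and counted.

**Major/minor convention.**  d_xy multiplies one population's major-allele
frequency by the other's minor-allele frequency, so both factors must refer
to the same physical nucleotide; otherwise the statistic is asymmetric and
d_xy(x, x) no longer reduces to within-population heterozygosity.  The
default therefore labels the allele with pooled all-sample frequency ≥ 0.5
as major (ties broken to REF) and uses that label in every population.
H_P is different: it is an intra-population quantity, and the sweep
signature — depressed heterozygosity in the selected lineage — only
appears when each population's own major allele is used.  With shared
global labels, a swept window's selected-population frequencies alternate
between ~0.98 and ~0.02 depending on which allele happens to be
pooled-major, and the pooled H_P form is driven *toward its maximum*
instead of its minimum.  `scan_genome` therefore folds frequencies to each
population's own major allele before computing H_P, while d_xy keeps the
global labels.  A `scope="per-pop"` option on `assign_major_minor`
exposes the fully per-population alternative for comparison.

**Fixation index.**  Default "wright": the frequency-based ratio of sums
Σ(H_T − H_S)/ΣH_T with H_T computed from the unweighted mean of the two
population frequencies and H_S the mean of the two 2pq terms.  It needs no
sample sizes, lies in [0, 1], and is the natural choice when frequencies
come from imputed or pooled data.  "hudson" (flag) is the
sample-size-corrected ratio of averages; it is unbiased for small samples
and may legitimately go negative, and it is deliberately not clamped, so
LSBL can be slightly negative under it.  Sites monomorphic in both
populations contribute zero to numerator and denominator; a window
monomorphic everywhere is NaN.

**d_xy modes.**  The default "per_site" form averages
f_x,maj·f_y,min + f_y,maj·f_x,min over sites and is bounded by [0, 1].
The "literal" mode evaluates the window-summed product form
Σf_x,maj·Σf_y,min + Σf_y,maj·Σf_x,min without normalisation; it grows
like n² and is only comparable between equal-n windows, but is retained
because the pooled-sum reading of the formula is defensible and cheap to
check.  Both are symmetric.

**H_P / ZH_P.**  H_P uses the pooled form 2·Σmaj·Σmin/(Σmaj+Σmin)², which
lies in [0, 0.5].  ZH_P standardises window H_P per population across all
windows of the scan using the sample (n−1) standard deviation (population
sd by flag).  Windows with fewer than `min_sites` variants (default 10)
carry NaN statistics and are excluded from μ and σ.

**Windowing.**  Windows are [start, start+W) half-open, tiled from 0 in
steps of S (defaults W = 30 kb, S = 15 kb); the terminal partial window is
kept and flagged rather than dropped, so genes near chromosome ends stay
covered.  Top-quantile extraction keeps every window at or above the
(1 − q) empirical quantile, including ties.

## Synthetic cohorts

The generator is the package's study design, not a tuning knob.  Each
site draws an ancestral derived-allele frequency p ~ Uniform(0.05, 0.95);
each population then draws its frequency from the Balding–Nichols
distribution Beta(p(1−F)/F, (1−p)(1−F)/F), giving frequency variance
p(1−p)F.  The model was chosen because it yields an analytically
checkable expectation: for two populations drifting independently with
the same F, the ratio-of-sums Wright F_ST on true frequencies is
F/(2−F) (≈ 0.00503 at F = 0.01), which the tests verify numerically.
Frequencies estimated from finite samples sit above this because binomial
sampling noise adds ≈ 1/(2·n_alleles) of apparent differentiation — with
30 diploids per population the observed background window F_ST is
≈ 0.013.

A sweep is planted by overriding the selected population's derived (ALT)
frequency inside a half-open interval; REF is the ancestral allele
throughout, so truth bookkeeping is unambiguous.  Genotypes are
Binomial(2, f) per sample; positions are drawn uniformly without
replacement and sorted.  Defaults (10-Mb chromosome, 20,000 sites = one
SNV per 500 bp ≈ 60 per 30-kb window, 30 samples per population,
F = 0.01, 200-kb sweep at frequency 0.98) represent a filtered livestock
resequencing panel at desk scale.  The generator does **not** simulate
recombination, linkage beyond the planted sweep, indels or missingness,
so passing recovery tests demonstrates that the statistics find a
frequency-differentiation signal of realistic magnitude and extent — not
that they are robust to LD structure or call-rate artefacts of real data.

Phenotypes follow y = intercept + Σβ_m·g_m + β_age·age + β_sex·sex +
N(0, σ²) with sex coded 0 = female / 1 = male.  The bundled hybrid-cohort
convenience generator uses n = 116, ~76% males, additive effects −3.3 cm
(tail length) and +3.5 cm (tail width) per allele at a frequency-0.5
marker duplicated into a complete-LD pair, and noise (σ = 3.0 and 2.1 cm)
chosen so the genotype coefficient's standard error is ≈ 0.4 and ≈ 0.3 cm
— the regime in which such effects are detected at p ≈ 10⁻¹⁵–10⁻²⁷.

## Retro-copy detection

The aligner is an exact-k-mer seed (k = 12), collinear-chain, extend
design: seeds are grouped by diagonal (±15) and query gap (≤ 250 bp),
chains with ≥ 20 bases of seed coverage are extended outward by greedy
ungapped X-drop (match +1, mismatch −2, drop 12) and scored by an
edit-distance alignment (edlib) whose extended CIGAR gives matches and
alignment columns.  Both strands are searched; k = 12 keeps random 150-kb
background hits to isolated single seeds (below the chain threshold)
while a 0.85-identity copy retains an exact 12-mer roughly every 7 bp.
The chain threshold of 20 (two collinear seeds) matters because short
exons of a diverged copy occasionally retain only two exact seeds.

Candidate loci must exceed 500 aligned bases **and** 0.80 length-weighted
identity, both strict inequalities.  Intron-loss classification looks at
each exon–exon junction: the blocks covering the two flanking exon ends
(20 bp slack) are mapped to target coordinates; a target-side gap ≤ 30 bp
where the parent intron is longer is *collapsed*, a gap within 20% of the
intron length is *retained*, anything else is *ambiguous*, and junctions
with an unaligned flank are *uncalled*.  The verdict is "retrocopy" when
at least ⌈half⌉ of the junctions are collapsed, "duplication_with_introns"
when at least half are retained, "no_candidate" below the thresholds, and
"no_intron_evidence" for single-exon parents or inconclusive junctions —
these last cases are labelled explicitly rather than forced into either
class.  The 30-bp junction gap and the half-of-junctions rule are this
package's operationalisation of what is otherwise a by-eye dot-plot call;
both are config-exposed.

Planted-copy fixtures apply an exact count of substitutions,
round((1−identity)·L), at distinct uniform positions, so the aligner's
identity estimate can be held to ±0.03 of truth.

## Repeat density and enrichment

Coverage is always the union of member intervals clipped to the region,
divided by region length, so nested/overlapping annotations cannot exceed
100%.  RepeatMasker coordinates (1-based inclusive) are converted to
0-based half-open on parse; strand "C" maps to "−".  The windowed density
uses a 50-kb window with step = window/2 by default (config-exposed).
Random-loci comparison draws n same-length regions uniformly, seeded,
overlapping neither the focal region nor each other (rejection sampling;
an impossible placement errors out), and reports focal fraction against
the random mean ± sample sd.  The annotation generator hits per-class
coverage targets exactly up to integer rounding by drawing element
lengths (lognormal, clipped to 60–6000 bp) until the target is reached
and distributing the leftover space as random gaps, which makes
construction-target tests sharp.

## Association

OLS via statsmodels; the genotype column is encoded per genetic model
(additive = allele count, dominant = carrier, recessive = homozygote) for
the declared mutated allele — the table must say which allele is counted,
it is never inferred.  Complete-case handling with n_used reported; a
constant encoded genotype returns an inestimable result instead of
raising; a rank-deficient covariate design raises and names the collinear
columns.  P-values are two-sided t-tests, unadjusted for multiple testing
(the report lists every model × adjustment combination side by side).

## Numerical and degenerate-input choices

NaN is the uniform "undefined" marker and propagates (LSBL of any NaN
input, ZH_P of NaN windows).  A constant H_P vector standardises to
all-NaN with a warning rather than dividing by zero.  Quantile thresholds
use the linear-interpolation empirical quantile with ties included.
Generator determinism is a contract: every generator is a pure function
of (configuration, seed), and byte-identical VCF output for identical
seeds is tested.

## Known limitations

* No LD/recombination structure in cohorts; sweep recovery rates here do
  not quantify power on real haplotype data.
* The aligner targets desk-scale regions (≤ a few Mb) and
  substitution-dominated divergence; large indels inside exons will
  fragment blocks and can leave junctions uncalled.
* Hudson-estimator windows require ≥ 2 called alleles per site and are
  sensitive to very small samples.
* The association module fits fixed-effect OLS only — no kinship or
  mixed-model correction, which real crossbred cohorts may need.
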