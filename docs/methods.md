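# Methods

## Scope and data model

The package analyzes diploid tandem-repeat (TR) repeat-length genotypes
and biallelic SNV dosages against per-cell-type pseudobulk expression in
two cohorts ("batches"). Coordinates are 0-based half-open internally
(BED-compatible arithmetic); VCF I/O converts to 1-based. A TR locus is an
interval plus a motif; motif identity everywhere means the equivalence
class under cyclic rotation and reverse complement, represented by the
lexicographically smallest member. The regressor for a TR is the summed
repeat dosage (both alleles' repeat counts); for an SNV it is the
non-reference allele dosage.

## Catalog algebra

Catalog merging parses catalogs sequentially and excludes a candidate
locus iff an already-included locus covers ≥ 66% of the candidate's length
and shares its motif class. The overlap denominator is the candidate
locus (configurable to reciprocal): the merge rule is stated against the
incoming locus, and measuring against the candidate makes the sequential
pass order-stable and idempotent. Compound locus definitions are not
modeled; the association operates per simple locus. An indel "represents"
a TR allele — and is pruned before fine-mapping — iff it lies inside a
cataloged TR interval and its inserted/deleted sequence is a nonzero whole
number of copies of some cyclic rotation of the locus motif; partial
copies and impure sequences are retained.

## Genotype QC

Calls with an allele more than 30 repeats below or 20 repeats above the
locus modal allele are set missing; one out-of-window allele voids the
whole diploid call, since the summed dosage would otherwise be undefined.
Masking precedes the call-rate computation. Loci are retained with call
rate ≥ 0.90, expected heterozygosity 1 − Σp² ≥ 0.00995 (the biallelic
equivalence 2pq makes this a non-major allele frequency of 0.5%), and a
Hardy-Weinberg exact binomial test of the heterozygote count against
Binomial(n_called, 1 − Σp²) at p ≥ 10⁻⁶; multiallelic loci collapse to
heterozygote-vs-homozygote for this test. Passing boundaries are
inclusive because the filters are stated as strict-inequality failures.
The direct heterozygote fraction is also reported per locus. SNVs are
kept at minor allele frequency ≥ 1% after multiallelic splitting.

## Association

Expression is inverse-normal transformed per gene using average ranks at
the Weibull plotting position rank/(n+1) (Blom available as an option;
the choice only rescales extremes and does not change ranks). The model
y = Wα + gβ + ε is fit by OLS with classical homoskedastic standard
errors and a two-sided t-test; dosage is used raw (centering moves only
the intercept). Missing dosages drop samples per test (complete-case),
with n recorded. A gene is skipped in a cell type where it is expressed
in fewer than 1% of cells. Methylation associations use the same model on
inverse-normal-transformed raw methylation probabilities (no logit first)
for CpG sites whose methylation sd exceeds 0.02, with Bonferroni
correction over TR-CpG pairs.

## Meta-analysis and cell-type specificity

Per-cohort estimates are pooled with the DerSimonian-Laird moment
estimator; the pooled p-value uses the normal approximation without
Knapp-Hartung adjustment, matching standard practice for this estimator.
With k = 2 studies τ² is noisy; it is used as-is, including in the
pairwise specificity meta-analyses. A consequence documented by the
calibration study (`analysis/03_calibration.py`): under a true null the
two-study pooled p-values are mildly conservative in the mid-tail
(empirical rate ≈ 0.037-0.053 at nominal 0.05), because a large observed
between-study difference inflates τ² and shrinks the z-statistic. The
empirical type-I error stays within three binomial standard errors of the
nominal level; a Kolmogorov-Smirnov test on a few hundred null p-values
will occasionally flag the mild conservative bend.

An sc-eTR significant at FDR < 5% is compared against every other cell
type where its gene is expressed in ≥ 1% of cells: it is *shared* with a
cell type iff the two-study pooled p-value is smaller than its original
p-value, and *cell-type-specific* iff the pooled p-value is larger in
every eligible comparison. Ties (p_meta == p_origin) count as neither;
with no eligible comparison the call is flagged undefined and reported as
not specific. Sign-discordant significant pairs are reported
descriptively; no dedicated opposite-sign criterion is claimed.

## Gene-level significance

The gene-level p-value is the Cauchy combination (ACAT-V) of the TR
p-values in the gene's window with equal weights (no weighting scheme is
prescribed; MAF-based weights are available). Summands use
tan((0.5 − p)π), switching to the stabilized 1/(pπ) below 10⁻¹⁵; the
combined tail is evaluated as arctan(1/T)/π for large T to avoid
cancellation. Storey q-values use the single-λ estimate
π̂₀ = min(1, #{p > 0.5}/(m/2)) — deterministic, no smoother — computed
across genes within each cell type; with π̂₀ = 1 the procedure reduces
exactly to Benjamini-Hochberg. The top eTR is the smallest-p TR per gene
per cell type; the lead variant is the smallest-p variant among TRs and
SNVs jointly, ties broken by coordinate then identifier.

## Fine-mapping, conditional analysis, colocalization

Fine-mapping deliberately re-implements the single-effect (L = 1) special
case of sum-of-single-effects regression from summary statistics: the
one-credible-set restriction makes the model exactly a softmax over
per-variant Wakefield log ABFs with a uniform prior on which variant is
causal. The prior effect variance is chosen from the grid {0.001, 0.005,
0.01, 0.0225, 0.05, 0.1, 0.2} by maximizing the marginal likelihood
log((1/J)ΣABF); 0.0225 = 0.15² is the conventional prior sd for a
quantile-normalized trait. The 95% credible set is the smallest
PIP-ranked prefix reaching 0.95 cumulative PIP; variants outside it keep
their PIPs but are flagged pruned rather than zeroed, so both readings of
single-credible-set pruning are recoverable. Meta-analysis summary
statistics (not per-cohort) feed fine-mapping. A TR is candidate causal
iff it is the lead variant of its gene and its PIP is ≥ 0.7.

Conditional analysis appends the conditioning variant's dosage to the
covariates and re-fits per cohort, pooling the conditional estimates with
the same meta-analysis; persistence is declared at P < 5×10⁻⁸.
Near-collinear test/conditioning pairs (r² > 0.999) are refused.

Colocalization enumerates the five hypotheses from per-variant ABFs in
log space with priors p1 = p2 = 10⁻⁴, p12 = 10⁻⁵ (the conventional
defaults; none are prescribed) and prior sd 0.15 for quantitative traits
(sdY = 1), 0.2 on the log-odds scale for binary traits. With one shared
variant the H3 term is exactly zero (handled as −∞ in log space). TR
identifiers are harmonized across catalogs by interval intersection plus
motif-class equality; SNVs match on position and allele set, with a
ref/alt swap recorded as a sign flip (posterior probabilities depend on
z², so the flip affects only reported directions). The gating rule for a
TR-driven trait signal requires PP H4 ≥ 0.8, a passing candidate-causal
call, r² ≥ 0.5 between the TR and some GWAS-cataloged variant in the
window (the TR itself, if the GWAS catalog includes TRs), and a
genome-wide significant GWAS hit in the window for eligibility. LD is the
squared Pearson correlation of dosages over complete cases (≥ 3 pairs,
both vectors non-constant).

## Genotype validation

PCR fragment lengths convert to repeat copies as c = floor(r + (w − l)/s)
with negative results masked. Offset scoring shifts a caller genotype by
a candidate offset d and credits 1 if both truth alleles are recovered,
0.5 if exactly one is recovered from a homozygous caller call, and 0.25
if exactly one from a heterozygous call. Every call is scored under every
candidate offset — a concordant call is full recovery at d = 0 — so
mostly-concordant loci rank the zero offset on top instead of being
out-voted by one or two sporadic errors; ranking ties break toward the
smaller magnitude, negative before positive. A locus adopts an offset
only if every caller present ranks it first and the locus has ≥ 20 calls;
adopted offsets are subtracted from the truth table (offset convention:
d = truth − caller). Concordance compares summed repeat dosage by default
(strict equality; tolerant allows ±1 repeat unit), with an unordered
allele-pair mode available — the two modes differ exactly when a shift
moves both alleles (dosage off by 2) or compensating errors preserve the
sum.

## Synthetic cohort generator

The generator defines the study conditions the tests exercise:

- **TR genotypes**: each haplotype draws Geometric(1 − step_prob) many ±1
  repeat-unit steps away from the locus modal allele (default mode 20,
  step_prob 0.3 — most alleles within a few repeats of the mode,
  matching mode-centered allele distributions of repeat genotyping at
  population scale), truncated at 1 repeat.
- **Tag SNVs**: the haplotype allele is the indicator of the TR haplotype
  exceeding the mode, flipped with a probability solved by bisection so
  the realized dosage r² meets ld_target (default 0.5). Because the tag
  is a binary function of a mode-concentrated distribution, the
  achievable r² is capped near 0.5-0.6 at the default step probability;
  higher targets realize the cap.
- **Expression**: y = cohort shift + Wα + βg_centered + N(0, 1) per
  (cohort, cell type), with covariates (sex, age, 12 genotype-PC and 6
  expression-PC standard-normal surrogates — drawn directly rather than
  via PCA of the simulated genotypes, since the adjustment, not the PCA,
  is what the model needs) and per-gene covariate loadings drawn once.
- **Methylation**: logistic-scale linear effect of standardized TR dosage
  at even-indexed CpG sites within 5 kb of their anchor TR; odd sites null.
- **Truth sets**: caller = truth − offset per locus plus sporadic ±1/±2
  single-allele errors at a configurable rate.
- **Trait GWAS**: an independent cohort with the same generative
  parameters (hence the same LD structure) yields marginal OLS summary
  statistics for a trait driven by nominated causal variants.

Synthetic loci sit on one artificial chromosome at 250 kb spacing with
each gene placed 1 kb from its paired TR, so cis-window membership is
exact by construction. All randomness derives from a single seed through
per-operation child generators; a fixed seed reproduces every table
byte-for-byte.

What the generator does **not** emulate: read-level artifacts (stutter,
coverage), single-cell count matrices (pseudobulk only), realistic allele
frequency spectra and LD decay, population structure actually expressed
in genotypes, or polygenic trait architecture. Passing tests therefore
demonstrate the correctness and calibration of the statistical machinery
under the assumed model, not robustness to the full messiness of real
cohort data.

## Problem sizes

The standard synthetic study is 2 cohorts × 400 samples, 20 TR loci with
tag and filler SNVs, 4 cell types and three planted effects (|β| = 0.5).
Calibration uses 2 × 250 samples and 200 genes (400 null meta tests);
recovery studies use n = 1000 with 500 (coverage), 200 (fine-mapping) and
100 (colocalization) replicates; the specificity study uses 2 × 300
samples, 4 cell types and 40 replicates per scenario. These sizes give
binomial standard errors a few times smaller than the margins being
checked while keeping any single driver in the seconds-to-minutes range.

## Known limitations

- Two-study DL τ² is noisy and yields the mild tail conservativeness
  described above; no small-sample adjustment is applied, by design.
- The single-causal-variant model cannot represent allelic series or
  multiple independent signals per window; conditional analysis is the
  only tool provided for secondary signals.
- The indicator-based tag-SNV construction caps achievable TR-SNV LD.
- VCF export uses symbolic repeat-count alleles (`<RL{n}>`) with the
  repeat counts in an INFO field, not full REF/ALT sequences.
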