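# Methods

## The discovery model

The pipeline's premise is that a gene modulating cholesterol metabolism
should (i) be expressed in liver, the organ that clears LDL; (ii) respond
to statin exposure in hepatocyte-derived lines and in a large panel of
donor lymphoblastoid cell lines (LCLs); (iii) respond in the same direction
in both systems; and (iv) co-respond with *HMGCR*, the statin target, whose
induction is the canonical cellular read-out of statin effect. Genes are
therefore passed through an ordered filter cascade and the survivors ranked
by the Pearson correlation of their statin-induced expression change
("delta") with that of *HMGCR* across donors, with Bonferroni control at
the size of the direction-concordant set — not the whole genome — because
only those genes reach the correlation stage.

All thresholds are strict inequalities (detection p < α, FDR < 0.01,
Q < 0.05, correlation p < α/m). Candidates are ordered by ascending
correlation p, ties broken by |r| descending and then gene id, so reports
are deterministic.

## Expression preprocessing

Traits are adjusted per exposure arm by ordinary least squares on the known
sample covariates (age, sex, growth rate, exposure batch, labeling batch;
categoricals one-hot encoded). Two variants are exposed:

* the default returns mean-zero residuals per arm — appropriate for
  correlation and association analyses;
* `keep_arm_means=True` restores each gene's within-arm mean, removing
  covariate-linked variation while preserving the exposure main effect.
  Paired differential expression *must* use this variant: mean-zero
  residuals by construction contain no paired mean difference to test.

Unknown structure is removed by regressing each gene on the principal
components of the per-gene-centered matrix whose variance fraction exceeds
5% (configurable). When the gene means are to be preserved (the
differential-expression branch), the part of the means explained across
genes by the removed components' gene loadings is subtracted as well: a
latent factor with a nonzero sample average shifts gene means in proportion
to its loadings, and leaving that share in place inflates the null
distribution of paired statistics. The loading-orthogonal share of the
means — the genuine response signal — is untouched in expectation.

"Quantile normalized across each gene" is implemented as the rank-based
inverse-normal transform Φ⁻¹((rank − 0.5)/n) with average ranks for ties,
because the purpose of the step is to guarantee per-gene normality for the
downstream linear models; between-array quantile normalization does not.
Genes whose deltas are all tied carry no ordering information and are
dropped with an explicit report rather than imputed.

The order of operations is: covariate adjustment → hidden-factor removal →
delta construction → per-gene normalization. Whether PCs are removed before
or after per-gene normalization, and per arm or pooled, is a genuinely open
design point; the chosen order is a documented default and each step is
independently callable.

## Paired SAM

For gene *i*, r_i is the mean statin-minus-sham difference across subject
pairs, s_i the standard error of that mean, and d_i = r_i/(s_i + s0). The
fudge factor s0 is selected from the percentile grid (0, 5, …, 100) of the
s distribution to minimize the coefficient of variation of the per-bin
median absolute deviation of d over ten s-quantile bins — the standard
recipe for making d's scale independent of s.

The null distribution comes from sign-flip permutations of the subject
differences: exhaustive over the 2ⁿ − 2 non-trivial sign patterns when that
fits the permutation budget, otherwise sampled without replacement from
distinct patterns. The identity pattern and its global negation are
excluded because they reproduce the observed statistics exactly (up to
sign) and would impose an FDR floor of 2/B however strong the signal — at
n = 7 pairs that floor alone would defeat an FDR < 0.01 stage.

The estimated FDR at threshold t is π0 · (mean permuted count of |d| ≥ t) /
(observed count of |d| ≥ t), with π0 = min(1, 2 · fraction of observed |d|
below the permutation median). A gene's q-value is the minimum estimated
FDR over all thresholds at which it would be called, which also makes q
non-increasing in |d|. The mean (not median) permuted count is used: the
median count at extreme thresholds is 0 with probability ≈ ½ on null data
by exchangeability, which would spuriously call the top gene in half of
all null datasets; with the mean, the min-over-thresholds statistic behaves
like a Simes test and the false-discovery proportion is α-calibrated
(verified by simulation in the acceptance suite). A reported q of exactly 0
occurs only when no permuted value anywhere exceeds the threshold.

Fold changes are reported as the mean ± SD of per-subject antilogged
deltas (statin/sham ratios), not the antilog of the mean delta.

## Haplotype association

The clinical phenotype is delta-log LDL-C: log(mean of on-treatment
measurements) − log(mean of the two baseline measurements); the descriptive
scale is unadjusted percent change, (mean_on − mean_base)/mean_base × 100.
Both are invariant to the order of replicate measures. The additive model
regresses delta-log on haplotype copy number (0/1/2) with age, sex, BMI and
smoking, plus a study indicator when the cohort spans both trials. Phasing
and imputation are upstream of this package: phased allele vectors or
ready-made copy counts are inputs. A chromosome matching no definition is
grouped as "other" and contributes zero copies to every tested haplotype;
definitions that cannot be distinguished raise an error.

The four-haplotype definition table over 24 tag SNPs near *RHOA*, with its
trial population counts, is encoded in `statpgx.assoc` and doubles as the
default frequency table for cohort simulation. The homozygote-vs-non-carrier
contrast is summarized as (mean₀ − mean₂)/mean₀ × 100 on *unadjusted*
percent change, matching how such group differences are conventionally
quoted.

## Splicing QTL and allele-specific expression

Exon inclusion is exon-level qPCR quantity over total-gene quantity × 100
(both reference-gene normalized, so the normalization constant cancels).
Within an exposure arm, fractions are batch-residualized (cell-mean model),
rank-normalized and regressed on haplotype copies.

ASE at a heterozygous SNP uses corrected odds
(cA/cB)/(gA/gB): the genomic DNA of a heterozygote carries exactly one copy
of each allele, so its observed peak-height odds measure pure assay bias,
and dividing by them cancels any multiplicative per-allele bias shared by
the two templates — an exact identity, property-tested. The deviation test
against the balanced null is an exact Wilcoxon signed-rank (peak-height
noise is not Gaussian); a paired signed-rank comparison of statin vs sham
fractions is provided for the descriptive treatment contrast.

## The synthetic-data generator

The generator emulates the study design, not microarray physics. Per LCL
pair *s* and gene *g* the statin-minus-sham delta is

    delta(g, s) = load(g)·F_s + batch(g, b_s) + Σ_k h(g,k)·Z_{k,s} + ε

with F_s ~ N(1, 1) a latent statin-response factor (nonzero mean, so
pathway genes are differentially expressed on average), load(g) uniform on
the configured range for the 40-gene pathway block (largest for *HMGCR*,
zero elsewhere), per-exposure-batch gene shifts, two hidden technical
factors, and N(0, 1) noise. Statin intensities are sham plus delta on the
log2 scale. Batch effects are drawn as sum-to-zero deviations across
batches within each gene: free-floating per-batch offsets would make the
batch average indistinguishable from the gene's exposure effect — no
adjustment can repair that confound, it must be absent from the design.

Default loading and noise magnitudes are calibrated only so that pathway
genes reach anchor correlations of r ≈ 0.3–0.5, the range a real
co-response screen reports, and are not fitted to any dataset. Off-pathway
gene classes (fractions of the 2,000-gene universe) give the funnel
strictly monotone attrition: 10% not expressed in LCLs, 10% not in liver,
5% hepatoma-only responders, 5% LCL-only responders, 3% direction-
discordant responders, 5% concordant-but-uncorrelated responders, the rest
null. The hepatoma panel (7 pairs) uses larger effects and lower noise
(cell lines, not donors; scale 1.5, SD 0.2 log2 units), mirroring how
tabulated hepatoma fold changes carry much smaller dispersions than LCL
panel ones.

The cohort generator draws two haplotypes per subject at the encoded
frequencies (42.6/25.6/22.4/9.4%) under Hardy–Weinberg across 580 + 1,306
subjects in two study arms. Expected percent LDL-C change is −30.7% for
non-carriers of the flagged haplotype (H3B) and −21.8% for homozygotes,
interpolated additively for heterozygotes. Between-subject response scatter
(SD 15.7%) is back-derived from the reported non-carrier group standard
error (0.4%) at its stratum size; per-measurement noise is multiplicative
log-normal with CV 5%, a realistic clinical lipid assay precision. Baseline
LDL-C is log-normal around 140 mg/dL (SD 0.2 log units), typical of statin
trial entry criteria. Lipids are log-normal so the delta-log phenotype is
always defined. Covariates (age, sex, BMI, smoking) are drawn from generic
adult-trial distributions and have no phenotype effect by default, so null
calibration holds exactly.

Splice samples (115 subjects × two exposures, four batches) get inclusion
percentages of 1% + 4% per flagged-haplotype copy with 0.5% noise — small
baseline inclusion of a cryptic exon with a strong cis effect. Trace
heights are proportional to the true allele fractions with multiplicative
log-normal noise (SD 0.05); gDNA heights are balanced up to the same noise.

Every injected quantity — gene class, loading, per-arm mean effect, subject
haplotype copies, expected percent change, true inclusion — is returned in
truth tables keyed by gene/subject/sample.

What the generator does **not** emulate: bead-level intensity physics,
probe cross-hybridization, linkage disequilibrium beyond the four defined
haplotypes, genotype uncertainty, dropout or missing lipid measurements.
Passing tests therefore demonstrate the statistical machinery is correct
and calibrated under the assumed generative structure, not that it is
robust to all real-data pathologies.

## Problem sizes and numerical choices

The default synthetic study uses 2,000 genes — large enough for every
funnel stage to bite and for pooled permutation FDR to be stable, small
enough that the full pipeline runs in seconds. Permutation defaults are
exhaustive sign patterns for the hepatoma arm and 1,000 sampled patterns
for the LCL arm; FDR-calibration checks use 60 pure-noise studies of 500
genes × 50 pairs. Association recovery uses the full 1,886-subject cohort
over 200 replicates; the expected delta-log slope is obtained by direct
Monte-Carlo integration of log1p over the response-scatter model rather
than the noise-free log-ratio, which differs by a Jensen term of ≈0.003.
Degenerate inputs fail loudly: all-tied vectors, constant covariates,
collinear designs (reported with the offending column names), constant
copy counts, empty detection matrices. Percent changes are floored at −95%
so simulated on-treatment lipids stay positive; inclusion percentages are
floored just above zero.

## Known limitations

* Pooled permutation FDR lets moderate null genes ride on strong signal
  blocks (the q-value is a property of the called list, not of the gene);
  the funnel's final Bonferroni stage is what controls candidate-level
  error.
* The s0 tuner uses a fixed ten-bin grid; at very small gene counts it
  degrades to near-constant bins (it then effectively returns a percentile
  of s).
* The mean-deconfounding step in hidden-factor removal assumes true gene
  effects are uncorrelated with latent-factor loadings across genes; a
  pathway whose response is itself the dominant latent factor would be
  attenuated. At the default composition the response factor explains
  <1% of delta variance and is untouched.
* Haplotype association treats copy counts as known; imputation uncertainty
  in real data would widen the reported standard errors.
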