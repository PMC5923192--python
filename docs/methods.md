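# Methods

## Overview

`pedigrec` reconstructs meiotic recombination from SNP-genotyped
pedigrees. The observable unit is a *meiosis*: one parent-to-offspring
gamete transmission inside a three-generation family (genotyped
offspring, genotyped donor parent, at least one genotyped grandparent).
The donor's two haplotypes are phased against the grandparents, the
offspring's transmitted haplotype against its parents, and crossovers
appear as switches in which donor haplotype the transmitted alleles
match. Aggregated over many meioses this yields per-SNP-interval
recombination rates (expected crossovers per meiosis), from which
hotspot regions, breed contrasts and GWAS phenotypes are derived.

## Phasing and detection

Phasing is single-site Mendelian resolution only: a heterozygous child
is phased where exactly one assignment of its alleles to the parents is
compatible with transmission (one parent homozygous, or one parent
missing and the other homozygous). Sites violating Mendelian
inheritance are flagged and set unknown; families whose donor shows
more than `max_mendel_rate` (default 2%) error sites are dropped. No
population/LD phasing is used — the method is strictly pedigree-based,
so simulated founders need no linkage structure.

*Informative sites* are sites where the donor is heterozygous and
phased; only there does the transmitted allele identify the donor
haplotype. Detection resolution is therefore the informative interval,
with two inherent limits:

* **parity**: an even number of crossovers between two consecutive
  informative sites cancels and is invisible;
* **censoring**: crossovers outside the span of a donor's informative
  sites (chromosome ends) are undetectable.

On error-free data with the run-length filter disabled, detection is
*exact* at this resolution: detected switches coincide with the
odd-parity informative intervals of the simulation truth (this is a
test invariant). With genotyping error, isolated matches produce
spurious double switches; runs of fewer than `min_support` (default 2)
consecutive same-haplotype matches are treated as artifacts, masked,
and tracing repeated. At a 0.2% allele error rate this keeps spurious
events below 0.5 per meiosis on the default simulated genome.

Each accepted crossover is assigned evenly — mass 1/k — to the k
adjacent-SNP intervals between its flanking informative sites. Because
informative sites are a minority of SNPs (heterozygosity x
phaseability, roughly a quarter at typical allele frequencies), this
smears each event over a few SNP intervals. Consequences documented
deliberately:

* interval rates are locally averaged: a single strongly enriched
  interval appears diluted over its neighbourhood, so hotspot *regions*
  (not point hotspots) are the natural object at SNP-panel resolution;
* per-interval masses vary less than binomial counts, so the
  chi-square breed scan on these masses is conservative (never
  anti-conservative); its nominal calibration is checked at full
  (count) resolution.

Meiosis-level QC removes records with more than `max_crossovers`
(default 45, strictly greater) genome-wide events. The threshold is
applied per meiosis; the rule could also be read per animal summed over
meioses, which users can emulate from the per-meiosis output.

## Maps, hotspots, comparison

A recombination map is rate_i = (total crossover mass in interval i) /
(number of meioses); its genome-wide sum equals the mean crossover
count, and maps merge by meiosis-count-weighted averaging, exactly.
Maps are built from high-density meioses only (pair typed-marker count
at or above the density threshold; default three quarters of the
panel), emulating the restriction of published maps to dense chips.

Hotspot regions are intervals with rate strictly greater than mean +
2.5 population SDs of all interval rates (zeros included). Sharing
across breed/sex sets is reported as the exact Venn partition plus the
conventional "pairwise excluding the all-shared core" counts.

Breed differences per interval use the 1-df Pearson chi-square on the
2x2 table [mass, meioses − mass] x breed with fractional masses entered
directly and no continuity correction; intervals with zero total mass
are untestable and excluded from the Bonferroni denominator (threshold
= alpha / number tested).

The position profile standardizes each interval midpoint by chromosome
length, normalizes rates per Mb (interval widths vary), pools all
chromosomes, bins into 100 relative-position bins and fits a cubic
smoothing spline to bin means. The roughness penalty is selected by
generalized cross-validation; when the GCV criterion has no interior
optimum a mild fixed penalty (1e-4) is used. The equal-sample map
correlation draws k meioses per breed without replacement, rebuilds
maps and averages Pearson correlations over repetitions, removing the
sample-size imbalance that otherwise dominates between-breed
correlation differences. Note the comparison is among *pools*: with
breed pools not much larger than k, pool idiosyncrasy (not resampling
noise) limits how closely exchangeable breeds agree.

## Phenotypes and GWAS

Genome-wide crossover counts are adjusted by OLS on SNP density (the
donor-offspring pair's typed-marker count, continuous), donor
informative markers and offspring informative markers, with intercept;
the per-animal phenotype is the mean residual over its meioses. The
adjustment is fitted within breed x sex so group differences in mean
count do not leak into residuals. Hotspot usage is the per-meiosis
share of crossover mass inside hotspot intervals, averaged over
meioses with at least one crossover (zero-crossover meioses are 0/0
and excluded).

The association model is y = Xg + Za + e with a ~ N(0, sigma_a^2 K)
and e ~ N(0, sigma_e^2 I). K is the VanRaden genomic relationship
matrix (columns centered by 2p, normalized by 2 * sum p(1-p),
missing genotypes mean-imputed); a pedigree numerator relationship
matrix via the tabular recursion is available as an alternative.
Variance components come from REML under the null model: K is
eigendecomposed once, the ratio delta = sigma_e^2/sigma_a^2 profiled
and optimized on log10 delta in [-5, 5] (coarse grid, then bounded
Brent). A flat profile (e.g. K = I, where only total variance is
identified) is flagged `indeterminate` and resolved to sigma_a^2 = 0,
making the scan exactly ordinary regression. The scan holds the fitted
covariance fixed (one-step/EMMAX-style approximation) and Wald-tests
each SNP by GLS through the cached rotation; monomorphic SNPs are
skipped. Fixed effects are intercept + SNP only. Sexes are analyzed
separately. Bonferroni thresholds divide alpha by the number of SNPs
actually tested.

## Synthetic cohorts

The generator emulates a multi-breed dairy-cattle pedigree study at
desk scale. Defaults: 10 autosomes x 400 SNPs (100 Mb each,
jittered but near-even spacing), genome lengths 24.8 (male) and 22.5
(female) expected crossovers per meiosis — the published Ayrshire
rates — 2% of intervals designated hotspots at 20x baseline intensity,
founder allele frequencies uniform on [0.05, 0.95] with unlinked SNPs,
a 75.7% / 24.3% mixture of a full and a half-density panel, 0.2%
symmetric allele-count error and 1% missing calls. Each family holds
five genotyped animals (grandsire, granddam, donor, mate, offspring);
only the donor-to-offspring meiosis is truth-recorded, because only it
is analyzable from the family structure.

Crossovers are placed by a plain Poisson process: per chromosome a
Poisson count with mean equal to the chromosome's intensity sum,
intervals chosen proportional to intensity, position uniform in bp
within the interval, starting haplotype fair per chromosome. No
crossover interference and no obligate chiasma — the analysis model
assumes neither, and the Poisson null is the simplest defensible
generative convention. Baseline intensity is uniform per interval
(hotspot enrichment multiplies it), so "rate per interval" and
"rate per Mb" differ only by the mild width jitter.

What the simulator does **not** emulate: linkage disequilibrium and
realistic haplotype structure (irrelevant to a purely pedigree-based
method), crossover interference, sex chromosomes, assembly errors,
family-size and breed-imbalance structure of industry pedigrees.
Passing tests therefore demonstrate correctness of the detection and
inference machinery under the stated generative model, not robustness
to assembly or LD artifacts in real data.

## Numerical and design choices

* Interval convention: interval i is (bp[i-1], bp[i]] stored on the row
  of SNP i; the first SNP of each chromosome carries rate 0. Map files
  are TSV with columns SNP, chromosome, bp, then one rate column per
  breed x sex in caller order.
* Mass conservation (sum of interval masses = crossover count) holds to
  float accumulation error (~1e-12 relative), since 1/k is not dyadic.
* Population (n-denominator) SD in the hotspot threshold; mean/SD over
  all intervals including zeros.
* Correlations use raw per-interval rates, all intervals, no transform.
* Chi-square scans run within sex; statistic symmetric in breed order.
* REML grid of 41 points in log10 delta brackets the Brent refinement;
  eigenvalues clipped at 0; the rotated restricted likelihood is
  validated against a dense-matrix implementation to 1e-8.
* Degenerate inputs: single-interval maps reject hotspot calling
  (SD undefined); constant maps yield undefined (NaN) correlations;
  zero-variance covariates are dropped from the adjustment with a
  warning; empty meiosis sets reject map construction.

## Problem sizes used in the checks

The packaged checks run at sizes chosen to make the statistical claims
sharp while staying desk-scale: 2,000 meioses per sex on a
10 x 1,000-SNP genome for the male/female map-length contrast (the
male excess is 10% with sampling SD about 0.8 percentage points, so
integer rounding can land on 9-11); 5,000 meioses on a 6 x 1,500-SNP
genome for truth recovery; 1,000 meioses per arm for chi-square
calibration; n = 500 for REML recovery and 200 animals x 2,000 SNPs
for scan calibration.

## Known limitations

* Crossovers beyond terminal informative sites are not imputed; maps
  slightly underestimate true genome length, proportionally in both
  sexes (the detected male/female contrast is unaffected).
* The adjusted-rate phenotype inherits any covariate misspecification;
  only linear covariate effects are removed.
* The one-step variance-component approximation understates per-SNP
  uncertainty marginally when a SNP explains a large variance share.
* Hotspot calling at SNP-panel resolution identifies enriched
  *regions*; kb-scale localization is out of scope.
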