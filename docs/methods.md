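# Methods

## Scope and data model

`longprs` analyses a binary longevity phenotype (1 = long-lived case,
0 = middle-aged control) against polygenic risk scores built from external
GWAS summary statistics, scored on the cohort's own genotypes. Genotypes
are diploid hard calls (VCF, GT field); dosages count the ALT allele and
missing calls are NaN throughout. All tables join on SNP id (rsID), with
a chromosome+position fallback when id sets are disjoint; inputs are
assumed to share one genome build, declared in the pipeline config
(coordinate conversion is out of scope).

## Target-data QC

SNP-level filters: missingness (default max 5% — configurable, since
chip-era studies vary), minor-allele frequency (default min 1%), and an
exact Hardy–Weinberg test (removal at p ≤ 10⁻⁵). The HWE test enumerates
the conditional distribution of the heterozygote count given allele
counts via log-gamma arithmetic and sums probabilities no larger than the
observed configuration's; no mid-p correction is applied, keeping the
statistic deterministic and oracle-checkable. HWE is evaluated in
controls only when a control mask is supplied, because genuine
case-enrichment at associated loci distorts HWE in cases. Sample-level QC
(relatedness, sex checks) is assumed done upstream.

## Summary-statistic harmonization

Each base-study row is matched to the target variant's allele pair with
four outcomes: direct match (kept), effect/other swap (beta negated),
complementary-strand flip (alleles rewritten A↔T, C↔G, then matched or
swapped), or exclusion. Strand-palindromic pairs (A/T, C/G) are excluded
by default — without frequency information their orientation is
undecidable — behind a `keep_palindromic` flag. Odds ratios are converted
by beta = ln(OR); p = 0 entries are clamped to the smallest positive
float. The harmonization report partitions the input row count exactly,
which the tests assert. `orient_to_risk` re-expresses negative effects on
the opposite allele so that all disease betas are non-negative
("risk-allele" orientation); it is idempotent and preserves |beta|, SE
and p.

## PRS engine

Scores follow the average-per-allele convention
`PRS_j = Σ S_i G_ij / M_j` with `M_j = 2 ×` (non-missing SNPs for j).
Missing genotypes drop out of both numerator and denominator (no mean
imputation); an individual with no scoreable SNP gets a missing score.
The per-SNP vs per-allele denominator choice is a constant factor that
cancels in regressions, and both are exposed (`mj_mode`).

Clumping is greedy by ascending p (ties by chromosome, then position, so
results are independent of input row order): each unassigned SNP becomes
an index and absorbs unassigned same-chromosome SNPs within ±500 kb with
r² > 0.1, r² being the squared Pearson correlation of dosages in the
target cohort itself (no external reference panel). The threshold ladder
runs from 5×10⁻⁸ up one order of magnitude per step, with the
no-threshold endpoint 1 appended; an optional dense ladder (step 5×10⁻⁵)
reproduces fine-grained best thresholds. Scores are z-standardized before
regression — coefficients become per-SD and p-values are unchanged — and
the smallest regression p marks the best row, ties resolved toward the
smaller (more parsimonious) threshold.

## Association statistics

Logistic fits use maximum likelihood (statsmodels) with Wald p-values;
under (quasi-)perfect separation — detected by a full-model
log-likelihood at zero, a non-finite SE, or a diverged coefficient — the
Wald statistic degenerates and the p-value falls back to the
likelihood-ratio test with a warning. Variance explained is Nagelkerke
pseudo-R², the rescaled Cox–Snell statistic, matching the convention of
standard PRS software. FDR control is Benjamini–Hochberg; the
implementation accepts a declared family size larger than the supplied
p-value list so that per-trait tables can be adjusted against the full
sets × traits family (e.g. 220 × 16 = 3520). Bonferroni thresholds are
plain alpha/m.

## Stratified and region-masked scores

Annotation sets arrive as BED intervals (0-based half-open, converted
internally to 1-based inclusive) or verbatim SNP-id lists, with an
optional set → group mapping whose group-level sets are unions of member
sets; sets may overlap. Each set is clumped *within itself* (mirroring
set-based PRS tools) and scored at threshold p ≤ 1 — both defaults are
configurable, since the upstream tools' exact defaults are not published.
Significance bins are (0, c₁], (c₁, c₂], … over the cutpoints 5×10⁻⁸,
10⁻⁷, 10⁻⁶, 10⁻⁵, 10⁻⁴, 10⁻³, 10⁻², 5×10⁻²; SNPs above the last cutpoint
are excluded, and the bins partition the remainder. Region masking drops
summary-statistic rows inside a 1-based endpoint-inclusive interval (the
bundled APOE region is chr19:45,361,224–45,436,657 on GRCh37).

LD blocks use the D′ confidence-interval rule: per SNP pair, haplotype
frequencies under random mating are profiled over a |D′| grid (the MLE
orientation fixed to positive D), the 90% likelihood interval is read off
the normalized grid, a pair is "strong LD" when the CI is within
[0.70, 1] with upper ≥ 0.98 and "recombinant" when the upper bound is
below 0.90, and a block is a maximal span whose outermost pair is strong
and in which ≥ 95% of informative pairs are strong. All parameters are
exposed.

## Pleiotropy dissection

From the disease's best-PRS SNPs (the disease best PRS anchors the
intersection), SNPs with p < 0.05 in both the risk-oriented disease table
and the longevity table are kept; the longevity beta is re-expressed on
the disease risk allele, and the sign of that aligned beta defines
panel 1 (> 0: raises disease risk *and* longevity odds) vs panel 2 (< 0).
Effect lookups report OR = exp(beta) with 95% CIs exp(beta ± 1.959964·SE).
Nearest-gene labels use the `NAME(dist = D)` convention, listing the
closest gene on each side for intergenic SNPs (comma-grouped distances
for D ≥ 10,000, matching the published table style); gene-set exports are
plain text for external enrichment tools — GO statistics themselves are
out of scope.

## All-PRS prediction

Per-trait best-PRS scores are inner-joined on individuals,
zero-variance columns dropped, and columns z-standardized. Candidate
families (L1/L2 logistic regression, linear-margin SVM, k-nearest
neighbours, Gaussian naive Bayes, decision tree, random forest — thin
wrappers over scikit-learn) are compared by mean validation accuracy over
repeated stratified k-fold CV (default k = 10; folds re-randomized each
iteration), AUC tracked alongside; the winner is refit on a stratified
80% split and evaluated on the held-out 20% (AUC, Nagelkerke pseudo-R²
from predicted probabilities, coefficients for linear winners). All
randomness — fold shuffles and the final split — derives from one seed
via spawned SeedSequences, so identical seeds give identical reports.
The logistic grid uses the liblinear solver (exact small-dimension
solutions, fast at desk scale); both the 80/20 split and the folds
re-randomize across iterations.

## Synthetic cohort generator

The generator exists to give every downstream stage data with the
statistical structure the analysis assumes, at desk scale.

*Genotypes.* A Gaussian copula: per LD block, a latent AR(1) normal
(lag-1 correlation `within_block_r`, the *latent* correlation) is
thresholded per haplotype at the normal quantile of the SNP's allele
frequency; genotype = sum of two independent haplotypes. This yields
exact HWE, tunable LD, and hard calls. Dichotomization attenuates
correlation: latent r = 0.9 at MAF 0.2–0.4 gives genotype r² ≈ 0.46
(Monte-Carlo calibrated, frozen in the tests). Blocks sit > 500 kb apart
so clump windows never span blocks. Allele pairs are drawn only from
non-palindromic combinations, so no planted signal is lost to strand
ambiguity at harmonization.

*Phenotype.* Liability threshold: liability = Σ planted longevity
log-odds × dosage + N(0,1); cases are the top `prevalence` fraction of
the empirical liability distribution. Default prevalence 0.5 mirrors the
balanced case/control design of centenarian studies (≈ 2,200 vs 2,300).

*Summary statistics.* Per SNP, SE = 1/√(2·N·maf·(1−maf)) — the
large-sample SE of a per-allele log-odds estimate — and the observed beta
is planted effect + SE·N(0,1), so realized z-scores are planted z + unit
noise, exactly as in a real GWAS of N samples. This is a planted-effect
simulation, not a second-cohort GWAS; a logistic-refit oracle in the
tests checks its calibration.

*Planted architectures.* `tradeoff_cohort` plants the bidirectional
significance-band structure: strong-band SNPs (disease z-scores in bands
at 6.4, 6.0 and 5.35) carry longevity effect −0.3 per allele; weak-band
SNPs (bands at 4.0, 3.4, 2.6, 2.25) carry +0.15. Because realized
z-scores wander with unit noise, a band placed near the p = 10⁻⁵ bin
boundary contaminates its neighbour; the band positions and counts (70,
570, 240 strong; 170, 530, 650, 170 weak) were chosen from an analytic
composition model — expected signed effect mass per significance bin
under N(0,1) z-noise, requiring ≥ ~3 SD margin of the correct sign in
every bin — and then frozen. Notably, the model shows the boundary bins
are best served by planting *no* strong SNPs near the boundary and
letting downward leakage from z ≥ 5.35 populate bin 4. The paper-scale
phenomenon (thousands of SNPs per bin) makes this easy; at 2,400 SNPs the
margins are the binding constraint. `annotated_cohort` plants two
annotation sets with opposite longevity effects (±0.2) and equal positive
disease effects (z ≈ 4), so stratified-score weights are informative and
the group directions are recoverable.

*What the generator does not emulate.* Population structure and
relatedness, imputation dosages/uncertainty, X-chromosome inheritance,
realistic genome-wide LD beyond block-diagonal AR(1), allele-frequency–
effect-size coupling, and between-cohort heterogeneity. Passing
recovery tests therefore demonstrates that the pipeline's inference
machinery is correct under its stated assumptions, not that any
particular real-data association would replicate.

## Numerical choices and problem sizes

Recovery checks run 10–20 seeded replicates at n = 4,000 individuals and
~2,400 SNPs (trade-off structure) or ~340 SNPs (annotation structure);
type-I-error calibration uses 500–1,000 null fits at n = 5,000;
permutation nulls re-permute labels each iteration. Exact-arithmetic
oracles (clumping re-scan, weighted-sum scoring, BH step-up, HWE
enumeration) are compared at 10⁻¹⁰–10⁻¹² tolerances; Monte-Carlo bands
are frozen from 20-replicate calibrations. p-values of 0 are clamped to
the smallest positive float; zero-variance predictors and empty SNP sets
are skipped with log entries rather than propagated as NaNs.

## Known limitations

Clumping LD always comes from the target cohort (no reference panel
option). The D′ CI block finder is an emulation of the published
CI-based viewers, not a reimplementation of any specific tool, and its
grid resolution (101 points) bounds CI precision at 0.01. The classifier
comparison optimizes mean accuracy (AUC reported alongside); with heavily
imbalanced phenotypes accuracy selection would be inappropriate, but the
design targets balanced case/control cohorts. GO enrichment, genotype
imputation, PCA stratification control, and LiftOver are intentionally
outside the package.
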