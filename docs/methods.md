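# Methods

## Data model and conventions

Genotypes are biallelic autosomal risk-allele counts (dosages) in
{0, 1, 2}; allele-pair cells ("C/G", order- and phase-separator-insensitive)
are resolved against each variant's declared effect allele at read time.
All analyses are restricted to complete cases: subjects with any missing
call are dropped before any statistic is computed, and the filter is
idempotent. Sex enters regression design matrices as male = 1, female = 0;
age enters in years, untransformed. Phenotype is strictly two-level
(case/control).

## RFLP genotype calling

Each allele of a variant has a digest fragment pattern; a heterozygote is
modelled as the union of the two allele patterns with shared lengths
collapsing to one band (co-dominant banding, the standard reading of an
RFLP gel). Calling compares the observed band multiset against the three
expected genotype patterns using greedy nearest one-to-one matching with a
per-band tolerance `tol_bp` (default 5 bp, a typical agarose sizing error).
Fragments below `min_detectable_bp` (default 50 bp — small digest products
do not resolve reliably on 3% agarose) are removed from *both* the observed
and expected sets so matching stays symmetric; the bundled TM6SF2 assay has
a 33 bp fragment that this filter removes. A call is made only when exactly
one genotype matches; anything else is a `no_call` with diagnostics listing
unexplained and undetected bands. `validate_patterns` warns when an
allele's fragments do not sum to the amplicon length: the bundled TM6SF2
C-allele pattern (178+33+85 against a 429 bp product) fails this check as
published and is deliberately kept as-is rather than silently corrected —
users may supply a corrected pattern file.

## Frequencies, Hardy–Weinberg and contingency tests

Allele frequencies are direct counts: effect-allele count
`2·n_homalt + n_het` over `2n` alleles. The Hardy–Weinberg test is the
Pearson 1-df chi-square against expected counts `n(1−p)², 2np(1−p), np²`
at the observed allele frequency (the exact test is not used; the
chi-square convention reproduces the study's published per-cohort HWE
p-values 0.078/0.699/0.427/0.221 from the printed genotype counts, which
the suite pins to three decimals). A monomorphic sample returns χ² = 0,
p = 1, flagged untestable. Contingency tests use the Pearson chi-square
without continuity correction; `auto` routes 2×2 tables with any expected
cell below 5 to the two-sided Fisher exact test. Crude 2×2 odds ratios are
cross-products with Woolf CIs `exp(ln OR ± 1.96·√Σ1/cell)`; the Haldane
correction (+0.5 per cell) is applied on request or automatically when a
zero cell is present, and suppressing it yields an infinite/zero OR with
an undefined CI, flagged rather than raised.

## Logistic and Firth regression

One Newton–Raphson solver with step-halving drives both fits. Convergence
requires a maximum coefficient change below 1e-8 within 50 iterations, with
up to 10 halvings per step; the accepted (penalized) log-likelihood is
non-decreasing by construction. A secondary stop accepts convergence when
the objective is flat to 1e-13 and the step is below 1e-7 — near the
optimum the Newton step can cycle at machine precision just above the
primary tolerance. Rank-deficient designs raise immediately. Separation
(monotone likelihood) is flagged when coefficients exceed |30| on the
log-odds scale or iterations exhaust while the likelihood still improves;
the flagged ML fit is returned with the recommendation to refit by Firth.

The Firth fit maximizes `ℓ(β) + ½ log det I(β)` (Jeffreys-prior penalty).
The score correction uses hat values h_i of the weighted design: the
working residual is `y_i − π_i + h_i(½ − π_i)`; frequency weights aggregate
identical covariate patterns with the leverage summed across the pattern.
Wald CIs come from the inverse penalized information. On a single binary
covariate the Firth estimate equals the Haldane-corrected cross-product
ratio in closed form, and the ML estimate equals the crude cross-product —
both identities serve as oracles at 1e-6 in the tests, alongside a
statsmodels cross-check of the ML path.

Genetic models encode the dosage g as: additive g; dominant 1{g ≥ 1};
recessive 1{g = 2}; genotypic the indicator pair (1{g=1}, 1{g=2}); the
allelic model is a per-allele 2×2 contrast (two alleles per subject)
reported as a crude OR. Covariate-adjusted fits add age and sex; `auto`
estimation fits ML and falls back to Firth on separation.

## PRS, strata and group comparison

The score is the β-weighted mean of genotype points g/2 normalized by Σβ,
hence bounded in [0, 1], permutation-invariant in the variant order and
monotone in every dosage. With two variants there are exactly nine score
levels. Strata follow the published convention: low is exactly score 0
(double wild type), moderate (0, c], high > c with c = 0.26 kept as a
fixed default taken from the published grouping rather than recomputed
empirical tertiles — the study labels the groups tertiles but defines the
reference as score = 0, which is not a third of the cohort, so the printed
cutpoints win; an empirical-tertile helper is provided separately. The
Wilcoxon rank-sum comparison uses exact enumeration of rank assignments
(mid-ranks for ties) when both groups have ≤ 10 subjects, and otherwise
the normal approximation with tie-corrected variance and 0.5 continuity
correction. SDs are reported with the n−1 denominator.

## Validation

AUC is the rank (Mann–Whitney) estimator with 0.5 credit for ties.
Bootstrap optimism correction is Harrell-style: per resample, refit the
declared model on the resample, record AUC on the resample minus AUC of
that refit applied to the original data; corrected = apparent − mean
optimism. A fixed-weight PRS declares nothing refit, so its optimism is
zero up to Monte-Carlo noise. Resampling is simple (non-stratified);
single-class resamples are redrawn and counted. The 95% CI is the
percentile interval of the bootstrap AUCs. The calibration slope is the
coefficient from refitting outcomes on a model's linear predictor (1 by
construction for a self-fit ML model — a property test, and the package
reports it as an apparent, refit-on-self quantity). Hosmer–Lemeshow bins
subjects by predicted probability into near-equal groups (default 10) with
ties kept in one bin and degenerate bins merged; χ² sums (O−E)²/E over
events and non-events, df = bins − 2 (deciles → 8). With a few-level
predictor such as a two-SNP PRS the realized bin count, and hence df,
shrinks.

## Synthetic cohorts

The generator provides the study conditions rather than tunable fiction:

- **hwe_cohort** draws genotypes per cohort from HWE proportions at the
  given allele frequencies. The two loci are coupled through a single
  dosage-level odds-ratio parameter θ: the joint 3×3 table is the iterative
  proportional fit (IPF) of the seed matrix θ^(i·j) to the HWE marginals;
  θ = 1 is independence.
- **disease_model** draws population genotypes under HWE and assigns case
  status from a logistic model `expit(α + Σθ_i d_i + γ_age·age +
  γ_sex·sex)`, sampling in batches until the case and control quotas fill;
  the truth is returned for parameter-recovery testing. An effectively
  zero (or one) case rate raises rather than looping.
- **reconstruct** expands published per-cohort genotype counts exactly:
  the real-valued IPF target (marginal proportions × n under the chosen
  coupling) is rounded by a largest-remainder scheme restricted to cells
  whose row and column still have a deficit, which preserves both margins
  exactly for every coupling and seed, then expanded to one record per
  subject.

Ages are Normal(58.5, 10²) years truncated at 18 and sex is
Bernoulli(0.87 male), matching the study cohort demographics; they are
covariate plumbing with no effect on risk unless the disease model sets
one. All randomness flows from one recorded seed.

What the generator does *not* emulate: linkage disequilibrium from real
haplotype structure, population stratification, genotyping error, and —
for reconstruction — the true joint two-locus distribution, which the
published per-variant counts do not identify. Quantities that are
marginal-sufficient (allele frequencies, HWE, per-variant ORs, cohort mean
PRS) are therefore exactly reproducible, while joint-dependent quantities
(strata sizes and ORs, score SDs, AUC) vary with the chosen coupling and
are reported as consistency checks, not reproductions.

## Problem sizes and numerical choices

Default pipeline settings mirror the study parameters: 1000 bootstrap
resamples, 10 Hosmer–Lemeshow groups, FDR levels 0.05 and 0.1, stratum
cutpoint 0.26. The test suite exercises the stochastic claims at sizes
chosen to keep the whole run fast while leaving Monte-Carlo noise well
below the asserted margins: optimism of a fixed score at n = 249 with
B = 200; estimator coverage with 200 replicates of 2000+2000 subjects
(Wald 95% CIs cover the true per-allele log-ORs 0.69/0.41 in ≥ 90% of
replicates); closed-form Firth/ML equivalence over 1000 random 2×2 tables.
Report tables round ORs and frequencies to 2 decimals and p-values and PRS
means to 3; the machine-readable metrics file keeps full precision, and
identical config + seed reproduces the bundle byte-for-byte.

## Known limitations

- Two-variant panels only in the bundled defaults; the PRS and IPF
  coupling machinery assume one or two loci (n-variant scores work, but
  coupling is pairwise).
- No imputation dosages, multi-allelic sites, liftover or phasing.
- Profile-penalized-likelihood CIs for Firth fits are not implemented
  (Wald only); no exact/permutation genotype association tests or trend
  tests.
- The published adjusted ORs and validation statistics depend on the
  unpublished individual-level joint data, so the package reproduces them
  only up to coupling uncertainty, as described above.
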