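# Methods

This note documents the statistical model behind `xburden`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not establish.

## Study design and subject classification

The analysis targets an extreme-phenotype, male-only, X-linked design:
cases are PCR-confirmed males under an age cutoff (default 60 years) in
clinical category 3 (hospitalized, CPAP/BiPAP) or 4 (hospitalized,
intubated); controls are confirmed males under the cutoff in category 0
(oligo-asymptomatic, not hospitalized).  Intermediate categories 1–2,
unconfirmed infections, subjects at or above the cutoff, and non-males are
excluded.  Because the cohort is male and the loci X-linked, every subject
is hemizygous: any non-reference genotype call (`1`, `0/1`, `1/1` — caller
dialects differ for male X calls) marks a carrier.

## Variant qualification and the boolean burden

A variant qualifies for the gene burden iff its consequence class is
missense, splicing (taken as the superset of splice-donor, splice-acceptor
and splice-region annotations) or loss-of-function, and it is rare: NFE
allele frequency ≤ 1%, or missing.  Treating a missing frequency as rare is
deliberate — very rare alleles are exactly the ones absent from reference
panels — and is exposed as a configuration flag.  The *candidate* rule adds
CADD ≥ 12.28.  The threshold is applied **inclusively**: a catalogued
carrier variant scores exactly 12.28, so a strict inequality would
contradict the carrier counts the rule must reproduce.  A missing CADD
score never qualifies (no imputation), with a warning.

The burden matrix entry (s, g) is 1 iff subject *s* carries at least one
qualifying variant in gene *g*; the collapse is idempotent by construction.
The gene universe defaults to the genes observed among qualifying variants;
a fixed X-gene list can be supplied to pin the column space.  Columns are
ordered lexicographically for determinism.

## PCA outlier removal

Principal components are computed on the column-centered, *unscaled* burden
matrix — all columns share the {0,1} scale, so variance-standardization
would only inflate near-constant columns.  A subject is flagged iff its
score deviates from the per-component mean by more than 5 population SDs on
any of the first three components; ties at exactly 5 SD are kept.  Flagging
is a single pass (statistics are not re-estimated after removal), matching
a one-shot QC step applied before regression.  The component sign convention
(largest-magnitude loading positive) makes scores reproducible across
platforms.

## Class-weighted L1 logistic regression

The model minimizes

    f(β₀, β) = (1/n) Σᵢ w_{yᵢ} [log(1 + exp(ηᵢ)) − yᵢηᵢ] + λ‖β‖₁

with ηᵢ = β₀ + xᵢ·β and balanced class weights w_c = n/(2n_c): the
minority class is up-weighted inversely to its frequency, and the weighted
effective sample size stays n.  The intercept is unpenalized.  Features are
not standardized (shared boolean scale); a flag can enable it.

**Solver.**  Cyclic coordinate descent with soft-thresholding on the local
quadratic (IRLS) approximation of the weighted loss.  Each outer iteration
re-forms the quadratic at the current iterate, admits features through a
vectorized KKT-violation check, and runs CD sweeps over the active set (a
numba kernel).  Two safeguards handle quasi-separation, which the small-λ
end of the grid routinely produces on boolean matrices with n < G: the IRLS
curvature is floored at 1e-4 per sample (probabilities clipped at 1e-5), and
a backtracking line search rejects any outer step that would increase the
objective, so the objective decreases monotonically across iterations.
Convergence requires an objective change below `tol` (default 1e-7) *and*
no remaining KKT violation among zero coefficients; non-convergence within
`max_iter` outer iterations raises with diagnostics.  The solver's optimum
matches a generic convex optimizer to ≤1e-6 on random small instances
(tested), and λ ≥ λ_max = max_j |(1/n) Σᵢ w_i(yᵢ − p̄)x_ij| returns the
exactly-zero vector by the KKT condition at the null solution.

**Cross-validation.**  Stratified k-fold (default 10) with shuffling from a
caller-provided seed; stratification avoids class-empty folds at n ≈ 156.
The penalty grid is log-spaced over [10⁻⁴·λ_max, λ_max] (default 50 points),
fitted with warm starts from large to small λ.  The chosen penalty
maximizes mean fold accuracy, ties resolved to the larger (sparser) penalty.
Out-of-fold predicted probabilities at the chosen penalty are pooled into a
single confusion matrix; hard labels use a 0.5 threshold; ROC-AUC is the
Mann-Whitney statistic with midrank ties; ratios with zero denominators are
reported missing (NaN), never zero.  Gene ranking sorts nonzero
coefficients by |β| (ties lexicographic), annotated susceptible (β > 0) or
protective (β < 0).

## Exact-test validation

The two-sided Fisher exact p-value uses the point-probability convention:
the sum, over all 2×2 tables with the observed margins, of hypergeometric
point probabilities not exceeding the observed table's probability (relative
slack 1+1e-7 guards ties against floating-point rounding).  Evaluation is
via the exact hypergeometric pmf; no normal approximation.  On the combined
young-male carrier table ([[129, 6], [104, 0]]) this yields p = 0.0372,
matching the published two-sided 0.037; the one-sided value is ≈0.031.  A
companion table footnote printing "0.0037" is inconsistent with the
enumeration and is treated as a typographical slip of the same 0.037.

The odds ratio is oriented as carrier odds in the severe arm over carrier
odds in the asymptomatic arm; with any zero cell and correction enabled,
0.5 is added to every cell (Haldane–Anscombe), giving 10.49 on the table
above.  Carrier-fraction summaries count distinct carrier patients (a
patient with two qualifying variants counts once) per stratum — age window
(under the cutoff vs all ages) × qualification rule (in-silico candidate vs
experimentally determined functional class ∈ {LOF, HYPO}) — over
caller-supplied denominators, with percentages formatted to one decimal by
round-half-even.  Functional classes encode wet-lab results and are always
consumed as annotations, never computed.

## qPCR relative quantification

Replicate Cts are averaged on the Ct scale (standard Livak procedure),
then ΔCt = Ct_target − Ct_housekeeping within each condition and
ΔΔCt = ΔCt_stimulated − ΔCt_medium; fold change = 2^−ΔΔCt.  Group
comparisons use the pooled-variance Student t-test on log2 fold changes
(df = n_a + n_b − 2); Welch is available via a flag; the t statistic and
p-value are invariant to the log base.  No replicate outlier rejection and
no amplification-efficiency correction are applied.

## Synthetic cohort generator

The generator emulates the study conditions: 79 severe cases vs 77
asymptomatic controls by default, all male, ages uniform on [20, 59]
(optional rows ≥ 60 exercise the age filter), cases in categories 3–4,
controls in 0.  Per subject and gene, burden is an independent Bernoulli
draw at a 2% background rate; the planted susceptibility gene instead uses
arm-specific carrier frequencies (defaults 6.33% in cases — the published
first-wave 5/79 — and 0% in controls).  Each burdened pair is materialized
as one qualifying variant record (rare log-uniform AF on [1e-6, 0.01], 5%
missing; CADD uniform on [12.28, 30]; consequence mix 70% missense / 15%
splicing / 15% LOF), with an option for a second record to exercise the
at-least-one collapse.  Distractor records that must not reach the matrix
(rare synonymous, or common missense with benign CADD on [0, 12.27]) are
added at a 2% rate.  Genotypes are written as hemizygous single-allele
calls in VCF 4.2 with INFO keys GENE/CSQ/NFE_AF/CADD.  Everything derives
from one integer seed; identical seeds reproduce byte-identical files.

Ct plates model a housekeeping gene at 24 cycles in both conditions and
target genes at 28 cycles in medium, induced by 3 log2 units (8-fold) under
stimulation; functional-variant carriers lose `qpcr_effect_log2` (default
2) of that induction; Gaussian noise (default SD 0.2 cycles) is added per
replicate measurement.  The noise-free expectations reproduce the ΔΔCt
arithmetic exactly.

**What the generator does not emulate:** linkage between variants,
population structure or relatedness (beyond optional planted outlier rows),
per-gene variation in mutational target size, genotyping error, and
covariate effects (age, comorbidity).  Passing tests therefore establish
the correctness and calibration of the machinery under the assumed
independence structure, not performance on real cohorts.

## Simulation scales and empirical checks

The test suite and the acceptance script verify, at the scales noted:
exact-test agreement with full rational enumeration on all tables with
cells ≤ 12–30; solver-vs-oracle objective agreement on ≥ 20 random small
instances; generator calibration over 1,000 replicate cohorts; null
calibration of cross-validated accuracy over 100–200 permuted-label cohorts
(156 × 300, 10 folds, 10-point grid); exact-test and log-t type-I error
over 1,000–2,000 null simulations; and planted-gene recovery over 100
cohorts at the study design, ranking features from a fit at λ = 0.3·λ_max
(a sparsity level that retains a few dozen genes; cross-validated penalty
selection gives the same ordering at far higher cost).

Two measurement choices deserve note.  First, null calibration reports the
cross-validated accuracy **averaged over the penalty grid**: the accuracy
at the selected penalty is upward-biased under the null by the selection
itself (a winner's curse over the grid, ≈ +0.03 at these dimensions), so it
is the grid average that should center at the weighted baseline of 0.5.
Second, planted-gene recovery is intrinsically limited by the design's
signal: with 79 cases at 6% carrier frequency the planted gene draws ≤ 3
carriers in ≈ 30% of cohorts, while among 300 background genes at 2%
burden a dozen or so per cohort carry ≥ 3 case-only carriers by chance.
Even an oracle ranking genes by the exact case−control carrier-count
difference tops three in only ≈ 66% of cohorts, so observed recovery rates
near 55–60% reflect the information ceiling of the design, not solver
quality.

## Known limitations

- The penalty parameterization is λ on the per-sample-averaged loss;
  penalty values from other parameterizations (e.g. inverse-regularization
  constants) are not comparable.
- The exact test is conservative for discrete data; no confidence interval
  is attached to the exact p.
- No multiple-testing correction is applied: the validation tests one
  pre-selected gene.
- Missing CADD scores exclude a variant from the candidate rule rather than
  being imputed.
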