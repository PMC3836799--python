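# Methods

## Statistical model

Case-control status is modelled by additive logistic regression on marker
dosages. A *marker* is always a biallelic presence/absence recoding: each
allele of a multi-allelic variant (a classical HLA allele, an amino-acid
residue at a protein position, an allele of a possibly multi-allelic SNP,
or a two-locus cis diplotype) becomes its own column with dosage in
[0, 2]. Hard phased calls give integer dosages; if per-call imputation
posteriors are supplied, dosages are expected counts and the per-locus
sum-to-2 constraint holds only in expectation (asserted to 1e-6 in tests).

Every model contains an intercept, the top principal components (default
5, consumed as given covariates — the package never computes PCA), and
`n-1` indicator covariates for `n` study strata. Using one pooled model
with stratum dummies encodes the assumption that genetic effects are fixed
across strata; it is not an inverse-variance meta-analysis.

### Omnibus tests and degrees of freedom

A variant with `p` alleles is tested by adding its `p-1` non-reference
allele columns jointly and comparing likelihoods: `D = 2(L1 - L0)`
referred to chi-square with `k` degrees of freedom. The reference allele
is the most frequent among controls. `k` is computed as the difference in
*rank* between the two designs, with rank determined by a greedy
orthogonalization in column order (intercept, covariates, conditioning
terms, then test terms; relative tolerance 1e-8). This makes the df
bookkeeping exact in the presence of structural collinearity — each
complete multi-allelic group sums to the constant 2, gene-level tests
overlap their conditioning sets, and perfectly tagged markers appear
routinely. A test whose columns are entirely absorbed by the conditioning
set comes back with df 0 and is reported as undefined rather than given a
spurious p-value. Because column order fixes which of several collinear
columns is retained, conditioning terms always take precedence over newly
tested terms; the likelihood, deviance and rank are invariant to that
choice. For gene-level (residual locus) tests the omnibus result also
records the number of columns offered before aliasing, so both df
conventions (all alleles vs. rank after the group-sum constraint) are
visible.

Gene-level tests ("residual locus effect") jointly test all of a gene's
four-digit allele columns not already conditioned on.

### Numerics

The fitter is Newton-Raphson with step-halving, started from zero
(deterministic), gradient tolerance 1e-8 (scaled by n), at most 100
iterations. Complete separation is flagged when any coefficient exceeds
15 on the log-odds scale; flagged fits are excluded from ranking rather
than reported with runaway estimates. P-values are computed and stored as
log10: the chi-square upper tail uses `chi2.logsf` where finite and
switches to the asymptotic expansion
`sf ≈ exp(-d/2) (d/2)^(k/2-1) / Γ(k/2) · Σ_j Π_i (k/2-i) / (d/2)^j`
once the survival function underflows (deviance ≳ 1420), so conditional
scans remain well-ordered at arbitrarily extreme significance.

### Stepwise engine

`forward_scan` ranks all candidate variants by conditional omnibus
p-value (ties broken by larger deviance, then lexicographic id — scans are
fully deterministic), absorbs the top hit's whole `p-1` column block into
the conditioning set, recomputes every gene's residual test, and repeats.
The stopping rule: terminate only when the best variant *and* every gene
residual exceed the significance threshold; if only a gene residual is
significant, variants keep being added until it dissolves. The threshold
defaults to 1e-5 (0.05 Bonferroni-corrected for 5,000 tests) and is
applied unchanged at every step; no per-step correction is attempted. A
step cap (default 25) guards against misconfigured thresholds. Variants
with r² = 1 to a selected variant are recorded as statistically
equivalent and removed from the candidate pool instead of being re-tested.
Every step's ranking is retained, and replaying any recorded conditioning
state reproduces the recorded p-values exactly.

`within_locus_selection` runs the same loop over one gene's four-digit
alleles with the residual locus test as the stopping rule, so the final
allele added need not itself clear the study-wide threshold.
`aa_stepwise` selects amino-acid positions (each position enters as its
residues-minus-reference block) and, if asked, adjudicates the selected
amino-acid block against a classical-allele block by testing each block
conditional on the other — the standard device for comparing non-nested
marker sets on the same data.

Variance explained is Nagelkerke's pseudo-R²,
`[1 - (L0/L1)^(2/N)] / [1 - L0^(2/N)]`, computed in log space and clipped
to [0, 1]; along nested model chains it is monotone non-decreasing up to
convergence tolerance.

### Regularized cross-checks

Lasso and elastic net use the binomial deviance loss, fitted by FISTA
(proximal gradient with Nesterov acceleration; Lipschitz constant from the
Gram spectrum; convergence 1e-9 on the max coefficient change) with the
intercept, PCs and stratum dummies unpenalized — the reason for a
hand-rolled solver is precisely that per-block penalty exemption. Allele
columns are standardized internally; reported coefficients are rescaled to
per-dosage units. The penalty grid is 30 log-spaced values from the
smallest all-zero lambda down by 1e-3, and the chosen penalty is the
largest whose 10-fold cross-validated deviance is within one standard
error of the minimum (folds stratified by case status, fold assignment
seeded). The elastic-net mixing parameter defaults to 0.5.

Least-angle regression and incremental forward stagewise are the classical
squared-error path algorithms; they run on outcome and allele columns
residualized on the covariate block (QR projection). Stagewise uses step
size 0.01 on standardized columns and stops when the maximum working
correlation falls below half a step. Model size along either path is
chosen by the same one-standard-error rule applied to cross-validated
squared error of OLS refits on each active set, read in the
parsimony-first direction (smallest size within one SE). Both methods also
report the order in which alleles enter, which is how cross-method
agreement is assessed: each method's first `k` entries are compared with
the `k`-allele stepwise selection. Exact active-set equality at the 1-SE
penalty is deliberately *not* the agreement criterion — shrinkage
solutions legitimately retain an extra near-null allele (the elastic net
does so on the benchmark here).

### cis-eQTL screen

SNP-gene pairs are formed within a 2 Mb window of the TSS (boundary
inclusive, strand ignored; a configurable always-include list exempts
chosen genes, e.g. classical HLA genes, from the distance rule).
Association is Spearman rank correlation with mid-ranks for ties and the
large-sample t approximation for the nominal p. Significance is
calibrated per gene: expression is permuted 10,000 times (per-gene
independent seeded streams), each permutation contributes the minimum
nominal p over the gene's cis SNPs, and a pair is called significant when
its nominal p falls below the 5th percentile of that null. Since the null
minimum is taken over the gene's actual LD-correlated SNPs, the implied
threshold automatically interpolates between the nominal 0.05 (one SNP)
and the Bonferroni bound (independent SNPs), and is invariant to
duplicating a SNP column. By default the per-gene threshold is applied to
all of the gene's cis SNPs; a best-SNP-only mode restricts the call to
each gene's top association. Confounder adjustment is accepted as a
precomputed residual matrix; the included covariate residualizer exists
for synthetic data only.

## Synthetic data generator

Cohorts are drawn from a finite pool of phased multi-locus haplotypes:
each subject is two independent draws, so LD between any two markers is
exactly the LD implied by the haplotype frequencies. Case status follows
the same logistic model the analysis assumes — per-allele additive
log-odds, stratum intercepts, optional standard-normal PC covariates with
optional effects. Strata can be filled naturally (case fraction set by
the intercept) or to exact case/control quotas by rejection sampling, the
retrospective analogue under which logistic slopes remain consistent.
Expression traits are `alpha + gamma * dosage + N(0, sd)` per gene. A
single integer seed makes cohort, phenotype and expression byte-identical
across runs.

What the generator deliberately does **not** emulate: recombination and
mutation (haplotypes are drawn intact), imputation error beyond an
optional per-call posterior, genuine population stratification (PCs are
synthetic covariates, not functions of genotype), sex, and
genomic-control-style inflation. Passing tests therefore demonstrate the
statistical machinery's correctness on data satisfying its own
assumptions, not robustness to the full messiness of real imputed data.

The built-in `example_mhc_pool` (11 haplotypes over DRB1, DQA1, DQB1, A, B
and three SNPs) reproduces the qualitative features that make MHC
fine-mapping hard: a 0.15-frequency class II risk haplotype with its
DQB1 tag at r² just below 1, six DRB1 alleles spanning 0.02-0.25, and
pervasive cross-locus LD. The eight-stratum study design ships with the
printed per-stratum sizes (totals 5,091 cases / 9,599 controls).

## Benchmark study designs

`benchmarks.py` freezes the package's reference scenarios:

- **OR recovery**: one planted effect of OR 2.92 at haplotype frequency
  0.15, 4,000 cases / 4,000 controls per replicate; the fitted 95% CI
  should cover the truth in ~95% of replicates.
- **Null calibration**: 200 near-independent SNPs (400-haplotype random
  pool), cohorts of n = 1,000, no effects; the omnibus test's type-I
  error at alpha 0.05 is checked over 1,000 replicates.
- **Three-effect scan**: ORs 2.9 / 1.4 / 1.3 at three loci, 5,000 cases /
  9,500 controls. This harness draws its haplotypes with the three loci
  in linkage equilibrium (400 haplotypes, realistic per-locus
  frequencies): under strong cross-locus LD every marker is a partial
  proxy of every effect and "exactly the planted variants" ceases to be a
  well-posed recovery target, while perfect proxies (two-digit families
  with a single member) remain and are scored through the equivalence
  annotation.
- **Six-allele within-locus selection**: six DRB1 alleles with ORs
  2.92 / 1.45 / 2.20 / 1.80 / 0.70 / 0.45 at frequencies 0.15 / 0.10 /
  0.02 / 0.03 / 0.08 / 0.02, n = 15,000. Effect magnitudes are set so
  every conditional signal carries z ≳ 8: the stopping rule is a residual
  locus test whose 3-4 degrees of freedom dilute single-allele signals,
  so a recovery harness must plant effects comfortably above that
  detection edge. The same data feed the four regularized methods for the
  cross-method agreement check.

Problem sizes in the test suite and `scripts/acceptance.py` (200
calibration replicates there, 1,000 in the suite; 10 vs 25 scan
replicates) were chosen so each stage still exercises its full pipeline
at meaningful power.

## Known limitations

- Wald and score tests are not offered; inference is LRT-only by design.
- The stepwise engine treats imputation dosages as fixed covariates;
  imputation-aware likelihoods are out of scope, and diplotype analyses
  on phased calls share the usual caveat that phase uncertainty makes
  their p-values slightly anti-conservative.
- The MAF filter (strictly-less-than 1% by default) is pooled across
  strata unless per-stratum filtering is requested; with very unbalanced
  strata a marker common overall can still be near-monomorphic in a small
  stratum and fit unstably (such fits are flagged via the separation
  guard).
- The permutation eQTL null assumes exchangeable subjects within a gene;
  expression batch structure must be removed upstream.
- `read_snp_vcf` expects complete, phased diploid genotypes; it does not
  handle missing calls or unphased data.
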