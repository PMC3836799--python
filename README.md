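# mhcfinemap

Fine-mapping of disease associations in the major histocompatibility
complex (MHC), for statistical geneticists working with imputed classical
HLA alleles, their amino-acid sequences, and dense SNP data in
case-control cohorts.

The MHC is the hardest region of the genome to fine-map: classical HLA
genes are hugely multi-allelic, long-range linkage disequilibrium couples
markers megabases apart, and candidate variants come in four different
shapes (SNPs, two- and four-digit classical alleles, amino-acid residues).
`mhcfinemap` implements the standard conditional-analysis framework for
this problem end to end, together with a synthetic-data generator that
plants known effects on realistic haplotype structure, so every stage can
be validated against ground truth.

## The model

Every variant is coded as biallelic presence/absence markers: an allele's
dosage is the number of haplotypes carrying it (0/1/2 for hard calls,
expected counts when imputation posteriors are supplied). Case-control
status is modelled by additive logistic regression,

```
logit P(y=1) = b0 + sum_j b_j x_j + sum_l c_l PC_l + sum_s d_s I(stratum s)
```

with the top principal components and `n-1` dummy variables for `n` study
strata as covariates (genetic effects are treated as fixed across strata).
A variant with `p` alleles enters as `p-1` markers — the reference allele,
the most frequent among controls, is dropped — and its **omnibus test** is
the likelihood-ratio statistic `D = 2(L1 - L0) ~ chi-square(k)`, where `k`
is the *rank* difference between the nested designs, so exactly collinear
columns (a multi-allelic group always sums to 2) never inflate the degrees
of freedom. P-values are kept in log10 space; the chi-square tail is
evaluated analytically far past 1e-300.

On top of this sit:

- **conditional forward stepwise selection** (`forward_scan`): rank all
  variants by conditional omnibus p, absorb the top hit into the model,
  repeat; stop only when no variant *and* no gene-level residual test
  (joint test of a gene's remaining four-digit alleles) reaches the
  a-priori threshold `0.05 / 5000 = 1e-5`. Variants in perfect LD with a
  selected variant are annotated as statistically equivalent.
- **within-locus selection** (`within_locus_selection`) with the residual
  locus effect as the stopping rule, and **amino-acid position stepwise**
  (`aa_stepwise`) with paired conditional LRTs to adjudicate an amino-acid
  model against a classical-allele model.
- **effect adjudication** (`compare_effects`): fit `M_A`, `M_B`, `M_AB`
  and test each variant given the other at nominal alpha 0.05 —
  "equivalent", "A explains B", or "independent".
- **regularized cross-checks** (`penalized_select`): lasso and elastic-net
  penalized logistic regression (covariates never penalized; penalty by
  10-fold cross-validation with the one-standard-error rule), plus
  least-angle and incremental forward-stagewise paths on covariate-
  residualized data.
- **variance explained**: Nagelkerke's pseudo-R²,
  `[1 - (L0/L1)^(2/N)] / [1 - L0^(2/N)]`.
- a **permutation-calibrated cis-eQTL screen**: Spearman rank correlation
  of SNP dosage with adjusted expression within 2 Mb of each TSS, with a
  per-gene null distribution of the minimum p over 10,000 expression
  permutations.

## Worked example

Simulate an eight-stratum case-control study (5,091 cases, 9,599 controls,
the per-stratum sizes of a large MS meta-analysis design) with two planted
effects — a risk allele with OR 2.92 on a class II haplotype and a
protective class I allele with OR 0.70 riding partly on the same
haplotype — then encode and scan:

```python
import math
import mhcfinemap as mf
from mhcfinemap import benchmarks as bm
from mhcfinemap.stepwise import forward_scan, variance_report

pool = mf.example_mhc_pool()
cfg = mf.SimulationConfig(
    strata=mf.table1_strata(),
    effects={"DRB1*15:01": math.log(2.92), "A*02:01": math.log(0.70)},
    n_pcs=5,
    seed=42,
)
cohort = mf.sample_cohort(pool, cfg)
dm = bm.encode_cohort(cohort)          # 4-digit + 2-digit + SNP markers, MAF >= 1%
data = mf.StudyData.from_cohort(cohort, dm)

res = mf.test_variant(data, "DRB1*15:01")
fit = data.fit(["DRB1*15:01"])
path = forward_scan(data, list(data.groups), genes=["DRB1", "DQA1", "DQB1", "A", "B"])
```

Printing the cohort summary, the omnibus result (`res`, `fit`), the scan
records and a `variance_report` over the selected sets gives:

```
cohort: 5091 cases / 9599 controls, 67 markers
DRB1*15:01 omnibus: OR=2.35 (95% CI 2.19-2.53), p = 10^-118.6 (df=1)
step 0: DRB1*15  p = 10^-118.6  equivalent: ['DRB1*15:01']
step 1: A*02  p = 10^-31.3  equivalent: ['A*02:01']
stop: no-variant-and-no-gene-significant
Nagelkerke R2 [DRB1*15:01]: 5.1%
Nagelkerke R2 [both effects]: 6.4%
```

Reading the result: the scan recovers exactly the two planted effects (the
two-digit families `DRB1*15` and `A*02` contain a single four-digit allele
here, so they are perfect r²=1 proxies, flagged as equivalent). The
*univariate* OR of 2.35 is attenuated below the planted 2.92 because the
protective A\*02:01 allele travels on the same extended haplotype — a
deliberate LD confound. The joint model resolves it:

```python
joint = data.fit(["DRB1*15:01", "A*02:01"])
# OR(DRB1*15:01) = 2.95, OR(A*02:01) = 0.71

mf.compare_effects(data, "DRB1*15:01", "DQB1*06:02", conditioning=["A*02:01"])
# label = "A explains B":  p[15:01 | 06:02] = 10^-13.9,  p[06:02 | 15:01] = 0.06
```

so the class II signal is attributed to DRB1\*15:01 and not to its tightly
linked DQB1\*06:02 tag — the canonical fine-mapping adjudication.

The same pipeline is available from the shell:

```bash
mhcfinemap simulate --seed 42 --out sim/
mhcfinemap encode --calls sim/calls.tsv --maf 0.01 --out matrix.tsv
mhcfinemap scan --matrix matrix.tsv --pheno sim/phenotype.tsv \
    --genes DRB1,DQB1,A,B --out scan/
mhcfinemap crosscheck --matrix matrix.tsv --pheno sim/phenotype.tsv \
    --locus DRB1 --out crosscheck.tsv
mhcfinemap eqtl --matrix matrix.tsv --expr expr.tsv --tss tss.bed \
    --perms 10000 --seed 1 --out eqtl.tsv
```

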