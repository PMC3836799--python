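"""Synthetic MHC cohorts with known ground truth.

The generator emulates the statistical structure that the association
machinery assumes about post-imputation phased MHC data:

* subjects are two independent draws from a pool of multi-locus haplotypes,
  so linkage disequilibrium between classical alleles and SNPs is exactly
  the LD implied by the haplotype frequencies (e.g. a high-risk
  DRB1*15:01--DQB1*06:02-like haplotype);
* case-control status follows a logistic model with additive per-allele
  log-odds effects, a per-stratum baseline (eight GWAS-like strata), and
  optional principal-component covariates;
* expression traits are linear in SNP dosage plus Gaussian noise, feeding
  the cis-eQTL screen.

Everything is driven by a single integer seed and is byte-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calls import PhasedCallSet

__all__ = [
    "HaplotypePool",
    "StratumSpec",
    "SimulationConfig",
    "SimTruth",
    "SimulatedCohort",
    "GeneSpec",
    "build_haplotype_pool",
    "sample_cohort",
    "simulate_expression",
    "example_mhc_pool",
    "example_aa_dictionary",
    "random_snp_pool",
    "parse_marker_id",
    "write_phenotype_tsv",
    "write_truth_tsv",
    "write_snp_vcf",
]

_FREQ_TOL = 1e-12


# ----------------------------------------------------------------------
# Haplotype pool
# ----------------------------------------------------------------------
class HaplotypePool:
    """A finite pool of phased multi-locus haplotypes with frequencies.

    ``sites`` covers classical loci and SNPs alike; ``snps`` names the
    subset whose labels are nucleotide bases.  ``snp_meta`` optionally maps
    SNP ids to ``(chrom, pos)`` (1-based, hg18-style) for VCF output and
    the cis-eQTL window.
    """

    def __init__(
        self,
        sites: Sequence[str],
        labels: Mapping[str, Sequence[str]],
        codes: Mapping[str, np.ndarray],
        frequencies: Sequence[float],
        snps: Sequence[str] = (),
        snp_meta: Mapping[str, tuple] | None = None,
    ) -> None:
        self.sites = list(sites)
        self.snps = [s for s in self.sites if s in set(snps)]
        self.loci = [s for s in self.sites if s not in set(self.snps)]
        self.labels = {s: list(labels[s]) for s in self.sites}
        freqs = np.asarray(frequencies, dtype=float)
        if np.any(freqs < 0):
            raise ValueError("haplotype frequencies must be non-negative")
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies sum to {freqs.sum()}, not 1")
        # exact renormalisation within tolerance keeps np.random.choice happy
        self.frequencies = freqs / freqs.sum()
        h = len(self.frequencies)
        self.codes = {}
        for s in self.sites:
            arr = np.asarray(codes[s], dtype=np.int32)
            if arr.shape != (h,):
                raise ValueError(f"site {s!r}: expected one allele per haplotype")
            self.codes[s] = arr
        self.snp_meta = dict(snp_meta or {})

    @property
    def n_haplotypes(self) -> int:
        return len(self.frequencies)

    def marker_frequency(self, site: str, allele: str) -> float:
        """Population frequency of *allele* at *site* implied by the pool."""
        code = self.labels[site].index(allele)
        return float(self.frequencies[self.codes[site] == code].sum())

    def marker_ids(self) -> list:
        """All classical-allele and SNP-allele marker ids definable on the pool."""
        out = []
        for s in self.loci:
            out.extend(f"{s}*{a}" for a in self.labels[s])
        for s in self.snps:
            out.extend(f"{s}:{a}" for a in self.labels[s])
        return out

    def to_frame(self) -> pd.DataFrame:
        data = {"frequency": self.frequencies}
        for s in self.sites:
            labs = np.asarray(self.labels[s], dtype=object)
            data[s] = labs[self.codes[s]]
        return pd.DataFrame(data)


def build_haplotype_pool(
    spec: pd.DataFrame,
    snps: Sequence[str] | None = None,
    snp_meta: Mapping[str, tuple] | None = None,
) -> HaplotypePool:
    """Build a :class:`HaplotypePool` from a table.

    *spec* has one row per haplotype, a ``frequency`` column, and one
    column per site carrying the allele on that haplotype.  Columns whose
    name starts with ``rs`` are treated as SNPs unless *snps* is given.
    """
    if "frequency" not in spec.columns:
        raise ValueError("pool table needs a 'frequency' column")
    sites = [c for c in spec.columns if c != "frequency"]
    if not sites:
        raise ValueError("pool table defines no sites")
    if spec[sites].isna().any().any():
        raise ValueError("every haplotype must define an allele at every site")
    if snps is None:
        snps = [s for s in sites if s.startswith("rs")]
    labels, codes = {}, {}
    for s in sites:
        col = spec[s].astype(str)
        labs = list(pd.unique(col))
        lindex = {a: i for i, a in enumerate(labs)}
        labels[s] = labs
        codes[s] = col.map(lindex).to_numpy(dtype=np.int32)
    return HaplotypePool(
        sites, labels, codes, spec["frequency"].to_numpy(dtype=float), snps, snp_meta
    )


def parse_marker_id(pool: HaplotypePool, marker_id: str) -> tuple:
    """Resolve a marker id to ``(site, allele)`` on the pool.

    Classical alleles are written ``LOCUS*allele`` (e.g. ``DRB1*15:01``),
    SNP alleles ``rsid:base`` (e.g. ``rs2516489:T``).
    """
    if "*" in marker_id:
        site, allele = marker_id.split("*", 1)
        if site in pool.loci and allele in pool.labels[site]:
            return site, allele
    if ":" in marker_id:
        site, allele = marker_id.rsplit(":", 1)
        if site in pool.snps and allele in pool.labels[site]:
            return site, allele
    raise KeyError(f"marker {marker_id!r} not defined on this pool")


# ----------------------------------------------------------------------
# Simulation configuration
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class StratumSpec:
    """One GWAS-like stratum.

    Either give ``n_subjects`` (natural sampling: case/control split is
    whatever the logistic model produces) or exact ``n_cases`` and
    ``n_controls`` quotas (retrospective sampling by rejection).
    ``intercept`` is the stratum baseline on the log-odds scale.
    """

    name: str
    n_subjects: int | None = None
    intercept: float = 0.0
    n_cases: int | None = None
    n_controls: int | None = None

    def __post_init__(self):
        exact = self.n_cases is not None or self.n_controls is not None
        if exact and (self.n_cases is None or self.n_controls is None):
            raise ValueError(f"stratum {self.name!r}: give both n_cases and n_controls")
        if not exact and (self.n_subjects is None or self.n_subjects <= 0):
            raise ValueError(f"stratum {self.name!r}: n_subjects must be positive")
        if exact and (self.n_cases < 0 or self.n_controls < 0 or self.n_cases + self.n_controls == 0):
            raise ValueError(f"stratum {self.name!r}: invalid case/control quotas")

    @property
    def exact(self) -> bool:
        return self.n_cases is not None

    @property
    def total(self) -> int:
        return self.n_subjects if self.n_subjects is not None else self.n_cases + self.n_controls


@dataclass(frozen=True)
class SimulationConfig:
    """Planted truth for one synthetic cohort.

    ``effects`` maps marker ids (``DRB1*15:01``, ``rs123:A``) to additive
    per-allele-copy log-odds.  ``pc_effects`` are log-odds per unit of each
    standard-normal principal-component covariate.
    """

    strata: Sequence[StratumSpec]
    effects: Mapping[str, float] = field(default_factory=dict)
    n_pcs: int = 5
    pc_effects: Sequence[float] = ()
    seed: int = 0

    def __post_init__(self):
        if not self.strata:
            raise ValueError("at least one stratum is required")
        if len(self.pc_effects) > self.n_pcs:
            raise ValueError("more pc_effects than PCs")


@dataclass(frozen=True)
class SimTruth:
    """Planted effects and the haplotype structure they were drawn against."""

    effects: Mapping[str, float]
    pc_effects: tuple
    stratum_intercepts: Mapping[str, float]
    haplotype_frequencies: tuple

    def to_frame(self) -> pd.DataFrame:
        rows = [("marker", k, v) for k, v in self.effects.items()]
        rows += [("pc", f"PC{i + 1}", v) for i, v in enumerate(self.pc_effects)]
        rows += [("intercept", k, v) for k, v in self.stratum_intercepts.items()]
        return pd.DataFrame(rows, columns=["kind", "term", "log_odds"])


@dataclass
class SimulatedCohort:
    calls: PhasedCallSet
    phenotype: np.ndarray  # 0/1 per subject
    covariates: pd.DataFrame  # subject_id, status, stratum, PC1..PCk
    truth: SimTruth
    pool: HaplotypePool


# ----------------------------------------------------------------------
# Cohort sampling
# ----------------------------------------------------------------------
def _haplotype_scores(pool: HaplotypePool, effects: Mapping[str, float]) -> np.ndarray:
    """Per-haplotype sum of planted log-odds contributions."""
    score = np.zeros(pool.n_haplotypes)
    for marker_id, beta in effects.items():
        site, allele = parse_marker_id(pool, marker_id)
        code = pool.labels[site].index(allele)
        score[pool.codes[site] == code] += beta
    return score


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def sample_cohort(pool: HaplotypePool, config: SimulationConfig) -> SimulatedCohort:
    """Draw a phased case-control cohort under the planted logistic model.

    Each subject is two independent haplotype draws;
    ``P(case) = logistic(stratum intercept + sum(beta * dosage) + PC terms)``.
    Strata with exact quotas are filled by rejection sampling, which yields
    the retrospective (case-control) analogue of the same model.
    """
    rng = np.random.default_rng(config.seed)
    hscore = _haplotype_scores(pool, config.effects)
    pc_eff = np.zeros(config.n_pcs)
    pc_eff[: len(config.pc_effects)] = config.pc_effects

    idx_blocks, pc_blocks, y_blocks, labels = [], [], [], []
    for st in config.strata:
        if not st.exact:
            n = st.n_subjects
            idx = rng.choice(pool.n_haplotypes, size=(n, 2), p=pool.frequencies)
            pcs = rng.standard_normal((n, config.n_pcs))
            lp = st.intercept + hscore[idx].sum(axis=1) + pcs @ pc_eff
            y = (rng.random(n) < _sigmoid(lp)).astype(np.int8)
        else:
            need_case, need_ctrl = st.n_cases, st.n_controls
            got_i, got_p, got_y = [], [], []
            while need_case > 0 or need_ctrl > 0:
                batch = max(256, 2 * (need_case + need_ctrl))
                idx_b = rng.choice(pool.n_haplotypes, size=(batch, 2), p=pool.frequencies)
                pcs_b = rng.standard_normal((batch, config.n_pcs))
                lp = st.intercept + hscore[idx_b].sum(axis=1) + pcs_b @ pc_eff
                y_b = rng.random(batch) < _sigmoid(lp)
                for take_y, need in ((True, need_case), (False, need_ctrl)):
                    sel = np.nonzero(y_b == take_y)[0][:need]
                    got_i.append(idx_b[sel])
                    got_p.append(pcs_b[sel])
                    got_y.append(np.full(len(sel), int(take_y), dtype=np.int8))
                    if take_y:
                        need_case -= len(sel)
                    else:
                        need_ctrl -= len(sel)
            idx = np.concatenate(got_i)
            pcs = np.concatenate(got_p)
            y = np.concatenate(got_y)
            # shuffle within stratum so case/control order carries no signal
            perm = rng.permutation(len(y))
            idx, pcs, y = idx[perm], pcs[perm], y[perm]
        idx_blocks.append(idx)
        pc_blocks.append(pcs)
        y_blocks.append(y)
        labels.extend([st.name] * len(y))

    idx = np.concatenate(idx_blocks)
    pcs = np.concatenate(pc_blocks)
    y = np.concatenate(y_blocks).astype(np.int8)
    n = len(y)
    subjects = [f"S{i + 1:06d}" for i in range(n)]
    codes = {s: pool.codes[s][idx] for s in pool.sites}
    calls = PhasedCallSet(subjects, codes, pool.labels)

    cov = pd.DataFrame({"subject_id": subjects, "status": y.astype(int), "stratum": labels})
    for j in range(config.n_pcs):
        cov[f"PC{j + 1}"] = pcs[:, j]
    truth = SimTruth(
        effects=dict(config.effects),
        pc_effects=tuple(pc_eff),
        stratum_intercepts={st.name: st.intercept for st in config.strata},
        haplotype_frequencies=tuple(pool.frequencies),
    )
    return SimulatedCohort(calls, y, cov, truth, pool)


# ----------------------------------------------------------------------
# Expression simulation (cis-eQTL stage input)
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class GeneSpec:
    """One synthetic gene: a TSS and an optional SNP effect on expression."""

    gene: str
    chrom: str
    tss: int
    strand: str = "+"
    alpha: float = 0.0
    effect_snp: str | None = None  # marker id, e.g. "rs2516489:T"
    gamma: float = 0.0
    noise_sd: float = 1.0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError(f"gene {self.gene!r}: negative noise sd")
        if self.tss <= 0:
            raise ValueError(f"gene {self.gene!r}: TSS must be a positive coordinate")


def simulate_expression(
    cohort: SimulatedCohort, gene_specs: Sequence[GeneSpec], seed: int
):
    """Per-gene expression = alpha + gamma * dosage(effect SNP) + N(0, sd).

    Returns an :class:`~mhcfinemap.eqtl.ExpressionSet` aligned with the
    cohort's subjects.
    """
    from .eqtl import ExpressionSet  # local import avoids a cycle

    rng = np.random.default_rng(seed)
    n = cohort.calls.n_subjects
    values = np.empty((len(gene_specs), n))
    for i, g in enumerate(gene_specs):
        mu = np.full(n, g.alpha)
        if g.effect_snp is not None:
            site, allele = parse_marker_id(cohort.pool, g.effect_snp)
            mu = mu + g.gamma * cohort.calls.dosage(site, allele)
        values[i] = mu + rng.standard_normal(n) * g.noise_sd
    genes = pd.DataFrame(
        {
            "gene": [g.gene for g in gene_specs],
            "chrom": [g.chrom for g in gene_specs],
            "tss": [g.tss for g in gene_specs],
            "strand": [g.strand for g in gene_specs],
        }
    )
    return ExpressionSet(values=values, genes=genes, subjects=list(cohort.calls.subjects))


# ----------------------------------------------------------------------
# Example structures
# ----------------------------------------------------------------------
def example_mhc_pool() -> HaplotypePool:
    """A small MHC-like haplotype pool with realistic LD features.

    Allele frequencies follow European-ancestry orders of magnitude:
    DRB1*15:01 at 0.15 rides almost exclusively on a DQB1*06:02 haplotype
    (r^2 just below 1, as for the classical class II risk haplotype), six
    DRB1 alleles span common to rare (0.02-0.25), and a handful of class I
    alleles and SNPs give the stepwise scan a realistic candidate set.
    """
    rows = []

    def hap(freq, drb1, dqa1, dqb1, a, b, rs_a, rs_b, rs_c):
        rows.append(
            {
                "frequency": freq,
                "DRB1": drb1,
                "DQA1": dqa1,
                "DQB1": dqb1,
                "A": a,
                "B": b,
                "rs100": rs_a,
                "rs200": rs_b,
                "rs300": rs_c,
            }
        )

    # DRB1*15:01 haplotypes: tight LD with DQA1*01:02-DQB1*06:02
    hap(0.145, "15:01", "01:02", "06:02", "02:01", "07:02", "A", "G", "T")
    hap(0.005, "15:01", "01:02", "05:01", "03:01", "07:02", "A", "G", "T")
    # DRB1*03:01 - B*08:01-like extended haplotype
    hap(0.070, "03:01", "05:01", "02:01", "01:01", "08:01", "G", "G", "C")
    hap(0.030, "03:01", "05:01", "02:01", "24:02", "38:01", "G", "A", "C")
    # DR4 haplotypes
    hap(0.030, "04:04", "03:01", "03:02", "02:01", "44:02", "G", "A", "C")
    hap(0.080, "04:01", "03:01", "03:01", "01:01", "44:02", "A", "A", "C")
    # rarer class II
    hap(0.020, "13:03", "05:01", "03:01", "03:01", "07:02", "G", "G", "C")
    hap(0.020, "14:01", "01:02", "05:03", "24:02", "37:01", "G", "G", "C")
    # common background
    hap(0.250, "07:01", "02:01", "02:02", "02:01", "07:02", "G", "A", "C")
    hap(0.200, "01:01", "01:01", "05:01", "01:01", "08:01", "A", "G", "T")
    hap(0.150, "08:01", "04:01", "04:02", "03:01", "14:02", "G", "A", "C")
    pool = pd.DataFrame(rows)
    snp_meta = {
        "rs100": ("6", 31_431_006),  # class I flank
        "rs200": ("6", 31_540_000),  # MICB-LST1-like class III block
        "rs300": ("6", 32_742_280),  # class II flank
    }
    return build_haplotype_pool(pool, snp_meta=snp_meta)


def example_aa_dictionary():
    """Synthetic DRB1 amino-acid dictionary over the example pool's alleles.

    Positions mirror the kind of structure seen in the DR beta-1
    peptide-binding groove (71, 74, 57, 86, and leader position -5):
    position 71 carries four residues that partially partition the risk
    alleles; no single position separates 15:01 from every other allele,
    so a residual classical-allele signal can survive amino-acid
    conditioning.  This is a synthetic stand-in, not an IMGT extract.
    """
    from .encode import AminoAcidDictionary

    table = {
        #            -5     57     71     74     86
        "15:01": ("Leu", "Asp", "Ala", "Ala", "Val"),
        "03:01": ("Met", "Asp", "Lys", "Arg", "Val"),
        "04:04": ("Leu", "Asp", "Arg", "Ala", "Gly"),
        "04:01": ("Leu", "Asp", "Lys", "Ala", "Gly"),
        "13:03": ("Leu", "Asp", "Glu", "Glu", "Val"),
        "14:01": ("Leu", "Asp", "Arg", "Glu", "Val"),
        "07:01": ("Met", "Val", "Arg", "Gln", "Gly"),
        "01:01": ("Leu", "Asp", "Arg", "Ala", "Gly"),
        "08:01": ("Leu", "Ser", "Arg", "Leu", "Val"),
    }
    positions = (-5, 57, 71, 74, 86)
    mapping = {
        ("DRB1", allele): dict(zip(positions, residues)) for allele, residues in table.items()
    }
    return AminoAcidDictionary(mapping)


def random_snp_pool(
    n_snps: int, n_haplotypes: int = 400, seed: int = 0, freq_range=(0.1, 0.9)
) -> HaplotypePool:
    """A pool of biallelic SNP haplotypes with near-independent markers.

    With many equifrequent random haplotypes, pairwise LD between SNPs is
    negligible; useful for null-calibration studies.
    """
    rng = np.random.default_rng(seed)
    sites = [f"rs{i + 1}" for i in range(n_snps)]
    freqs = rng.uniform(*freq_range, size=n_snps)
    labels = {s: ["A", "G"] for s in sites}
    codes = {
        s: (rng.random(n_haplotypes) < freqs[i]).astype(np.int32) for i, s in enumerate(sites)
    }
    # guard against monomorphic draws
    for s in sites:
        if codes[s].min() == codes[s].max():
            codes[s][0] = 1 - codes[s][0]
    hap_freq = np.full(n_haplotypes, 1.0 / n_haplotypes)
    meta = {s: ("6", 29_300_000 + 20_000 * i) for i, s in enumerate(sites)}
    return HaplotypePool(sites, labels, codes, hap_freq, snps=sites, snp_meta=meta)


# ----------------------------------------------------------------------
# Writers
# ----------------------------------------------------------------------
def write_phenotype_tsv(cohort: SimulatedCohort, path) -> None:
    cohort.covariates.to_csv(path, sep="\t", index=False)


def write_truth_tsv(cohort: SimulatedCohort, path) -> None:
    cohort.truth.to_frame().to_csv(path, sep="\t", index=False)


def write_snp_vcf(cohort: SimulatedCohort, path) -> None:
    """Write SNP calls as a minimal phased VCF (one ALT per record, hg18-like)."""
    pool = cohort.pool
    calls = cohort.calls
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=6>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(calls.subjects)
            + "\n"
        )
        for s in pool.snps:
            chrom, pos = pool.snp_meta.get(s, ("6", 0))
            labs = calls.labels[s]
            if len(labs) < 2:
                continue
            ref, alts = labs[0], labs[1:]
            for ai, alt in enumerate(alts, start=1):
                gt = (calls.codes[s] == ai).astype(int)
                cols = [f"{a}|{b}" for a, b in gt]
                fh.write(
                    f"{chrom}\t{pos}\t{s}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(cols) + "\n"
                )


def table1_strata() -> list:
    """The eight GWAS strata of the study design, with exact case/control sizes."""
    sizes = [
        ("GeneMSA_DU", 219, 225),
        ("GeneMSA_US", 437, 402),
        ("GeneMSA_SW", 239, 190),
        ("IMSGC", 790, 1677),
        ("BWH", 821, 2705),
        ("ANZgene", 1582, 1949),
        ("Rotterdam", 459, 1938),
        ("KaiserPermanente", 544, 513),
    ]
    return [StratumSpec(name=n, n_cases=ca, n_controls=co) for n, ca, co in sizes]
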