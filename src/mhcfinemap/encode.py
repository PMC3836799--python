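"""Encode phased MHC calls into analysis-ready presence/absence dosages.

Every variant — SNP allele, two- or four-digit classical HLA allele,
amino-acid residue, diplotype — becomes one biallelic marker whose dosage
counts the haplotypes carrying it (0/1/2 for hard calls, expected counts
when per-call posteriors are present).  Markers belonging to the same
underlying multi-allelic variant share a ``group`` key, which is what the
omnibus tests operate on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .calls import PhasedCallSet

__all__ = [
    "VariantDef",
    "AminoAcidDictionary",
    "DosageMatrix",
    "binarize_classical",
    "encode_snps",
    "rollup_two_digit",
    "translate_to_amino_acids",
    "build_diplotype",
    "maf_filter",
    "info_score",
    "read_snp_vcf",
    "write_dosage_tsv",
    "read_dosage_tsv",
]

KINDS = ("SNP", "HLA2d", "HLA4d", "AA", "DIPLOTYPE")


@dataclass(frozen=True)
class VariantDef:
    """Metadata for one biallelic presence/absence marker."""

    id: str
    kind: str  # one of KINDS
    locus: str  # gene name, or "chrom:pos" for SNPs
    allele: str  # allele label / residue symbol / base
    group: str  # omnibus grouping key (locus, snp id, or gene:position)
    position: int | None = None  # amino-acid position; may be negative (leader)
    chrom: str | None = None
    pos: int | None = None  # 1-based coordinate for SNPs

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown variant kind {self.kind!r}")


class AminoAcidDictionary:
    """Map (gene, four-digit allele) -> {position: residue}.

    The dictionary file is the single source of truth for the
    allele-to-residue correspondence; positions follow mature-protein
    numbering and may be negative for the leader peptide.
    """

    def __init__(self, mapping: Mapping[tuple, Mapping[int, str]]):
        self._map = {k: dict(v) for k, v in mapping.items()}

    def genes(self) -> list:
        return sorted({g for g, _ in self._map})

    def positions(self, gene: str) -> list:
        pos: set = set()
        for (g, _), table in self._map.items():
            if g == gene:
                pos.update(table)
        return sorted(pos)

    def residue(self, gene: str, allele: str, position: int) -> str:
        return self._map[(gene, allele)][position]

    def has_allele(self, gene: str, allele: str) -> bool:
        return (gene, allele) in self._map

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AminoAcidDictionary":
        required = {"gene", "allele", "position", "residue"}
        if not required <= set(frame.columns):
            raise ValueError(f"dictionary table needs columns {sorted(required)}")
        mapping: dict = {}
        for row in frame.itertuples(index=False):
            mapping.setdefault((row.gene, str(row.allele)), {})[int(row.position)] = str(
                row.residue
            )
        return cls(mapping)

    @classmethod
    def read_tsv(cls, path) -> "AminoAcidDictionary":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype={"allele": str}))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (g, a, p, r)
            for (g, a), table in sorted(self._map.items())
            for p, r in sorted(table.items())
        ]
        return pd.DataFrame(rows, columns=["gene", "allele", "position", "residue"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


class DosageMatrix:
    """Subjects x markers dosage matrix with per-marker metadata.

    ``values`` is ``(n_subjects, n_markers)`` float; dosages lie in
    ``[0, 2]`` and are integral for hard calls.  Frequencies are allele
    frequencies (mean dosage / 2) over all subjects.
    """

    def __init__(self, subjects: Sequence[str], values: np.ndarray, variants: Sequence[VariantDef]):
        self.subjects = list(subjects)
        values = np.asarray(values, dtype=float)
        if values.shape != (len(self.subjects), len(variants)):
            raise ValueError("dosage matrix shape does not match subjects x variants")
        if values.size and (values.min() < -1e-9 or values.max() > 2 + 1e-9):
            raise ValueError("dosages must lie in [0, 2]")
        self.values = values
        self.variants = list(variants)
        ids = [v.id for v in self.variants]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate variant ids: {dup[:5]}")
        self._index = {v.id: j for j, v in enumerate(self.variants)}

    # -- basic access ---------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def ids(self) -> list:
        return [v.id for v in self.variants]

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def column(self, variant_id: str) -> np.ndarray:
        return self.values[:, self._index[variant_id]]

    def columns(self, variant_ids: Iterable[str]) -> np.ndarray:
        idx = [self._index[i] for i in variant_ids]
        return self.values[:, idx]

    def variant(self, variant_id: str) -> VariantDef:
        return self.variants[self._index[variant_id]]

    def frequencies(self) -> np.ndarray:
        return self.values.mean(axis=0) / 2.0

    def frequency(self, variant_id: str) -> float:
        return float(self.column(variant_id).mean() / 2.0)

    # -- grouping -------------------------------------------------------
    def groups(self, kinds: Sequence[str] | None = None) -> dict:
        """Ordered map group key -> list of member variant ids."""
        out: dict = {}
        for v in self.variants:
            if kinds is not None and v.kind not in kinds:
                continue
            out.setdefault(v.group, []).append(v.id)
        return out

    def group_members(self, group: str) -> list:
        ids = [v.id for v in self.variants if v.group == group]
        if not ids:
            raise KeyError(f"no markers in group {group!r}")
        return ids

    def locus_members(self, locus: str, kind: str = "HLA4d") -> list:
        return [v.id for v in self.variants if v.kind == kind and v.locus == locus]

    # -- combination ----------------------------------------------------
    def select(self, variant_ids: Sequence[str]) -> "DosageMatrix":
        idx = [self._index[i] for i in variant_ids]
        return DosageMatrix(
            self.subjects, self.values[:, idx], [self.variants[j] for j in idx]
        )

    @staticmethod
    def concat(parts: Sequence["DosageMatrix"]) -> "DosageMatrix":
        if not parts:
            raise ValueError("nothing to concatenate")
        subjects = parts[0].subjects
        for p in parts[1:]:
            if p.subjects != subjects:
                raise ValueError("subject sets differ between matrices")
        values = np.hstack([p.values for p in parts])
        variants = [v for p in parts for v in p.variants]
        return DosageMatrix(subjects, values, variants)

    # -- I/O -------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        meta = pd.DataFrame(
            {
                "id": self.ids,
                "kind": [v.kind for v in self.variants],
                "locus": [v.locus for v in self.variants],
                "allele": [v.allele for v in self.variants],
                "group": [v.group for v in self.variants],
                "chrom": [v.chrom for v in self.variants],
                "pos": [v.pos for v in self.variants],
                "frequency": self.frequencies(),
                "info": [info_score(self.column(v.id)) for v in self.variants],
            }
        )
        dos = pd.DataFrame(self.values.T, columns=self.subjects)
        return pd.concat([meta, dos], axis=1)


def write_dosage_tsv(dm: DosageMatrix, path) -> None:
    dm.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_dosage_tsv(path) -> DosageMatrix:
    frame = pd.read_csv(path, sep="\t", dtype={"allele": str})
    meta_cols = ["id", "kind", "locus", "allele", "group", "chrom", "pos", "frequency", "info"]
    subjects = [c for c in frame.columns if c not in meta_cols]
    variants = [
        VariantDef(
            id=r.id,
            kind=r.kind,
            locus=str(r.locus),
            allele=str(r.allele),
            group=str(r.group),
            chrom=None if pd.isna(r.chrom) else str(r.chrom),
            pos=None if pd.isna(r.pos) else int(r.pos),
        )
        for r in frame.itertuples(index=False)
    ]
    values = frame[subjects].to_numpy(dtype=float).T
    return DosageMatrix(subjects, values, variants)


# ----------------------------------------------------------------------
# Encoders
# ----------------------------------------------------------------------
def binarize_classical(calls: PhasedCallSet, locus: str) -> DosageMatrix:
    """One presence/absence marker per observed four-digit allele at *locus*.

    Dosage is the number of haplotypes carrying the allele (expected count
    under per-call posteriors).  Markers share the locus as group key only
    at the gene level; each classical allele is itself a biallelic variant,
    so its group is its own id.
    """
    if locus not in calls.codes:
        raise KeyError(f"locus {locus!r} not present in calls")
    alleles = calls.observed_alleles(locus)
    cols, variants = [], []
    for allele in alleles:
        cols.append(calls.dosage(locus, allele))
        vid = f"{locus}*{allele}"
        variants.append(
            VariantDef(id=vid, kind="HLA4d", locus=locus, allele=allele, group=vid)
        )
    return DosageMatrix(calls.subjects, np.column_stack(cols), variants)


def encode_snps(
    calls: PhasedCallSet,
    snps: Sequence[str],
    positions: Mapping[str, tuple] | None = None,
) -> DosageMatrix:
    """Presence/absence markers for SNP alleles (multi-allelic SNPs expand).

    For a biallelic SNP this yields two complementary columns in one
    group; the omnibus test uses one of them (the non-reference allele).
    """
    positions = positions or {}
    cols, variants = [], []
    for snp in snps:
        if snp not in calls.codes:
            raise KeyError(f"SNP {snp!r} not present in calls")
        chrom, pos = positions.get(snp, (None, None))
        for allele in calls.observed_alleles(snp):
            cols.append(calls.dosage(snp, allele))
            variants.append(
                VariantDef(
                    id=f"{snp}:{allele}",
                    kind="SNP",
                    locus=f"{chrom}:{pos}" if chrom is not None else snp,
                    allele=allele,
                    group=snp,
                    chrom=chrom,
                    pos=pos,
                )
            )
    if not cols:
        raise ValueError("no SNPs to encode")
    return DosageMatrix(calls.subjects, np.column_stack(cols), variants)


def _split_four_digit(allele: str) -> tuple:
    parts = allele.split(":")
    if len(parts) < 2 or not parts[0]:
        raise ValueError(f"allele label {allele!r} is not four-digit (family:protein)")
    return parts[0], parts[1]


def rollup_two_digit(dm: DosageMatrix, locus: str | None = None) -> DosageMatrix:
    """Two-digit (allele family) markers as sums of their four-digit members."""
    members: dict = {}
    for v in dm.variants:
        if v.kind != "HLA4d":
            continue
        if locus is not None and v.locus != locus:
            continue
        family, _ = _split_four_digit(v.allele)
        members.setdefault((v.locus, family), []).append(v.id)
    if not members:
        raise ValueError("no four-digit classical markers to roll up")
    cols, variants = [], []
    for (loc, family), ids in members.items():
        col = dm.columns(ids).sum(axis=1)
        if col.max() > 2 + 1e-9:
            raise ValueError(f"{loc}*{family}: two-digit dosage exceeds 2")
        vid = f"{loc}*{family}"
        cols.append(col)
        variants.append(VariantDef(id=vid, kind="HLA2d", locus=loc, allele=family, group=vid))
    return DosageMatrix(dm.subjects, np.column_stack(cols), variants)


def translate_to_amino_acids(
    dm: DosageMatrix,
    dictionary: AminoAcidDictionary,
    gene: str,
    drop_monomorphic: bool = True,
) -> tuple:
    """Residue dosages per amino-acid position of *gene*.

    Residue dosage at a position is the sum of the dosages of the
    four-digit alleles carrying that residue — a fixed 0/1 linear map of
    the classical-allele dosages.  Returns ``(matrix, excluded)`` where
    *excluded* lists monomorphic positions left out of the matrix.

    Raises ``KeyError`` listing every allele absent from the dictionary.
    """
    allele_ids = dm.locus_members(gene, kind="HLA4d")
    if not allele_ids:
        raise ValueError(f"no four-digit markers for gene {gene!r}")
    alleles = [dm.variant(i).allele for i in allele_ids]
    missing = [a for a in alleles if not dictionary.has_allele(gene, a)]
    if missing:
        raise KeyError(f"alleles missing from amino-acid dictionary for {gene}: {sorted(missing)}")
    cols, variants, excluded = [], [], []
    for position in dictionary.positions(gene):
        residues: dict = {}
        for aid, allele in zip(allele_ids, alleles):
            residues.setdefault(dictionary.residue(gene, allele, position), []).append(aid)
        if drop_monomorphic and len(residues) < 2:
            excluded.append(position)
            continue
        group = f"{gene}:{position}"
        for res, ids in sorted(residues.items()):
            cols.append(dm.columns(ids).sum(axis=1))
            variants.append(
                VariantDef(
                    id=f"{gene}_pos{position}_{res}",
                    kind="AA",
                    locus=gene,
                    allele=res,
                    group=group,
                    position=position,
                )
            )
    if not cols:
        raise ValueError(f"gene {gene!r}: every amino-acid position is monomorphic")
    return DosageMatrix(dm.subjects, np.column_stack(cols), variants), excluded


def build_diplotype(
    calls: PhasedCallSet, pair_a: tuple, pair_b: tuple
) -> DosageMatrix:
    """Dosage of the cis two-locus haplotype (alleleA at locusA and
    alleleB at locusB on the same haplotype)."""
    (locus_a, allele_a), (locus_b, allele_b) = pair_a, pair_b
    col = calls.diplotype_dosage(locus_a, allele_a, locus_b, allele_b)
    label = f"{locus_a}*{allele_a}-{locus_b}*{allele_b}"
    v = VariantDef(
        id=label, kind="DIPLOTYPE", locus=f"{locus_a}-{locus_b}", allele=label, group=label
    )
    return DosageMatrix(calls.subjects, col[:, None], [v])


# ----------------------------------------------------------------------
# Filters and quality metrics
# ----------------------------------------------------------------------
def maf_filter(
    dm: DosageMatrix,
    threshold: float = 0.01,
    strata: Sequence | None = None,
    per_stratum: bool = False,
) -> tuple:
    """Drop markers with minor allele frequency strictly below *threshold*.

    The boundary is read strictly: a marker at exactly the threshold is
    retained.  By default frequencies are pooled over all subjects; with
    ``per_stratum=True`` a marker is dropped if its MAF falls below the
    threshold in any stratum.  Returns ``(filtered, log)`` where *log*
    records the removed markers and their frequencies.
    """
    freqs = dm.frequencies()
    maf = np.minimum(freqs, 1.0 - freqs)
    if per_stratum:
        if strata is None:
            raise ValueError("per_stratum filtering needs stratum labels")
        strata = np.asarray(strata)
        for s in np.unique(strata):
            f = dm.values[strata == s].mean(axis=0) / 2.0
            maf = np.minimum(maf, np.minimum(f, 1.0 - f))
    keep = maf >= threshold
    log = pd.DataFrame(
        {
            "id": [v.id for v, k in zip(dm.variants, keep) if not k],
            "frequency": freqs[~keep],
            "maf": maf[~keep],
        }
    )
    kept_ids = [v.id for v, k in zip(dm.variants, keep) if k]
    return dm.select(kept_ids), log


def info_score(dosage: np.ndarray, frequency: float | None = None) -> float:
    """Imputation quality: observed dosage variance over expected 2f(1-f).

    Hard calls at Hardy-Weinberg equilibrium give values near 1; expected
    dosages shrunk towards 2f give values below 1.  Monomorphic columns
    (f of 0 or 1) raise ``ValueError``.
    """
    dosage = np.asarray(dosage, dtype=float)
    f = float(dosage.mean() / 2.0) if frequency is None else float(frequency)
    if not 0.0 < f < 1.0:
        raise ValueError("INFO score undefined for monomorphic marker")
    expected = 2.0 * f * (1.0 - f)
    return float(dosage.var() / expected)


# ----------------------------------------------------------------------
# VCF input (SNP path)
# ----------------------------------------------------------------------
def read_snp_vcf(path) -> tuple:
    """Read phased SNP genotypes from a VCF into call-set structures.

    Returns ``(calls, positions)`` where *positions* maps SNP id to
    ``(chrom, pos)`` with 1-based coordinates.  Multi-allelic records are
    supported; genotypes must be phased and complete.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    n = len(subjects)
    codes: dict = {}
    labels: dict = {}
    positions: dict = {}
    for rec in vcf:
        snp = rec.ID or f"{rec.CHROM}:{rec.POS}"
        labs = [rec.REF] + list(rec.ALT)
        geno = np.asarray([g[:2] for g in rec.genotypes], dtype=np.int32)
        if geno.shape != (n, 2) or geno.min() < 0:
            raise ValueError(f"{snp}: genotypes must be complete diploid calls")
        if snp in codes:
            # later record for the same multi-allelic site: merge alleles
            prev_labs = labels[snp]
            remap = {}
            for i, lab in enumerate(labs):
                if lab not in prev_labs:
                    prev_labs.append(lab)
                remap[i] = prev_labs.index(lab)
            merged = np.vectorize(remap.get)(geno)
            codes[snp] = np.where(merged > 0, merged, codes[snp])
        else:
            codes[snp] = geno
            labels[snp] = labs
            positions[snp] = (rec.CHROM, rec.POS)
    calls = PhasedCallSet(subjects, codes, labels)
    return calls, positions
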