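"""Phased per-subject allele calls at classical HLA loci and MHC SNPs.

A :class:`PhasedCallSet` holds, for every subject, two haplotypes worth of
allele labels at a set of named sites.  Sites are either classical HLA loci
(allele labels like ``"15:01"``) or SNPs (labels are bases).  Labels are
stored as small integer codes against a per-site label list so that large
simulated cohorts stay cheap to manipulate; labels are materialised only at
the I/O boundary.

An optional per-call posterior (in ``(0, 1]``) models imputation
uncertainty: encoders downstream then produce expected rather than
hard-call dosages.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = ["PhasedCallSet", "read_calls_tsv", "write_calls_tsv"]


class PhasedCallSet:
    """Two phased haplotypes per subject across named sites.

    Parameters
    ----------
    subjects
        Subject identifiers, one per row.
    codes
        Mapping site -> int array of shape ``(n_subjects, 2)`` indexing
        into ``labels[site]``.
    labels
        Mapping site -> list of allele labels for that site.
    posteriors
        Optional mapping site -> float array ``(n_subjects, 2)`` of
        per-call posterior probabilities.  Absent means certain calls.
    """

    def __init__(
        self,
        subjects: Iterable[str],
        codes: Mapping[str, np.ndarray],
        labels: Mapping[str, list],
        posteriors: Mapping[str, np.ndarray] | None = None,
    ) -> None:
        self.subjects = list(subjects)
        n = len(self.subjects)
        self.codes = {}
        self.labels = {}
        for site, arr in codes.items():
            arr = np.asarray(arr, dtype=np.int32)
            if arr.shape != (n, 2):
                raise ValueError(
                    f"site {site!r}: codes have shape {arr.shape}, expected {(n, 2)}"
                )
            labs = list(labels[site])
            if arr.size and (arr.min() < 0 or arr.max() >= len(labs)):
                raise ValueError(f"site {site!r}: allele code out of range")
            self.codes[site] = arr
            self.labels[site] = labs
        self.posteriors = None
        if posteriors is not None:
            self.posteriors = {}
            for site, post in posteriors.items():
                post = np.asarray(post, dtype=float)
                if post.shape != (n, 2):
                    raise ValueError(f"site {site!r}: posterior shape mismatch")
                if np.any(post <= 0) or np.any(post > 1):
                    raise ValueError(f"site {site!r}: posteriors must be in (0, 1]")
                self.posteriors[site] = post

    # ------------------------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def sites(self) -> list:
        return list(self.codes)

    def allele_labels(self, site: str) -> list:
        return list(self.labels[site])

    def observed_alleles(self, site: str) -> list:
        """Labels actually carried by at least one haplotype, in label order."""
        seen = np.unique(self.codes[site])
        return [self.labels[site][c] for c in seen]

    def haplotype_alleles(self, site: str) -> np.ndarray:
        """``(n, 2)`` object array of allele labels at *site*."""
        labs = np.asarray(self.labels[site], dtype=object)
        return labs[self.codes[site]]

    def dosage(self, site: str, allele: str) -> np.ndarray:
        """Per-subject count (or expected count) of haplotypes carrying *allele*."""
        try:
            code = self.labels[site].index(allele)
        except ValueError:
            raise KeyError(f"allele {allele!r} not defined at site {site!r}") from None
        carrier = self.codes[site] == code
        if self.posteriors is not None and site in self.posteriors:
            return (carrier * self.posteriors[site]).sum(axis=1)
        return carrier.sum(axis=1).astype(float)

    def diplotype_dosage(self, site_a: str, allele_a: str, site_b: str, allele_b: str) -> np.ndarray:
        """Count of haplotypes carrying both alleles in cis."""
        ca = self.labels[site_a].index(allele_a)
        cb = self.labels[site_b].index(allele_b)
        both = (self.codes[site_a] == ca) & (self.codes[site_b] == cb)
        return both.sum(axis=1).astype(float)

    # ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Long table: subject_id, hap_index (1/2), locus, allele[, posterior]."""
        rows = []
        subj = np.asarray(self.subjects, dtype=object)
        for site in self.codes:
            labs = np.asarray(self.labels[site], dtype=object)
            for hap in (0, 1):
                block = pd.DataFrame(
                    {
                        "subject_id": subj,
                        "hap_index": hap + 1,
                        "locus": site,
                        "allele": labs[self.codes[site][:, hap]],
                    }
                )
                if self.posteriors is not None and site in self.posteriors:
                    block["posterior"] = self.posteriors[site][:, hap]
                rows.append(block)
        out = pd.concat(rows, ignore_index=True)
        return out.sort_values(["subject_id", "locus", "hap_index"], kind="stable").reset_index(
            drop=True
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PhasedCallSet":
        required = {"subject_id", "hap_index", "locus", "allele"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"phased-call table missing columns: {sorted(missing)}")
        subjects = list(pd.unique(frame["subject_id"]))
        sindex = {s: i for i, s in enumerate(subjects)}
        n = len(subjects)
        codes: dict = {}
        labels: dict = {}
        posts: dict = {}
        has_post = "posterior" in frame.columns
        for site, grp in frame.groupby("locus", sort=False):
            labs = list(pd.unique(grp["allele"]))
            lindex = {a: i for i, a in enumerate(labs)}
            arr = np.full((n, 2), -1, dtype=np.int32)
            post = np.ones((n, 2))
            rows = grp["subject_id"].map(sindex).to_numpy()
            haps = grp["hap_index"].to_numpy(dtype=int) - 1
            if np.any((haps < 0) | (haps > 1)):
                raise ValueError("hap_index must be 1 or 2")
            arr[rows, haps] = grp["allele"].map(lindex).to_numpy()
            if has_post:
                post[rows, haps] = grp["posterior"].to_numpy(dtype=float)
            if np.any(arr < 0):
                bad = [subjects[i] for i in np.nonzero((arr < 0).any(axis=1))[0][:5]]
                raise ValueError(f"site {site!r}: missing haplotype call for subjects {bad}")
            codes[site] = arr
            labels[site] = labs
            if has_post:
                posts[site] = post
        return cls(subjects, codes, labels, posts if has_post else None)


def write_calls_tsv(calls: PhasedCallSet, path) -> None:
    calls.to_frame().to_csv(path, sep="\t", index=False)


def read_calls_tsv(path) -> PhasedCallSet:
    return PhasedCallSet.from_frame(pd.read_csv(path, sep="\t", dtype={"allele": str}))
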