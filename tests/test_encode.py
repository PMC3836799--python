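"""Variant encoding: presence/absence dosages, roll-ups, residues, filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mhcfinemap as mf
from mhcfinemap.calls import PhasedCallSet
from mhcfinemap.encode import AminoAcidDictionary, VariantDef, info_score


def _calls(rows):
    return PhasedCallSet.from_frame(
        pd.DataFrame(rows, columns=["subject_id", "hap_index", "locus", "allele"])
    )


class TestBinarize:
    def test_heterozygote_and_homozygote(self):
        calls = _calls(
            [
                ("S1", 1, "DRB1", "15:01"), ("S1", 2, "DRB1", "03:01"),
                ("S2", 1, "DRB1", "15:01"), ("S2", 2, "DRB1", "15:01"),
            ]
        )
        dm = mf.binarize_classical(calls, "DRB1")
        assert list(dm.column("DRB1*15:01")) == [1, 2]
        assert list(dm.column("DRB1*03:01")) == [1, 0]

    def test_frequency_tracks_pool(self, example_pool):
        cfg = mf.SimulationConfig(
            strata=[mf.StratumSpec(name="all", n_subjects=100)], n_pcs=0, seed=21
        )
        cohort = mf.sample_cohort(example_pool, cfg)
        dm = mf.binarize_classical(cohort.calls, "DRB1")
        f = dm.frequency("DRB1*15:01")
        sd = np.sqrt(0.15 * 0.85 / 200)
        assert abs(f - 0.15) < 3 * sd

    def test_unknown_locus(self):
        calls = _calls([("S1", 1, "DRB1", "15:01"), ("S1", 2, "DRB1", "03:01")])
        with pytest.raises(KeyError):
            mf.binarize_classical(calls, "DPB1")

    def test_group_sum_is_two_per_locus(self, risk_data):
        for locus in ("DRB1", "DQB1", "A", "B"):
            members = risk_data.dm.locus_members(locus)
            total = risk_data.dm.columns(members).sum(axis=1)
            np.testing.assert_allclose(total, 2.0)


class TestTwoDigit:
    def test_singleton_family_equals_member(self):
        calls = _calls(
            [
                ("S1", 1, "B", "37:01"), ("S1", 2, "B", "08:01"),
                ("S2", 1, "B", "08:01"), ("S2", 2, "B", "08:01"),
            ]
        )
        dm = mf.binarize_classical(calls, "B")
        two = mf.rollup_two_digit(dm)
        np.testing.assert_array_equal(two.column("B*37"), dm.column("B*37:01"))

    def test_family_sum_within_subject(self):
        calls = _calls(
            [
                ("S1", 1, "DRB1", "04:01"), ("S1", 2, "DRB1", "04:04"),
                ("S2", 1, "DRB1", "15:01"), ("S2", 2, "DRB1", "15:01"),
            ]
        )
        two = mf.rollup_two_digit(mf.binarize_classical(calls, "DRB1"))
        assert list(two.column("DRB1*04")) == [2, 0]

    def test_two_digit_equals_sum_of_members(self, risk_data):
        dm = risk_data.dm
        two_digit = [v for v in dm.variants if v.kind == "HLA2d"]
        assert two_digit
        for v in two_digit:
            members = [
                w.id for w in dm.variants
                if w.kind == "HLA4d" and w.locus == v.locus and w.allele.startswith(v.allele + ":")
            ]
            np.testing.assert_allclose(
                dm.column(v.id), dm.columns(members).sum(axis=1), atol=1e-12
            )

    def test_absent_family_removed_by_maf_filter(self):
        calls = _calls(
            [("S%d" % i, h, "DRB1", "15:01") for i in range(1, 60) for h in (1, 2)]
            + [("S60", 1, "DRB1", "13:01"), ("S60", 2, "DRB1", "15:01")]
        )
        dm = mf.rollup_two_digit(mf.binarize_classical(calls, "DRB1"))
        filtered, log = mf.maf_filter(dm, threshold=0.01)
        assert "DRB1*13" not in filtered.ids and "DRB1*13" in list(log["id"])

    def test_malformed_label(self):
        dm = mf.DosageMatrix(
            ["S1"], np.array([[1.0]]),
            [VariantDef(id="DRB1*x", kind="HLA4d", locus="DRB1", allele="fifteen", group="DRB1*x")],
        )
        with pytest.raises(ValueError, match="four-digit"):
            mf.rollup_two_digit(dm)


class TestAminoAcids:
    def test_residue_dosage_follows_mapping(self):
        calls = _calls([("S1", 1, "DRB1", "15:01"), ("S1", 2, "DRB1", "03:01")])
        d = AminoAcidDictionary(
            {("DRB1", "15:01"): {71: "Ala"}, ("DRB1", "03:01"): {71: "Lys"}}
        )
        aa, _ = mf.translate_to_amino_acids(mf.binarize_classical(calls, "DRB1"), d, "DRB1")
        assert list(aa.column("DRB1_pos71_Ala")) == [1]
        assert list(aa.column("DRB1_pos71_Lys")) == [1]

    def test_monomorphic_position_excluded(self, aa_dict, risk_data):
        # every allele shares Asp at 57 except 07:01/08:01; build a truly
        # monomorphic dictionary to check the exclusion path
        calls = _calls(
            [("S1", 1, "DRB1", "15:01"), ("S1", 2, "DRB1", "03:01")]
        )
        d = AminoAcidDictionary(
            {("DRB1", "15:01"): {9: "Trp", 71: "Ala"}, ("DRB1", "03:01"): {9: "Trp", 71: "Lys"}}
        )
        aa, excluded = mf.translate_to_amino_acids(
            mf.binarize_classical(calls, "DRB1"), d, "DRB1"
        )
        assert excluded == [9]
        assert {v.position for v in aa.variants} == {71}

    def test_four_residue_position_yields_four_columns(self, aa_dict, risk_data):
        aa, _ = mf.translate_to_amino_acids(
            risk_data.dm.select(risk_data.dm.locus_members("DRB1")), aa_dict, "DRB1"
        )
        pos71 = [v for v in aa.variants if v.position == 71]
        assert len(pos71) == 4  # Ala, Arg, Glu, Lys
        assert sorted(v.allele for v in pos71) == ["Ala", "Arg", "Glu", "Lys"]

    def test_position_group_sums_to_two(self, aa_dict, risk_data):
        aa, _ = mf.translate_to_amino_acids(
            risk_data.dm.select(risk_data.dm.locus_members("DRB1")), aa_dict, "DRB1"
        )
        for group, members in aa.groups().items():
            np.testing.assert_allclose(aa.columns(members).sum(axis=1), 2.0)

    def test_translation_is_linear_in_classical_dosages(self, aa_dict, risk_data):
        four = risk_data.dm.select(risk_data.dm.locus_members("DRB1"))
        aa, _ = mf.translate_to_amino_acids(four, aa_dict, "DRB1")
        # indicator matrix: residue x allele
        A = np.array(
            [
                [
                    1.0 if aa_dict.residue("DRB1", w.allele, v.position) == v.allele else 0.0
                    for w in four.variants
                ]
                for v in aa.variants
            ]
        )
        np.testing.assert_allclose(aa.values, four.values @ A.T, atol=1e-12)

    def test_missing_allele_reported(self):
        calls = _calls([("S1", 1, "DRB1", "15:01"), ("S1", 2, "DRB1", "09:01")])
        d = AminoAcidDictionary({("DRB1", "15:01"): {71: "Ala"}})
        with pytest.raises(KeyError, match="09:01"):
            mf.translate_to_amino_acids(mf.binarize_classical(calls, "DRB1"), d, "DRB1")


class TestDiplotype:
    def test_cis_counting_and_trans_exclusion(self):
        calls = _calls(
            [
                ("S1", 1, "DRB1", "15:01"), ("S1", 2, "DRB1", "03:01"),
                ("S1", 1, "DQB1", "06:02"), ("S1", 2, "DQB1", "02:01"),
                ("S2", 1, "DRB1", "15:01"), ("S2", 2, "DRB1", "03:01"),
                ("S2", 1, "DQB1", "02:01"), ("S2", 2, "DQB1", "06:02"),
            ]
        )
        dip = mf.build_diplotype(calls, ("DRB1", "15:01"), ("DQB1", "06:02"))
        assert list(dip.values[:, 0]) == [1, 0]

    def test_perfect_ld_diplotype_equals_allele_column(self, two_hap_pool):
        cfg = mf.SimulationConfig(
            strata=[mf.StratumSpec(name="all", n_subjects=400)], n_pcs=0, seed=22
        )
        cohort = mf.sample_cohort(two_hap_pool, cfg)
        dip = mf.build_diplotype(cohort.calls, ("DRB1", "15:01"), ("DQB1", "06:02"))
        allele = mf.binarize_classical(cohort.calls, "DRB1").column("DRB1*15:01")
        np.testing.assert_array_equal(dip.values[:, 0], allele)


class TestMafFilter:
    def _matrix(self, freqs, n=1000):
        rng = np.random.default_rng(33)
        cols = [rng.binomial(2, f, size=n).astype(float) for f in freqs]
        variants = [
            VariantDef(id=f"v{i}", kind="SNP", locus="6", allele="A", group=f"v{i}")
            for i in range(len(freqs))
        ]
        return mf.DosageMatrix([f"S{i}" for i in range(n)], np.column_stack(cols), variants)

    def test_boundary_strictly_less_than(self):
        n = 1000
        values = np.zeros((n, 2))
        values[:10, 0] = 1.0  # f = 0.005 -> removed
        values[:20, 1] = 1.0  # f = 0.010 -> retained (strict less-than)
        dm = mf.DosageMatrix(
            [f"S{i}" for i in range(n)], values,
            [VariantDef(id=a, kind="SNP", locus="6", allele="A", group=a) for a in ("lo", "at")],
        )
        filtered, log = mf.maf_filter(dm, threshold=0.01)
        assert filtered.ids == ["at"]
        assert list(log["id"]) == ["lo"]

    def test_counts_on_toy_matrix(self):
        dm = self._matrix([0.001, 0.004, 0.008, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        filtered, log = mf.maf_filter(dm, threshold=0.01)
        assert len(filtered.variants) == 7 and len(log) == 3

    def test_idempotence(self):
        dm = self._matrix([0.004, 0.05, 0.3])
        once, _ = mf.maf_filter(dm)
        twice, log2 = mf.maf_filter(once)
        assert twice.ids == once.ids and len(log2) == 0
        np.testing.assert_array_equal(twice.values, once.values)


class TestInfoScore:
    def test_hard_calls_at_hwe_near_one(self):
        rng = np.random.default_rng(44)
        d = rng.binomial(2, 0.3, size=20_000).astype(float)
        assert info_score(d) == pytest.approx(1.0, abs=0.05)

    def test_constant_expected_dosage_is_zero(self):
        d = np.full(100, 0.6)  # everyone at 2f = 0.6
        assert info_score(d, frequency=0.3) == 0.0

    def test_hand_computed_ratio(self):
        d = np.array([0.0, 1.0, 1.0, 2.0])  # variance 0.5, f = 0.5
        assert info_score(d) == pytest.approx(1.0)

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            info_score(np.zeros(10))


class TestExpectedDosagePath:
    def test_group_sum_holds_in_expectation(self):
        rng = np.random.default_rng(55)
        n = 50
        codes = {"DRB1": rng.integers(0, 3, size=(n, 2)).astype(np.int32)}
        labels = {"DRB1": ["15:01", "03:01", "07:01"]}
        post = {"DRB1": rng.uniform(0.7, 1.0, size=(n, 2))}
        calls = PhasedCallSet([f"S{i}" for i in range(n)], codes, labels, post)
        dm = mf.binarize_classical(calls, "DRB1")
        total = dm.values.sum(axis=1)
        np.testing.assert_allclose(total, post["DRB1"].sum(axis=1), atol=1e-6)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_group_sum_conservation_property(seed):
    """Complete hard calls: classical dosages at a locus always sum to 2."""
    rng = np.random.default_rng(seed)
    n_hap = rng.integers(2, 6)
    alleles = [f"{i:02d}:01" for i in range(n_hap)]
    freq = rng.dirichlet(np.ones(n_hap))
    table = pd.DataFrame({"frequency": freq, "DRB1": alleles})
    pool = mf.build_haplotype_pool(table)
    cfg = mf.SimulationConfig(
        strata=[mf.StratumSpec(name="all", n_subjects=40)], n_pcs=0, seed=int(seed)
    )
    cohort = mf.sample_cohort(pool, cfg)
    dm = mf.binarize_classical(cohort.calls, "DRB1")
    np.testing.assert_allclose(dm.values.sum(axis=1), 2.0)
    assert np.isin(dm.values, [0.0, 1.0, 2.0]).all()


def test_vcf_roundtrip(tmp_path, example_pool):
    cyvcf2 = pytest.importorskip("cyvcf2")
    cfg = mf.SimulationConfig(
        strata=[mf.StratumSpec(name="all", n_subjects=50)], n_pcs=0, seed=66
    )
    cohort = mf.sample_cohort(example_pool, cfg)
    path = tmp_path / "snps.vcf"
    from mhcfinemap.simulate import write_snp_vcf
    from mhcfinemap.encode import read_snp_vcf

    write_snp_vcf(cohort, path)
    calls, positions = read_snp_vcf(path)
    assert calls.subjects == cohort.calls.subjects
    for snp in example_pool.snps:
        for allele in example_pool.labels[snp]:
            np.testing.assert_array_equal(
                calls.dosage(snp, allele), cohort.calls.dosage(snp, allele)
            )
        assert positions[snp][1] == example_pool.snp_meta[snp][1]
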