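"""Association core: logistic fits, omnibus LRTs, comparisons, R^2."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mhcfinemap as mf
from mhcfinemap.assoc import (
    bonferroni_threshold,
    fit_logistic,
    lrt,
    nagelkerke_r2,
)
from mhcfinemap.encode import DosageMatrix, VariantDef


def _data_from_columns(columns: dict, y, strata=None, pcs=None):
    """Assemble a StudyData from raw dosage columns (test helper)."""
    n = len(y)
    subjects = [f"S{i}" for i in range(n)]
    variants = [
        VariantDef(id=k, kind="SNP", locus="6", allele="A", group=k) for k in columns
    ]
    dm = DosageMatrix(subjects, np.column_stack(list(columns.values())), variants)
    pheno = pd.DataFrame({"subject_id": subjects, "status": np.asarray(y, dtype=int)})
    if strata is not None:
        pheno["stratum"] = strata
    if pcs is not None:
        for j in range(pcs.shape[1]):
            pheno[f"PC{j + 1}"] = pcs[:, j]
    return mf.StudyData(dm, pheno)


class TestFitLogistic:
    def test_null_model_closed_form(self):
        n = 200
        y = np.array([0, 1] * (n // 2), dtype=float)
        fit = fit_logistic(np.ones((n, 1)), y)
        assert fit.coef("x0") == pytest.approx(0.0, abs=1e-8)
        assert fit.loglik == pytest.approx(n * math.log(0.5), rel=1e-12)
        assert fit.loglik <= 0

    def test_two_by_two_closed_form(self):
        # exposed cases 30 / unexposed cases 70; exposed controls 10 / unexposed 90
        y = np.r_[np.ones(100), np.zeros(100)]
        x = np.r_[np.ones(30), np.zeros(70), np.ones(10), np.zeros(90)]
        fit = fit_logistic(np.column_stack([np.ones(200), x]), y, names=("b0", "x"))
        assert fit.coef("x") == pytest.approx(math.log(27 / 7), abs=1e-7)
        assert fit.odds_ratio("x") == pytest.approx(27 / 7, rel=1e-6)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(1)
        n = 400
        X = np.column_stack([np.ones(n), rng.binomial(2, 0.3, n), rng.standard_normal(n)])
        eta = -0.3 + 0.6 * X[:, 1] - 0.4 * X[:, 2]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        mine = fit_logistic(X, y)
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(mine.params, ref.params, atol=1e-6)
        np.testing.assert_allclose(mine.se, ref.bse, atol=1e-5)
        assert mine.loglik == pytest.approx(ref.llf, abs=1e-8)

    def test_aliased_column_dropped_and_counted(self):
        rng = np.random.default_rng(2)
        n = 300
        x = rng.binomial(2, 0.4, n).astype(float)
        X = np.column_stack([np.ones(n), x, 2.0 - x])  # third = 2 - second
        y = (rng.random(n) < 0.5).astype(float)
        fit = fit_logistic(X, y, names=("b0", "a", "comp"))
        assert fit.rank == 2
        assert fit.aliased == ("comp",)
        assert np.isnan(fit.coef("comp"))

    def test_separation_flagged(self):
        y = np.r_[np.ones(20), np.zeros(20)]
        x = y.copy()  # perfect separation
        fit = fit_logistic(np.column_stack([np.ones(40), x]), y)
        assert fit.separated

    def test_stratum_confounding_removed_by_dummies(self):
        # Simpson structure: within each stratum OR = 2, but stratum 2 has
        # higher exposure and lower baseline risk
        rng = np.random.default_rng(3)
        n = 4000
        stratum = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
        p_exp = np.where(stratum == "a", 0.2, 0.8)
        x = rng.binomial(2, p_exp).astype(float)
        base = np.where(stratum == "a", 1.0, -2.0)
        eta = base + math.log(2) * x
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        data_plain = _data_from_columns({"x": x}, y)
        data_strat = _data_from_columns({"x": x}, y, strata=stratum)
        fit_plain = data_plain.fit(["x"])
        fit_strat = data_strat.fit(["x"])
        # adjusted estimate within ~2.5 SE of truth; unadjusted badly biased
        assert abs(fit_strat.coef("x") - math.log(2)) < 2.5 * fit_strat.stderr("x")
        assert abs(fit_plain.coef("x") - math.log(2)) > 0.3  # confounded


class TestLRT:
    def test_identical_models(self):
        y = np.array([0.0, 1.0] * 50)
        f = fit_logistic(np.ones((100, 1)), y)
        res = lrt(f, f)
        assert res.deviance == 0.0 and res.df == 0 and not res.defined

    def test_textbook_quantile(self):
        res = mf.LRTResult(deviance=3.841458820694124, df=1, log10p=stats.chi2.logsf(3.841458820694124, 1) / math.log(10))
        assert res.p == pytest.approx(0.05, rel=1e-6)

    def test_deviance_matches_grid_search_oracle(self):
        # brute-force maximization over (intercept, slope) on a small set
        rng = np.random.default_rng(4)
        n = 60
        x = rng.binomial(2, 0.4, n).astype(float)
        eta = -0.2 + 0.8 * x
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)

        def loglik(b0, b1):
            e = b0 + b1 * x
            return float(y @ e - np.logaddexp(0, e).sum())

        def grid_max(f):
            c = np.zeros(2)
            width = 4.0
            for _ in range(6):
                g0 = np.linspace(c[0] - width, c[0] + width, 41)
                g1 = np.linspace(c[1] - width, c[1] + width, 41)
                vals = np.array([[f(a, b) for b in g1] for a in g0])
                i, j = np.unravel_index(np.argmax(vals), vals.shape)
                c = np.array([g0[i], g1[j]])
                width /= 8.0
            return f(*c)

        l1 = grid_max(loglik)
        l0 = grid_max(lambda b0, b1: loglik(b0, 0.0))
        d_oracle = 2 * (l1 - l0)
        fit1 = fit_logistic(np.column_stack([np.ones(n), x]), y)
        fit0 = fit_logistic(np.ones((n, 1)), y)
        assert lrt(fit0, fit1).deviance == pytest.approx(d_oracle, abs=1e-4)

    def test_log_space_tail_below_1e_300(self):
        from mhcfinemap.assoc import chi2_log10sf

        # inside scipy's range the two agree ...
        assert chi2_log10sf(1074.0, 1) == pytest.approx(
            stats.chi2.logsf(1074.0, 1) / math.log(10), rel=1e-10
        )
        # ... and the asymptotic branch continues smoothly past underflow
        # (scipy's sf is 0 beyond deviance ~1420)
        lo, hi = chi2_log10sf(1419.0, 2), chi2_log10sf(1421.0, 2)
        assert np.isfinite(hi) and hi < lo < -300
        # k = 1 cross-check against the exact normal-tail identity
        d = 2000.0
        expected = (math.log(2.0) + stats.norm.logsf(math.sqrt(d))) / math.log(10)
        assert chi2_log10sf(d, 1) == pytest.approx(expected, rel=1e-8)


class TestOmnibus:
    def test_reference_allele_invariance(self, risk_data):
        """Omnibus p is an exact reparameterization across reference choices."""
        dm = risk_data.dm
        members = [v.id for v in dm.variants if v.group == "rs100"]
        assert len(members) == 2
        fit0 = risk_data.null_fit(())
        results = []
        for drop in members:
            cols = [m for m in members if m != drop]
            fit1 = risk_data.fit(cols)
            results.append(lrt(fit0, fit1).log10p)
        assert results[0] == pytest.approx(results[1], abs=1e-10)

    def test_aa_position_df_three_for_four_residues(self, risk_data, aa_dict):
        four = risk_data.dm.select(risk_data.dm.locus_members("DRB1"))
        aa, _ = mf.translate_to_amino_acids(four, aa_dict, "DRB1")
        dm = mf.DosageMatrix.concat([risk_data.dm, aa])
        data = mf.StudyData(dm, _pheno_from(risk_data))
        res = mf.omnibus_aa_position(data, "DRB1", 71)
        assert res.df == 3  # four residues -> three non-reference columns

    def test_self_conditioning_undefined(self, risk_data):
        res = mf.test_variant(risk_data, "DRB1*15:01", conditioning=["DRB1*15:01"])
        assert not res.defined and res.df == 0

    def test_locus_test_after_conditioning(self, risk_data):
        full = mf.test_locus(risk_data, "DQB1")
        cond = mf.test_locus(risk_data, "DQB1", conditioning=["DQB1*06:02"])
        # group-sum aliasing: full locus of p alleles has df p-1
        assert full.df == len(risk_data.dm.locus_members("DQB1")) - 1
        assert cond.df == full.df - 1

    def test_deviance_additivity_along_chain(self, risk_data):
        d_total = mf.test_variant(risk_data, "DRB1*15:01").deviance + mf.test_variant(
            risk_data, "A*02:01", conditioning=["DRB1*15:01"]
        ).deviance
        fit0 = risk_data.null_fit(())
        fit2 = risk_data.fit(["DRB1*15:01", "A*02:01"])
        assert 2 * (fit2.loglik - fit0.loglik) == pytest.approx(d_total, abs=1e-6)


def _pheno_from(data):
    pheno = pd.DataFrame({"subject_id": data.dm.subjects, "status": data.y.astype(int)})
    pheno["stratum"] = data.strata
    C = data._C
    for j, name in enumerate(data.pc_names):
        pheno[name] = C[:, 1 + j]
    return pheno


class TestCompareEffects:
    def test_perfect_proxies_labelled_equivalent(self, two_hap_pool):
        cfg = mf.SimulationConfig(
            strata=[mf.StratumSpec(name="all", n_subjects=600)],
            effects={"DRB1*15:01": 0.8},
            n_pcs=0,
            seed=30,
        )
        cohort = mf.sample_cohort(two_hap_pool, cfg)
        dm = mf.DosageMatrix.concat(
            [mf.binarize_classical(cohort.calls, "DRB1"), mf.binarize_classical(cohort.calls, "DQB1")]
        )
        data = mf.StudyData.from_cohort(cohort, dm)
        cmp = mf.compare_effects(data, "DRB1*15:01", "DQB1*06:02")
        assert cmp.label == "equivalent"
        assert not cmp.a_given_b.defined  # no residual df once the proxy is in

    def test_causal_explains_tag(self, uniform4_pool):
        # 15:01 causal; DQB1*06:02 tags it at r^2 < 1
        cfg = mf.SimulationConfig(
            strata=[mf.StratumSpec(name="all", n_subjects=6000)],
            effects={"DRB1*15:01": 1.0},
            n_pcs=0,
            seed=31,
        )
        cohort = mf.sample_cohort(uniform4_pool, cfg)
        dm = mf.DosageMatrix.concat(
            [mf.binarize_classical(cohort.calls, "DRB1"), mf.binarize_classical(cohort.calls, "DQB1")]
        )
        data = mf.StudyData.from_cohort(cohort, dm)
        cmp = mf.compare_effects(data, "DRB1*15:01", "DQB1*06:02")
        assert cmp.label == "A explains B"

    def test_independent_effects_detected(self, example_pool):
        cfg = mf.SimulationConfig(
            strata=[mf.StratumSpec(name="all", n_subjects=6000)],
            effects={"DRB1*15:01": 0.9, "B*08:01": 0.5},
            n_pcs=0,
            seed=32,
        )
        cohort = mf.sample_cohort(example_pool, cfg)
        dm = mf.DosageMatrix.concat(
            [mf.binarize_classical(cohort.calls, "DRB1"), mf.binarize_classical(cohort.calls, "B")]
        )
        data = mf.StudyData.from_cohort(cohort, dm)
        cmp = mf.compare_effects(data, "DRB1*15:01", "B*08:01")
        assert cmp.label == "independent"


class TestInteraction:
    def test_planted_product_term_detected(self):
        rng = np.random.default_rng(40)
        n = 8000
        a = rng.binomial(2, 0.3, n).astype(float)
        b = rng.binomial(2, 0.4, n).astype(float)
        eta = -0.5 + 0.3 * a + 0.2 * b + 0.5 * a * b
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        data = _data_from_columns({"a": a, "b": b}, y)
        res = mf.interaction_test(data, "a", "b")
        assert res.df == 1 and res.p < 1e-5

    def test_constant_factor_raises(self):
        rng = np.random.default_rng(41)
        n = 200
        a = np.zeros(n)
        b = rng.binomial(2, 0.4, n).astype(float)
        y = (rng.random(n) < 0.5).astype(float)
        data = _data_from_columns({"a": a, "b": b}, y)
        with pytest.raises(ValueError, match="aliased"):
            mf.interaction_test(data, "a", "b")

    def test_additive_null_calibration(self):
        """Under a purely additive model the interaction p is uniform."""
        rng = np.random.default_rng(42)
        n = 600
        pvals = []
        for _ in range(200):
            a = rng.binomial(2, 0.3, n).astype(float)
            b = rng.binomial(2, 0.4, n).astype(float)
            eta = -0.2 + 0.4 * a + 0.3 * b
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
            data = _data_from_columns({"a": a, "b": b}, y)
            pvals.append(mf.interaction_test(data, "a", "b").p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestStratifiedScan:
    def test_simpson_structure_recovered(self):
        # the risk SNP allele rides mostly on non-15:01 haplotypes, so its
        # marginal association is masked by the strong 15:01 effect while
        # both carrier strata show the true within-stratum effect
        table = pd.DataFrame(
            {
                "frequency": [0.13, 0.02, 0.50, 0.35],
                "DRB1": ["15:01", "15:01", "07:01", "07:01"],
                "rs1": ["C", "G", "G", "C"],
            }
        )
        pool = mf.build_haplotype_pool(table)
        cfg = mf.SimulationConfig(
            strata=[mf.StratumSpec(name="all", n_subjects=12000)],
            effects={"DRB1*15:01": math.log(3.0), "rs1:G": math.log(1.25)},
            n_pcs=0,
            seed=50,
        )
        cohort = mf.sample_cohort(pool, cfg)
        dm = mf.DosageMatrix.concat(
            [
                mf.binarize_classical(cohort.calls, "DRB1"),
                mf.encode_snps(cohort.calls, ["rs1"]),
            ]
        )
        data = mf.StudyData.from_cohort(cohort, dm)
        out = mf.stratified_scan(data, "DRB1*15:01", ["rs1:G"])
        or_carrier = out["carrier"].iloc[0]["OR"]
        or_non = out["non-carrier"].iloc[0]["OR"]
        assert or_carrier > 1.1 and or_non > 1.1
        marginal = data.fit(["rs1:G"]).odds_ratio("rs1:G")
        # marginally the effect is hidden (near or below 1)
        assert marginal < 1.1
        assert marginal < min(or_carrier, or_non)

    def test_empty_stratum_raises(self):
        rng = np.random.default_rng(51)
        n = 100
        idx = np.ones(n)  # everyone carries the index variant
        b = rng.binomial(2, 0.3, n).astype(float)
        y = (rng.random(n) < 0.5).astype(float)
        data = _data_from_columns({"idx": idx, "b": b}, y)
        with pytest.raises(ValueError, match="empty"):
            mf.stratified_scan(data, "idx", ["b"])


class TestNagelkerke:
    def test_null_is_zero(self):
        y = np.array([0.0, 1.0] * 50)
        f0 = fit_logistic(np.ones((100, 1)), y)
        assert nagelkerke_r2(f0, f0) == 0.0

    def test_arithmetic_oracle(self):
        f0 = mf.FitResult(("i",), np.zeros(1), np.zeros(1), -69.31, 1, True, False, 100)
        f1 = mf.FitResult(("i",), np.zeros(1), np.zeros(1), -59.31, 2, True, False, 100)
        expected = (1 - math.exp((2 / 100) * (-69.31 + 59.31))) / (1 - math.exp((2 / 100) * -69.31))
        assert nagelkerke_r2(f0, f1, 100) == pytest.approx(expected, rel=1e-12)

    def test_saturated_limit_near_one(self):
        rng = np.random.default_rng(60)
        n = 300
        x = rng.standard_normal(n)
        y = (x > 0).astype(float)  # deterministically separable
        f0 = fit_logistic(np.ones((n, 1)), y)
        f1 = fit_logistic(np.column_stack([np.ones(n), x]), y)
        assert nagelkerke_r2(f0, f1) > 0.9

    def test_worse_fit_rejected(self):
        f0 = mf.FitResult(("i",), np.zeros(1), np.zeros(1), -50.0, 1, True, False, 100)
        f1 = mf.FitResult(("i",), np.zeros(1), np.zeros(1), -60.0, 2, True, False, 100)
        with pytest.raises(ValueError):
            nagelkerke_r2(f0, f1, 100)


class TestModelSpec:
    def test_eight_strata_give_seven_dummies(self, example_pool):
        cfg = mf.SimulationConfig(strata=mf.table1_strata(), n_pcs=5, seed=70)
        # tiny per-stratum cohort shares the same stratum structure
        small = [
            mf.StratumSpec(name=s.name, n_subjects=30) for s in cfg.strata
        ]
        cohort = mf.sample_cohort(
            example_pool, mf.SimulationConfig(strata=small, n_pcs=5, seed=70)
        )
        dm = mf.binarize_classical(cohort.calls, "DRB1")
        data = mf.StudyData.from_cohort(cohort, dm)
        spec = data.model_spec(["DRB1*15:01"])
        assert len(spec.stratum_dummies) == 7
        assert len(spec.pc_terms) == 5

    def test_type_one_error_calibrated_small(self):
        """Quick check the omnibus test holds its size (full study in acceptance)."""
        pool = mf.random_snp_pool(40, seed=71)
        rej = tot = 0
        from mhcfinemap.benchmarks import null_calibration_replicate

        for rep in range(25):
            r, t, _ = null_calibration_replicate(pool, seed=1000 + rep, n_subjects=500)
            rej += r
            tot += t
        rate = rej / tot
        assert 0.02 < rate < 0.09


def test_bonferroni_threshold_exact():
    assert bonferroni_threshold(0.05, 5000) == 1e-5
    with pytest.raises(ValueError):
        bonferroni_threshold(0.0, 100)
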