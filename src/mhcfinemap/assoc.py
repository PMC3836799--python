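"""Logistic association models and omnibus likelihood-ratio tests.

The modelling convention throughout: case-control status is regressed on
additive per-allele dosages, with the top principal components and
study-stratum dummy variables (one fewer than the number of strata) as
covariates.  Genetic effects are assumed fixed across strata, so pooling
is a single model with stratum dummies, not a meta-analysis.

A multi-allelic variant with ``p`` alleles contributes ``p - 1`` marker
columns (the reference allele — the most frequent among controls — is
excluded), and its omnibus p-value is the likelihood-ratio test of all of
them jointly.  Deviances follow a chi-square with degrees of freedom equal
to the *rank* difference between the nested designs, so exactly collinear
(aliased) columns never inflate the df.  P-values are computed and stored
in log10 space; the chi-square upper tail is evaluated in log space so
values far below 1e-300 remain representable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve

from .encode import DosageMatrix

__all__ = [
    "FitResult",
    "LRTResult",
    "ModelSpec",
    "StudyData",
    "EffectComparison",
    "fit_logistic",
    "lrt",
    "test_variant",
    "test_locus",
    "omnibus_aa_position",
    "compare_effects",
    "interaction_test",
    "stratified_scan",
    "nagelkerke_r2",
    "bonferroni_threshold",
    "association_scan",
    "chi2_log10sf",
]

_LN10 = math.log(10.0)


def bonferroni_threshold(alpha: float = 0.05, n_tests: int = 5000) -> float:
    """Study-wide significance threshold: alpha over the number of tests."""
    if not 0 < alpha < 1 or n_tests < 1:
        raise ValueError("need 0 < alpha < 1 and n_tests >= 1")
    return alpha / n_tests


# ----------------------------------------------------------------------
# Core fitter
# ----------------------------------------------------------------------
def _independent_columns(X: np.ndarray, tol: float = 1e-8) -> list:
    """Greedy rank detection preserving column order.

    Column j is kept iff its residual after projection onto the already
    kept columns exceeds ``tol`` times its own norm.  Keeping order means
    covariates and conditioning terms take precedence over newly added
    marker terms when a group is exactly collinear.
    """
    n, p = X.shape
    Q = np.empty((n, min(n, p)))
    r = 0
    keep = []
    for j in range(p):
        v = X[:, j].astype(float)
        nv = np.linalg.norm(v)
        if nv == 0:
            continue
        if r:
            v = v - Q[:, :r] @ (Q[:, :r].T @ v)
            v = v - Q[:, :r] @ (Q[:, :r].T @ v)  # re-orthogonalise once
        rv = np.linalg.norm(v)
        if rv > tol * nv:
            Q[:, r] = v / rv
            r += 1
            keep.append(j)
    return keep


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


@dataclass
class FitResult:
    """A fitted logistic model: estimates, log-likelihood, effective rank."""

    names: tuple
    params: np.ndarray  # full length; NaN for aliased columns
    se: np.ndarray
    loglik: float
    rank: int
    converged: bool
    separated: bool
    n_obs: int
    aliased: tuple = ()

    def coef(self, name: str) -> float:
        return float(self.params[self.names.index(name)])

    def stderr(self, name: str) -> float:
        return float(self.se[self.names.index(name)])

    def odds_ratio(self, name: str) -> float:
        return math.exp(self.coef(name))

    def or_conf_int(self, name: str, level: float = 0.95) -> tuple:
        z = stats.norm.ppf(0.5 + level / 2.0)
        b, s = self.coef(name), self.stderr(name)
        return math.exp(b - z * s), math.exp(b + z * s)


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    names: Sequence[str] | None = None,
    gtol: float = 1e-8,
    max_iter: int = 100,
    rank_tol: float = 1e-8,
) -> FitResult:
    """Maximum-likelihood logistic regression by Newton-Raphson.

    Exactly collinear columns are detected up front and excluded (their
    coefficients are NaN); ``rank`` counts the retained columns, which is
    what the likelihood-ratio df bookkeeping uses.  Coefficients running
    away (|beta| > 15) flag complete separation.  The fit is deterministic:
    it always starts from zero.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if names is None:
        names = tuple(f"x{j}" for j in range(p))
    names = tuple(names)

    norms = np.linalg.norm(X, axis=0)
    norms[norms == 0] = 1.0
    keep = _independent_columns(X / norms, tol=rank_tol)
    Xk = X[:, keep]
    rank = len(keep)

    beta = np.zeros(rank)
    eta = Xk @ beta
    ll = _loglik(eta, y)
    converged = False
    H = np.eye(rank)
    for _ in range(max_iter):
        mu = _sigmoid(eta)
        g = Xk.T @ (y - mu)
        if np.max(np.abs(g), initial=0.0) <= gtol * max(1.0, n):
            converged = True
            break
        w = mu * (1.0 - mu) + 1e-12
        H = Xk.T @ (Xk * w[:, None])
        try:
            step = solve(H, g, assume_a="pos")
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        # step halving keeps the likelihood monotone
        t = 1.0
        for _ in range(40):
            eta_new = Xk @ (beta + t * step)
            ll_new = _loglik(eta_new, y)
            if ll_new >= ll - 1e-12:
                break
            t *= 0.5
        beta = beta + t * step
        eta, ll = eta_new, ll_new
    else:
        converged = np.max(np.abs(Xk.T @ (y - _sigmoid(eta))), initial=0.0) <= gtol * max(1.0, n)

    separated = bool(np.max(np.abs(beta), initial=0.0) > 15.0)
    mu = _sigmoid(eta)
    w = mu * (1.0 - mu) + 1e-12
    H = Xk.T @ (Xk * w[:, None])
    try:
        cov = np.linalg.inv(H)
        se_k = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se_k = np.full(rank, np.nan)

    params = np.full(p, np.nan)
    se = np.full(p, np.nan)
    params[keep] = beta
    se[keep] = se_k
    aliased = tuple(names[j] for j in range(p) if j not in set(keep))
    return FitResult(
        names=names,
        params=params,
        se=se,
        loglik=ll,
        rank=rank,
        converged=converged,
        separated=separated,
        n_obs=n,
        aliased=aliased,
    )


# ----------------------------------------------------------------------
# Likelihood-ratio machinery
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class LRTResult:
    """Deviance, degrees of freedom, and log10 p of a nested comparison."""

    deviance: float
    df: int
    log10p: float  # NaN when df == 0 (test undefined)
    n_terms: int | None = None  # columns offered before aliasing, if relevant

    @property
    def defined(self) -> bool:
        return self.df > 0

    @property
    def p(self) -> float:
        if not self.defined:
            return float("nan")
        return 10.0 ** self.log10p if self.log10p > -300 else 0.0

    def significant(self, threshold: float) -> bool:
        return self.defined and self.log10p <= math.log10(threshold)


def lrt(fit0: FitResult, fit1: FitResult, n_terms: int | None = None) -> LRTResult:
    """Likelihood-ratio (deviance) test of nested fits.

    ``D = 2 (L1 - L0)`` referred to a chi-square whose df is the rank
    difference of the two designs.  The tail is computed with
    ``chi2.logsf`` so astronomically small p-values keep full precision.
    """
    if fit0.n_obs != fit1.n_obs:
        raise ValueError("nested fits must use the same subjects")
    d = 2.0 * (fit1.loglik - fit0.loglik)
    if d < -1e-5:
        raise ValueError(f"negative deviance ({d:.3g}): models are not nested or did not converge")
    d = max(d, 0.0)
    k = fit1.rank - fit0.rank
    if k <= 0:
        return LRTResult(deviance=d, df=0, log10p=float("nan"), n_terms=n_terms)
    return LRTResult(deviance=d, df=k, log10p=chi2_log10sf(d, k), n_terms=n_terms)


def chi2_log10sf(d: float, k: int) -> float:
    """log10 of the chi-square upper tail, finite even past 1e-300.

    Uses scipy's ``chi2.logsf`` where it is finite; when the survival
    function underflows (deviances beyond ~1420) falls back to the
    asymptotic series ``sf ~ exp(-d/2) (d/2)^(k/2-1) / Gamma(k/2) *
    sum_j prod_i (k/2 - i) / (d/2)^j``, valid for d >> k.
    """
    val = float(stats.chi2.logsf(d, k)) / _LN10
    if math.isfinite(val):
        return val
    a = k / 2.0
    x = d / 2.0
    # series sum: 1 + (a-1)/x + (a-1)(a-2)/x^2 + ...
    term, total = 1.0, 1.0
    for i in range(1, 20):
        term *= (a - i) / x
        total += term
        if abs(term) < 1e-16:
            break
    return ((a - 1.0) * math.log(x) - x - math.lgamma(a) + math.log(max(total, 1e-300))) / _LN10


# ----------------------------------------------------------------------
# Study data: dosages + phenotype + covariates
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class ModelSpec:
    """Symbolic description of one logistic model.

    Marker terms are dosage columns (already reduced to p-1 per
    multi-allelic group); stratum dummies number one fewer than the
    strata.  The intercept is implicit.
    """

    marker_terms: tuple
    conditioning_terms: tuple
    pc_terms: tuple
    stratum_dummies: tuple

    @property
    def column_names(self) -> tuple:
        return (
            ("(intercept)",)
            + self.pc_terms
            + self.stratum_dummies
            + self.conditioning_terms
            + self.marker_terms
        )


class StudyData:
    """A dosage matrix aligned with phenotype, PCs and stratum labels.

    The phenotype table needs ``subject_id``, ``status`` (0/1), and
    optionally ``stratum`` plus ``PC*`` columns.  Rows are aligned to the
    dosage matrix subject order.
    """

    def __init__(
        self,
        dm: DosageMatrix,
        phenotype: pd.DataFrame,
        pc_cols: Sequence[str] | None = None,
        stratum_col: str = "stratum",
        status_col: str = "status",
    ) -> None:
        pheno = phenotype.set_index("subject_id").loc[dm.subjects]
        self.dm = dm
        self.y = pheno[status_col].to_numpy(dtype=float)
        if set(np.unique(self.y)) - {0.0, 1.0}:
            raise ValueError("status must be 0/1")
        if pc_cols is None:
            pc_cols = [c for c in pheno.columns if c.startswith("PC")]
        self.pc_names = tuple(pc_cols)
        pcs = pheno[list(pc_cols)].to_numpy(dtype=float) if pc_cols else np.empty((len(pheno), 0))
        if stratum_col in pheno.columns:
            self.strata = pheno[stratum_col].astype(str).to_numpy()
            levels = sorted(set(self.strata))
        else:
            self.strata = np.array(["all"] * len(pheno))
            levels = ["all"]
        self.stratum_levels = levels
        dummies = np.column_stack(
            [(self.strata == lev).astype(float) for lev in levels[1:]]
        ) if len(levels) > 1 else np.empty((len(pheno), 0))
        self.dummy_names = tuple(f"stratum[{lev}]" for lev in levels[1:])
        n = len(self.y)
        self._C = np.column_stack([np.ones(n), pcs, dummies])
        self._cov_names = ("(intercept)",) + self.pc_names + self.dummy_names
        self.groups: Mapping[str, list] = dm.groups()
        self._ref_cache: dict = {}
        self._null_cache: dict = {}

    # ------------------------------------------------------------------
    @classmethod
    def from_cohort(cls, cohort, dm: DosageMatrix) -> "StudyData":
        return cls(dm, cohort.covariates)

    @property
    def n(self) -> int:
        return len(self.y)

    def model_spec(self, markers: Sequence[str], conditioning: Sequence[str] = ()) -> ModelSpec:
        return ModelSpec(
            marker_terms=tuple(self._expand(markers)),
            conditioning_terms=tuple(self._expand(conditioning)),
            pc_terms=self.pc_names,
            stratum_dummies=self.dummy_names,
        )

    # -- group / reference handling ------------------------------------
    def reference_allele(self, group: str) -> str | None:
        """Most frequent member among controls; None for single-marker groups."""
        members = self.groups[group]
        if len(members) == 1:
            return None
        if group not in self._ref_cache:
            controls = self.y == 0
            freqs = self.dm.columns(members)[controls].mean(axis=0)
            self._ref_cache[group] = members[int(np.argmax(freqs))]
        return self._ref_cache[group]

    def test_columns(self, group: str) -> list:
        """The p-1 non-reference marker columns of a multi-allelic group."""
        members = self.groups[group]
        if len(members) == 1:
            return list(members)
        ref = self.reference_allele(group)
        return [m for m in members if m != ref]

    def _expand(self, ids: Sequence[str]) -> list:
        """Resolve a mix of group keys and column ids to column ids."""
        out: list = []
        for i in ids:
            if i in self.groups:
                cols = self.test_columns(i)
            elif i in self.dm:
                cols = [i]
            else:
                raise KeyError(f"unknown variant or group {i!r}")
            out.extend(c for c in cols if c not in out)
        return out

    # -- fitting ---------------------------------------------------------
    def design(self, column_ids: Sequence[str], extra: np.ndarray | None = None):
        parts = [self._C]
        names = list(self._cov_names)
        if column_ids:
            parts.append(self.dm.columns(column_ids))
            names.extend(column_ids)
        if extra is not None:
            extra = np.atleast_2d(np.asarray(extra, dtype=float))
            if extra.shape[0] != self.n:
                extra = extra.T
            parts.append(extra)
            names.extend(f"extra{j}" for j in range(extra.shape[1]))
        return np.hstack(parts), tuple(names)

    def fit(self, column_ids: Sequence[str] = (), extra: np.ndarray | None = None, extra_names=None) -> FitResult:
        X, names = self.design(list(column_ids), extra)
        if extra_names is not None:
            names = names[: len(names) - len(extra_names)] + tuple(extra_names)
        return fit_logistic(X, self.y, names)

    def null_fit(self, conditioning_cols: Sequence[str] = ()) -> FitResult:
        key = tuple(conditioning_cols)
        if key not in self._null_cache:
            self._null_cache[key] = self.fit(list(key))
        return self._null_cache[key]

    def fit_model(self, spec: ModelSpec) -> FitResult:
        return self.fit(list(spec.conditioning_terms) + list(spec.marker_terms))

    # -- subsetting -------------------------------------------------------
    def subset(self, mask: np.ndarray) -> "StudyData":
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("empty subject subset")
        dm_sub = DosageMatrix(
            [s for s, m in zip(self.dm.subjects, mask) if m],
            self.dm.values[mask],
            self.dm.variants,
        )
        pheno = pd.DataFrame({"subject_id": dm_sub.subjects, "status": self.y[mask].astype(int)})
        pheno["stratum"] = self.strata[mask]
        pcs = self._C[:, 1 : 1 + len(self.pc_names)]
        for j, name in enumerate(self.pc_names):
            pheno[name] = pcs[mask, j]
        return StudyData(dm_sub, pheno, pc_cols=list(self.pc_names))


# ----------------------------------------------------------------------
# Tests
# ----------------------------------------------------------------------
def _test_with_fit(data: StudyData, test_cols: Sequence[str], conditioning_cols: Sequence[str]):
    test_cols = [c for c in test_cols if c not in set(conditioning_cols)]
    fit0 = data.null_fit(conditioning_cols)
    if not test_cols:
        return LRTResult(0.0, 0, float("nan")), fit0
    fit1 = data.fit(list(conditioning_cols) + test_cols)
    return lrt(fit0, fit1, n_terms=len(test_cols)), fit1


def test_variant(data: StudyData, group: str, conditioning: Sequence[str] = ()) -> LRTResult:
    """Omnibus LRT of one variant (all its non-reference alleles jointly).

    *group* may be a SNP id, a classical allele id, an amino-acid position
    key (``gene:position``), or a diplotype id.  The test conditions on the
    resolved *conditioning* markers; a variant entirely aliased by the
    conditioning set comes back with df 0 (undefined), never a spurious p.
    """
    cond = data._expand(conditioning)
    if group in data.groups:
        cols = data.test_columns(group)
    elif group in data.dm:
        cols = [group]
    else:
        raise KeyError(f"unknown variant {group!r}")
    res, _ = _test_with_fit(data, cols, cond)
    return res


def test_locus(data: StudyData, locus: str, conditioning: Sequence[str] = ()) -> LRTResult:
    """Residual locus effect: joint LRT of the gene's four-digit alleles
    not already held in the conditioning set."""
    cond = data._expand(conditioning)
    members = data.dm.locus_members(locus, kind="HLA4d")
    if not members:
        raise KeyError(f"no four-digit markers for locus {locus!r}")
    cols = [m for m in members if m not in set(cond)]
    res, _ = _test_with_fit(data, cols, cond)
    return res


def omnibus_aa_position(
    data: StudyData, gene: str, position: int, conditioning: Sequence[str] = ()
) -> LRTResult:
    """Omnibus test of all residues (but the reference) at one position."""
    group = f"{gene}:{position}"
    if group not in data.groups:
        raise KeyError(f"no amino-acid markers at {gene} position {position}")
    return test_variant(data, group, conditioning)


@dataclass(frozen=True)
class EffectComparison:
    """Paired conditional LRTs for two variants fitted jointly."""

    a: str
    b: str
    a_given_b: LRTResult
    b_given_a: LRTResult
    label: str


def compare_effects(
    data: StudyData, a: str, b: str, conditioning: Sequence[str] = (), alpha: float = 0.05
) -> EffectComparison:
    """Adjudicate two effects by testing each given the other.

    Fits M_A, M_B and M_AB (same covariates throughout) and compares
    M_AB against each single-variant model.  At the nominal *alpha*:
    both residual tests non-significant -> "equivalent"; only A keeps a
    residual effect -> "A explains B"; only B does -> "B explains A";
    both residuals significant -> "independent".
    """
    cond = data._expand(conditioning)
    cols_a = [c for c in data._expand([a]) if c not in cond]
    cols_b = [c for c in data._expand([b]) if c not in cond]
    fit_a = data.fit(cond + cols_a)
    fit_b = data.fit(cond + cols_b)
    fit_ab = data.fit(cond + cols_a + [c for c in cols_b if c not in cols_a])
    a_given_b = lrt(fit_b, fit_ab)
    b_given_a = lrt(fit_a, fit_ab)

    def sig(r: LRTResult) -> bool:
        return r.defined and r.p <= alpha

    if sig(a_given_b) and not sig(b_given_a):
        label = "A explains B"
    elif sig(b_given_a) and not sig(a_given_b):
        label = "B explains A"
    elif sig(a_given_b) and sig(b_given_a):
        label = "independent"
    else:
        label = "equivalent"
    return EffectComparison(a=a, b=b, a_given_b=a_given_b, b_given_a=b_given_a, label=label)


def interaction_test(
    data: StudyData, a: str, b: str, conditioning: Sequence[str] = ()
) -> LRTResult:
    """LRT of the product term: {A, B, AxB} against {A, B} (df 1).

    *a* and *b* must resolve to single dosage columns.  An aliased product
    column (e.g. a constant factor) raises rather than reporting df 0.
    """
    cond = data._expand(conditioning)
    cols_a, cols_b = data._expand([a]), data._expand([b])
    if len(cols_a) != 1 or len(cols_b) != 1:
        raise ValueError("interaction_test needs scalar dosage terms")
    base_cols = cond + [c for c in cols_a + cols_b if c not in cond]
    product = data.dm.column(cols_a[0]) * data.dm.column(cols_b[0])
    fit0 = data.fit(base_cols)
    fit1 = data.fit(base_cols, extra=product[:, None], extra_names=(f"{a}x{b}",))
    res = lrt(fit0, fit1, n_terms=1)
    if not res.defined:
        raise ValueError(f"interaction term {a} x {b} is aliased in this design")
    return res


def stratified_scan(
    data: StudyData, index_variant: str, groups: Sequence[str]
) -> dict:
    """Univariate scans within carriers and non-carriers of an index variant.

    Carriers are subjects with at least one copy (heterozygous or
    homozygous).  Returns ``{"carrier": frame, "non-carrier": frame}``
    with per-group OR, 95% CI and log10 p from each within-stratum fit.
    Raises if either stratum is empty.
    """
    index_cols = data._expand([index_variant])
    if len(index_cols) != 1:
        raise ValueError("index variant must be a single dosage column")
    carrier = data.dm.column(index_cols[0]) > 0
    out = {}
    for name, mask in (("carrier", carrier), ("non-carrier", ~carrier)):
        if not mask.any():
            raise ValueError(f"{name} stratum is empty")
        sub = data.subset(mask)
        rows = []
        for g in groups:
            res, fit1 = _test_with_fit(sub, sub._expand([g]), [])
            row = {"group": g, "deviance": res.deviance, "df": res.df, "log10p": res.log10p}
            cols = sub._expand([g])
            if len(cols) == 1 and res.defined and not np.isnan(fit1.coef(cols[0])):
                row["OR"] = fit1.odds_ratio(cols[0])
                row["OR_lo"], row["OR_hi"] = fit1.or_conf_int(cols[0])
            rows.append(row)
        out[name] = pd.DataFrame(rows)
    return out


def nagelkerke_r2(fit0: FitResult, fit1: FitResult, n: int | None = None) -> float:
    """Nagelkerke's pseudo-R^2 for nested logistic fits.

    ``[1 - (L0/L1)^(2/N)] / [1 - L0^(2/N)]`` with likelihoods L0 (null)
    and L1 (fitted); evaluated in log space and clipped to [0, 1].
    """
    if n is None:
        n = fit1.n_obs
    l0, l1 = fit0.loglik, fit1.loglik
    if l1 < l0 - 1e-6:
        raise ValueError("fitted model has lower likelihood than the null")
    num = 1.0 - math.exp((2.0 / n) * (l0 - l1))
    den = 1.0 - math.exp((2.0 / n) * l0)
    if den <= 0:
        return 0.0
    return float(min(max(num / den, 0.0), 1.0))


# ----------------------------------------------------------------------
# Scan table (regional-plot style output)
# ----------------------------------------------------------------------
def association_scan(
    data: StudyData, groups: Sequence[str] | None = None, conditioning: Sequence[str] = ()
) -> pd.DataFrame:
    """Per-variant omnibus results: id, kind, df, deviance, log10p, ORs.

    For single-column variants the per-allele odds ratio and 95% CI from
    the fitted model are included.
    """
    if groups is None:
        groups = list(data.groups)
    cond = data._expand(conditioning)
    rows = []
    for g in groups:
        cols = data.test_columns(g) if g in data.groups else [g]
        res, fit1 = _test_with_fit(data, cols, cond)
        kind = data.dm.variant(cols[0]).kind if cols else ""
        row = {
            "group": g,
            "kind": kind,
            "df": res.df,
            "deviance": res.deviance,
            "log10p": res.log10p,
        }
        free = [c for c in cols if c not in set(cond)]
        if len(free) == 1 and res.defined and not np.isnan(fit1.coef(free[0])):
            row["OR"] = fit1.odds_ratio(free[0])
            row["OR_lo"], row["OR_hi"] = fit1.or_conf_int(free[0])
        rows.append(row)
    out = pd.DataFrame(rows)
    return out.sort_values("log10p", na_position="last", kind="stable").reset_index(drop=True)
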