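"""Regularized-regression cross-checks for within-locus allele selection.

Four selection routes replicate the stepwise result from a different
statistical angle:

* **lasso** and **elastic net** — penalized *logistic* regression (the
  outcome is case-control), fitted by proximal gradient (FISTA) with the
  covariates (PCs, stratum dummies, intercept) always unpenalized.  The
  penalty is chosen by 10-fold cross-validated binomial deviance with the
  one-standard-error rule: the largest lambda whose mean CV error is
  within one SE of the minimum.
* **least-angle regression (LARS)** and **incremental forward stagewise**
  — the classical squared-error path algorithms, run on the outcome and
  allele dosages residualized on the covariates; the model size along the
  path is chosen by the same 1-SE rule on cross-validated squared error.

All four report the order in which alleles enter, so agreement between
methods can be checked both as sets and as paths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import lstsq
from sklearn.linear_model import lars_path
from sklearn.model_selection import StratifiedKFold

from .assoc import StudyData

__all__ = [
    "CVResult",
    "PenalizedPath",
    "SelectionResult",
    "one_se_penalty",
    "penalized_select",
    "enet_logistic",
    "stagewise_path",
]

METHODS = ("lasso", "enet", "lars", "stagewise")


@dataclass(frozen=True)
class CVResult:
    """Cross-validated error along a penalty (or model-size) grid."""

    grid: np.ndarray  # penalties, descending; or model sizes, ascending
    mean_error: np.ndarray
    se_error: np.ndarray
    chosen: float  # grid value picked by the 1-SE rule

    def as_dict(self) -> dict:
        return {
            "grid": self.grid.tolist(),
            "mean_error": self.mean_error.tolist(),
            "se_error": self.se_error.tolist(),
            "chosen": self.chosen,
        }


@dataclass(frozen=True)
class PenalizedPath:
    """Coefficients of the penalized block along the regularization path."""

    penalties: np.ndarray  # descending
    coefs: np.ndarray  # (n_penalties, n_alleles)
    names: tuple

    def active_sets(self) -> list:
        return [
            tuple(n for n, c in zip(self.names, row) if abs(c) > 1e-8) for row in self.coefs
        ]

    def entry_order(self) -> list:
        order: list = []
        for row in self.coefs:
            for name, c in zip(self.names, row):
                if abs(c) > 1e-8 and name not in order:
                    order.append(name)
        return order


@dataclass(frozen=True)
class SelectionResult:
    method: str
    selected: tuple  # allele ids in the chosen model
    order: tuple  # entry order along the path
    coefficients: dict  # allele -> coefficient in the chosen model
    cv: CVResult


def one_se_penalty(cv: CVResult) -> float:
    """Largest penalty whose mean CV error is within one SE of the minimum.

    For model-size grids (ascending) this is the *smallest* size within
    one SE, which is the same parsimony-first reading of the rule.
    """
    if len(cv.grid) == 0:
        raise ValueError("empty penalty grid")
    i_min = int(np.argmin(cv.mean_error))
    limit = cv.mean_error[i_min] + cv.se_error[i_min]
    ok = np.nonzero(cv.mean_error <= limit + 1e-12)[0]
    descending = len(cv.grid) < 2 or cv.grid[0] >= cv.grid[-1]
    if descending:
        return float(cv.grid[ok[0]])  # earliest = largest penalty
    return float(cv.grid[ok[0]])  # ascending sizes: earliest = smallest model


# ----------------------------------------------------------------------
# Penalized logistic regression (FISTA)
# ----------------------------------------------------------------------
def enet_logistic(
    X_pen: np.ndarray,
    X_unpen: np.ndarray,
    y: np.ndarray,
    lam: float,
    l1_ratio: float = 1.0,
    beta_init: np.ndarray | None = None,
    max_iter: int = 5000,
    tol: float = 1e-9,
) -> np.ndarray:
    """Elastic-net penalized logistic fit by FISTA.

    Minimizes ``(1/n) * NLL(beta) + lam * (l1_ratio*|b|_1 +
    (1-l1_ratio)/2*|b|_2^2)`` where the penalty applies only to the
    ``X_pen`` block; ``X_unpen`` (intercept, covariates) is free.  Returns
    the concatenated coefficient vector ``[unpenalized, penalized]``.
    """
    n = len(y)
    X = np.hstack([X_unpen, X_pen])
    p_u = X_unpen.shape[1]
    p = X.shape[1]
    beta = np.zeros(p) if beta_init is None else beta_init.copy()
    # Lipschitz constant of the logistic gradient: lambda_max(X'X) / (4n)
    gram = X.T @ X
    lip = float(np.linalg.eigvalsh(gram)[-1]) / (4.0 * n) + lam * (1.0 - l1_ratio)
    step = 1.0 / max(lip, 1e-12)
    z = beta.copy()
    t_acc = 1.0
    thr = lam * l1_ratio * step
    shrink = 1.0 / (1.0 + lam * (1.0 - l1_ratio) * step)
    for _ in range(max_iter):
        eta = X @ z
        mu = 0.5 * (1.0 + np.tanh(0.5 * eta))
        grad = X.T @ (mu - y) / n
        grad[p_u:] += lam * (1.0 - l1_ratio) * z[p_u:]
        b_new = z - step * grad
        pen = b_new[p_u:]
        b_new[p_u:] = np.sign(pen) * np.maximum(np.abs(pen) - thr, 0.0)
        t_new = 0.5 * (1.0 + math.sqrt(1.0 + 4.0 * t_acc * t_acc))
        z = b_new + ((t_acc - 1.0) / t_new) * (b_new - beta)
        delta = np.max(np.abs(b_new - beta))
        beta, t_acc = b_new, t_new
        if delta <= tol * max(1.0, np.max(np.abs(beta))):
            break
    return beta


def _lambda_grid(X_pen, X_unpen, y, l1_ratio, n_lambdas=30, ratio=1e-3):
    n = len(y)
    # gradient at the covariate-only optimum bounds the smallest
    # all-zero-coefficients lambda
    from .assoc import fit_logistic

    fit0 = fit_logistic(X_unpen, y)
    eta0 = X_unpen[:, ~np.isnan(fit0.params)] @ fit0.params[~np.isnan(fit0.params)]
    mu0 = 0.5 * (1.0 + np.tanh(0.5 * eta0))
    lam_max = np.max(np.abs(X_pen.T @ (y - mu0))) / (n * max(l1_ratio, 1e-3))
    return np.geomspace(lam_max, lam_max * ratio, n_lambdas)


def _binomial_deviance(eta: np.ndarray, y: np.ndarray) -> float:
    return float(2.0 * np.mean(np.logaddexp(0.0, eta) - y * eta))


def _standardize(X: np.ndarray):
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mean) / sd, mean, sd


def _enet_path(X_pen, X_unpen, y, lambdas, l1_ratio):
    coefs = np.empty((len(lambdas), X_pen.shape[1]))
    beta = None
    p_u = X_unpen.shape[1]
    for i, lam in enumerate(lambdas):
        beta = enet_logistic(X_pen, X_unpen, y, lam, l1_ratio, beta_init=beta)
        coefs[i] = beta[p_u:]
    return coefs


def _cv_enet(X_pen, X_unpen, y, lambdas, l1_ratio, folds, seed):
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    errors = np.empty((folds, len(lambdas)))
    for f, (tr, te) in enumerate(skf.split(X_pen, y)):
        beta = None
        p_u = X_unpen.shape[1]
        for i, lam in enumerate(lambdas):
            beta = enet_logistic(X_pen[tr], X_unpen[tr], y[tr], lam, l1_ratio, beta_init=beta)
            eta_te = X_unpen[te] @ beta[:p_u] + X_pen[te] @ beta[p_u:]
            errors[f, i] = _binomial_deviance(eta_te, y[te])
    mean = errors.mean(axis=0)
    se = errors.std(axis=0, ddof=1) / math.sqrt(folds)
    cv = CVResult(grid=np.asarray(lambdas), mean_error=mean, se_error=se, chosen=0.0)
    chosen = one_se_penalty(cv)
    return CVResult(grid=cv.grid, mean_error=mean, se_error=se, chosen=chosen)


# ----------------------------------------------------------------------
# Squared-error path methods on residualized data
# ----------------------------------------------------------------------
def _residualize(X_pen, X_unpen, y):
    """Project the covariate span out of the alleles and the outcome."""
    q, _ = np.linalg.qr(X_unpen)
    Xr = X_pen - q @ (q.T @ X_pen)
    yr = y - q @ (q.T @ y)
    return Xr, yr


def stagewise_path(X: np.ndarray, y: np.ndarray, eps: float = 0.01, max_steps: int = 20000):
    """Incremental forward stagewise on standardized columns.

    Repeatedly nudges the coefficient most correlated with the residual by
    ``eps * sign``; with small eps the visited active sets track the lasso
    path.  Returns ``(entry_order, coef_snapshots)`` with one snapshot per
    new-variable entry.
    """
    n, p = X.shape
    beta = np.zeros(p)
    r = y.astype(float).copy()
    order: list = []
    snapshots: list = []
    c_stop = eps * 0.5
    for _ in range(max_steps):
        c = X.T @ r / n
        j = int(np.argmax(np.abs(c)))
        if abs(c[j]) < c_stop:
            break
        if beta[j] == 0 and j not in order:
            order.append(j)
            snapshots.append(beta.copy())
        delta = eps * np.sign(c[j])
        beta[j] += delta
        r -= delta * X[:, j]
    snapshots.append(beta.copy())
    return order, snapshots


def _cv_model_size(Xr, yr, y_strat, order_fn, max_size, folds, seed):
    """CV squared error of OLS refits on the first-k active sets of a path."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    sizes = np.arange(0, max_size + 1)
    errors = np.empty((folds, len(sizes)))
    for f, (tr, te) in enumerate(skf.split(Xr, y_strat)):
        order = order_fn(Xr[tr], yr[tr])
        for k in sizes:
            active = order[:k]
            if k == 0 or not active:
                pred = np.zeros(len(te))
            else:
                coef = lstsq(Xr[tr][:, active], yr[tr])[0]
                pred = Xr[te][:, active] @ coef
            errors[f, k] = float(np.mean((yr[te] - pred) ** 2))
    mean = errors.mean(axis=0)
    se = errors.std(axis=0, ddof=1) / math.sqrt(folds)
    cv = CVResult(grid=sizes.astype(float), mean_error=mean, se_error=se, chosen=0.0)
    chosen = one_se_penalty(cv)
    return CVResult(grid=cv.grid, mean_error=mean, se_error=se, chosen=chosen)


def _lars_order(Xr, yr):
    _, active, _ = lars_path(Xr, yr, method="lar")
    return list(active)


def _stagewise_order(Xr, yr):
    order, _ = stagewise_path(Xr, yr)
    return order


# ----------------------------------------------------------------------
# Public entry point
# ----------------------------------------------------------------------
def penalized_select(
    data: StudyData,
    allele_ids: Sequence[str],
    method: str = "lasso",
    folds: int = 10,
    seed: int = 0,
    l1_ratio_enet: float = 0.5,
    n_lambdas: int = 30,
) -> SelectionResult:
    """Select alleles by one of the four regularized routes.

    Covariates (intercept, PCs, stratum dummies) are never penalized.
    Fold assignment is stratified by case status and fully determined by
    *seed*.  For ``lasso``/``enet`` the reported coefficients are on the
    original dosage scale at the 1-SE penalty; for ``lars``/``stagewise``
    they are the OLS refit on the chosen active set of the residualized
    problem.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    allele_ids = list(allele_ids)
    if len(allele_ids) < 2:
        raise ValueError("need at least two candidate alleles")
    y = data.y
    if len(y) < folds:
        raise ValueError("fewer subjects than folds")
    X_unpen = data._C
    X_raw = data.dm.columns(allele_ids)
    X_std, _, sd = _standardize(X_raw)

    if method in ("lasso", "enet"):
        l1_ratio = 1.0 if method == "lasso" else l1_ratio_enet
        lambdas = _lambda_grid(X_std, X_unpen, y, l1_ratio, n_lambdas=n_lambdas)
        cv = _cv_enet(X_std, X_unpen, y, lambdas, l1_ratio, folds, seed)
        path_coefs = _enet_path(X_std, X_unpen, y, lambdas, l1_ratio)
        path = PenalizedPath(penalties=lambdas, coefs=path_coefs, names=tuple(allele_ids))
        i_sel = int(np.argmin(np.abs(lambdas - cv.chosen)))
        coef_std = path_coefs[i_sel]
        coef = coef_std / sd  # back to per-dosage scale
        selected = tuple(a for a, c in zip(allele_ids, coef) if abs(c) > 1e-8)
        order = tuple(path.entry_order())
        coefficients = {a: float(c) for a, c in zip(allele_ids, coef) if abs(c) > 1e-8}
        return SelectionResult(method=method, selected=selected, order=order,
                               coefficients=coefficients, cv=cv)

    # lars / stagewise on residualized squared-error problem
    Xr, yr = _residualize(X_std, X_unpen, y)
    order_fn = _lars_order if method == "lars" else _stagewise_order
    full_order = order_fn(Xr, yr)
    cv = _cv_model_size(Xr, yr, y, order_fn, max_size=len(allele_ids), folds=folds, seed=seed)
    k = int(cv.chosen)
    active = full_order[:k]
    coef = np.zeros(len(allele_ids))
    if active:
        coef[active] = lstsq(Xr[:, active], yr)[0]
    selected = tuple(allele_ids[j] for j in active)
    coefficients = {allele_ids[j]: float(coef[j]) for j in active}
    return SelectionResult(
        method=method,
        selected=selected,
        order=tuple(allele_ids[j] for j in full_order),
        coefficients=coefficients,
        cv=cv,
    )
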