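"""Class-vs-condomless-sex association: 2x2 tables, logistic, mixed logistic.

Three estimators of the same contrast, in increasing order of structure:

* ``odds_ratio_2x2`` — closed-form odds ratio with a Wald confidence interval
  on the log-odds scale.
* ``logistic`` — maximum-likelihood logit with the latent class as the only
  (categorical) covariate; on a single binary contrast this reproduces the
  2x2 odds ratio exactly.
* ``mixed_logistic`` — random-intercept logistic regression (participants as
  clusters), maximized by adaptive Gauss-Hermite quadrature.  With the
  random-intercept standard deviation constrained to zero it reduces exactly
  to the plain logit.

A class in which every event has the outcome (or none does) separates the
likelihood and is rejected with an explicit error; the caller is expected to
exclude such degenerate classes from regression.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.special import expit, logsumexp
from scipy.stats import norm
import statsmodels.api as sm

__all__ = [
    "Method",
    "AssociationResult",
    "DegenerateTableError",
    "SeparationError",
    "odds_ratio_2x2",
    "logistic",
    "mixed_logistic",
]

Z975 = 1.959963984540054  # norm.ppf(0.975)


class DegenerateTableError(ValueError):
    """A 2x2 cell is zero; the all-outcome class must be excluded instead."""


class SeparationError(ValueError):
    """A class level perfectly predicts the outcome."""


class Method(enum.Enum):
    TWO_BY_TWO_WALD = "two_by_two_wald"
    LOGISTIC = "logistic"
    MIXED_LOGISTIC = "mixed_logistic"


@dataclass(frozen=True)
class AssociationResult:
    """One estimated contrast: odds ratio, Wald 95% CI, and p-value."""

    comparison: tuple[object, object]  # (class, reference class)
    odds_ratio: float
    ci95: tuple[float, float]
    se_log_or: float
    p_value: float
    method: Method
    random_intercept_sd: float | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        if not (self.odds_ratio > 0):
            raise ValueError("odds ratio must be positive")
        lo, hi = self.ci95
        if not (lo <= self.odds_ratio <= hi):
            raise ValueError("odds ratio must lie inside its CI")


def _wald(log_or: float, se: float, comparison, method: Method,
          sd: float | None = None, converged: bool = True) -> AssociationResult:
    z = log_or / se if se > 0 else np.inf * np.sign(log_or)
    return AssociationResult(
        comparison=comparison,
        odds_ratio=float(np.exp(log_or)),
        ci95=(float(np.exp(log_or - Z975 * se)), float(np.exp(log_or + Z975 * se))),
        se_log_or=float(se),
        p_value=float(2.0 * norm.sf(abs(z))),
        method=method,
        random_intercept_sd=sd,
        converged=converged,
    )


def odds_ratio_2x2(a: int, b: int, c: int, d: int,
                   comparison: tuple[object, object] = ("exposed", "reference")
                   ) -> AssociationResult:
    """Wald odds ratio for the table (a, b) exposed / (c, d) reference.

    ``a``/``c`` count events with the outcome, ``b``/``d`` without.
    OR = ad/bc; CI = exp(ln OR +- 1.96 sqrt(1/a + 1/b + 1/c + 1/d)).
    """
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise ValueError("cell counts must be nonnegative")
    if any(x == 0 for x in cells):
        raise DegenerateTableError(
            "zero cell in 2x2 table: a class with all (or no) events having the "
            "outcome cannot contribute an odds ratio and must be excluded from "
            "regression"
        )
    log_or = float(np.log(a) + np.log(d) - np.log(b) - np.log(c))
    se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    return _wald(log_or, se, comparison, Method.TWO_BY_TWO_WALD)


def _check_classes(outcome: np.ndarray, class_label: np.ndarray, reference) -> list:
    present = sorted(set(class_label.tolist()))
    if reference not in present:
        raise ValueError(f"reference class {reference!r} not present in the data")
    if len(present) < 2:
        raise SeparationError(
            "at least 2 classes are required after excluding degenerate classes"
        )
    for cl in present:
        y = outcome[class_label == cl]
        if y.all() or not y.any():
            raise SeparationError(
                f"class {cl!r} has {'100%' if y.all() else '0%'} outcome; "
                "perfect separation — exclude it from regression"
            )
    return present


def logistic(outcome: Sequence[bool], class_label: Sequence, reference
             ) -> list[AssociationResult]:
    """Per-class odds ratios versus the reference class from an ML logit fit."""
    y = np.asarray(outcome, dtype=float)
    cl = np.asarray(class_label)
    present = _check_classes(y.astype(bool), cl, reference)
    others = [c for c in present if c != reference]
    X = np.column_stack(
        [np.ones_like(y)] + [(cl == c).astype(float) for c in others]
    )
    res = sm.Logit(y, X).fit(disp=0, method="newton", tol=1e-12, maxiter=200)
    out = []
    for pos, c in enumerate(others, start=1):
        out.append(
            _wald(float(res.params[pos]), float(res.bse[pos]),
                  (c, reference), Method.LOGISTIC)
        )
    return out


# ---------------------------------------------------------------------------
# Random-intercept logistic regression via adaptive Gauss-Hermite quadrature
# ---------------------------------------------------------------------------


class _MixedLogitData:
    """Clustered design padded to (n_clusters, max_cluster_size) for vector ops."""

    def __init__(self, y: np.ndarray, X: np.ndarray, groups: np.ndarray):
        uniq, idx = np.unique(groups, return_inverse=True)
        self.n_groups = len(uniq)
        sizes = np.bincount(idx)
        M = sizes.max()
        G = self.n_groups
        self.y = np.zeros((G, M))
        self.mask = np.zeros((G, M), dtype=bool)
        self.row = np.zeros((G, M), dtype=np.int64)
        fill = np.zeros(G, dtype=np.int64)
        for i, g in enumerate(idx):
            j = fill[g]
            self.y[g, j] = y[i]
            self.mask[g, j] = True
            self.row[g, j] = i
            fill[g] += 1
        self.X = X

    def eta(self, beta: np.ndarray) -> np.ndarray:
        e = self.X @ beta
        out = np.zeros_like(self.y)
        out[self.mask] = e[self.row[self.mask]]
        return out


def _cluster_loglik_sd0(data: _MixedLogitData, beta: np.ndarray) -> float:
    eta = data.eta(beta)
    ll = data.y * eta - np.log1p(np.exp(-np.abs(eta))) - np.maximum(eta, 0.0)
    return float(ll[data.mask].sum())


def _mixed_loglik(data: _MixedLogitData, beta: np.ndarray, sd: float,
                  nodes: np.ndarray, weights: np.ndarray) -> float:
    """Marginal log-likelihood by per-cluster adaptive Gauss-Hermite quadrature."""
    if sd == 0.0:
        return _cluster_loglik_sd0(data, beta)
    eta = data.eta(beta)                       # (G, M)
    y, mask = data.y, data.mask
    var = sd * sd

    def cond_ll(u):  # u: (G,) or (G, Q); conditional loglik per cluster
        if u.ndim == 1:
            z = eta + u[:, None]
            ll = y * z - np.log1p(np.exp(-np.abs(z))) - np.maximum(z, 0.0)
            return np.where(mask, ll, 0.0).sum(axis=1)
        z = eta[:, None, :] + u[:, :, None]    # (G, Q, M)
        ll = y[:, None, :] * z - np.log1p(np.exp(-np.abs(z))) - np.maximum(z, 0.0)
        return np.where(mask[:, None, :], ll, 0.0).sum(axis=2)

    # Laplace step: find the mode of h(u) = cond_ll(u) - u^2 / (2 var)
    u = np.zeros(data.n_groups)
    for _ in range(50):
        z = eta + u[:, None]
        mu = expit(z)
        grad = np.where(mask, y - mu, 0.0).sum(axis=1) - u / var
        hess = -np.where(mask, mu * (1 - mu), 0.0).sum(axis=1) - 1.0 / var
        step = grad / hess
        u_new = u - step
        u = u_new
        if np.max(np.abs(step)) < 1e-10:
            break
    z = eta + u[:, None]
    mu = expit(z)
    hess = -np.where(mask, mu * (1 - mu), 0.0).sum(axis=1) - 1.0 / var
    tau = 1.0 / np.sqrt(-hess)                 # (G,)

    # integral: \int exp(cond_ll(u)) N(u; 0, var) du, nodes centred at the mode
    U = u[:, None] + np.sqrt(2.0) * tau[:, None] * nodes[None, :]   # (G, Q)
    log_phi = -0.5 * U * U / var - 0.5 * np.log(2.0 * np.pi * var)
    log_terms = (
        np.log(weights)[None, :]
        + nodes[None, :] ** 2
        + cond_ll(U)
        + log_phi
        + 0.5 * np.log(2.0) + np.log(tau)[:, None]
    )
    return float(logsumexp(log_terms, axis=1).sum())


def _numerical_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    n = len(x)
    H = np.zeros((n, n))
    steps = h * np.maximum(1.0, np.abs(x))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = steps[i]
            ej = np.zeros(n); ej[j] = steps[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
    return H


_LOG_SD_MIN, _LOG_SD_MAX = np.log(1e-6), np.log(50.0)


def mixed_logistic(
    outcome: Sequence[bool],
    class_label: Sequence,
    participant_id: Sequence,
    reference,
    n_nodes: int = 15,
    fix_sd: float | None = None,
) -> list[AssociationResult]:
    """Random-intercept logistic regression of the outcome on latent class.

    Maximum likelihood over fixed effects and the random-intercept standard
    deviation, integrating over the participant intercepts with per-cluster
    adaptive Gauss-Hermite quadrature (``n_nodes`` nodes).  ``fix_sd=0``
    constrains the variance component to zero, in which case the fit reduces
    exactly to the plain logit.
    """
    y = np.asarray(outcome, dtype=float)
    cl = np.asarray(class_label)
    groups = np.asarray(participant_id)
    if len(set(groups.tolist())) < 2:
        raise ValueError("mixed_logistic requires at least 2 participants")
    present = _check_classes(y.astype(bool), cl, reference)
    others = [c for c in present if c != reference]
    X = np.column_stack(
        [np.ones_like(y)] + [(cl == c).astype(float) for c in others]
    )
    data = _MixedLogitData(y, X, groups)
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    p = X.shape[1]

    beta0 = sm.Logit(y, X).fit(disp=0).params

    if fix_sd is not None:
        if fix_sd == 0.0:
            def negll(beta):
                return -_cluster_loglik_sd0(data, beta)
        else:
            def negll(beta):
                return -_mixed_loglik(data, beta, fix_sd, nodes, weights)
        res = optimize.minimize(negll, beta0, method="BFGS",
                                options={"gtol": 1e-10, "maxiter": 500})
        theta = res.x
        sd_hat = float(fix_sd)
        H = _numerical_hessian(negll, theta)
        free = np.arange(p)
    else:
        def negll_full(theta):
            beta, log_sd = theta[:p], theta[p]
            return -_mixed_loglik(data, beta, float(np.exp(log_sd)), nodes, weights)

        x0 = np.append(beta0, np.log(0.5))
        res = optimize.minimize(
            negll_full, x0, method="L-BFGS-B",
            bounds=[(None, None)] * p + [(_LOG_SD_MIN, _LOG_SD_MAX)],
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8},
        )
        theta = res.x
        sd_hat = float(np.exp(theta[p]))
        H = _numerical_hessian(negll_full, theta)
        free = np.arange(p + 1)

    converged = bool(res.success)
    # Wald covariance of the fixed effects from the observed information;
    # fall back to the beta block if the full matrix is ill-conditioned
    # (e.g. variance component at its boundary).
    cov = None
    try:
        cov = np.linalg.inv(H[np.ix_(free, free)])
        if not np.all(np.isfinite(np.diag(cov))) or np.any(np.diag(cov)[:p] <= 0):
            cov = None
    except np.linalg.LinAlgError:
        cov = None
    if cov is None:
        Hb = H[:p, :p]
        cov = np.linalg.pinv(Hb)

    out = []
    for pos, c in enumerate(others, start=1):
        se = float(np.sqrt(max(cov[pos, pos], 0.0)))
        out.append(
            _wald(float(theta[pos]), se, (c, reference), Method.MIXED_LOGISTIC,
                  sd=sd_hat, converged=converged)
        )
    return out
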