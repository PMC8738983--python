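"""Latent class analysis for categorical event indicators.

The model is a finite mixture of products of multinomials: event i belongs to
an unobserved class k with probability pi_k, and given the class its J
categorical indicators are independent, indicator j taking level c with
probability rho_jkc.  Estimation is by multi-start EM; model choice uses AIC,
BIC, and the relative-entropy classification diagnostic; events are assigned
to their modal posterior class.

Log-likelihood for N events:

    ll = sum_i log sum_k pi_k prod_j rho_{j,k,c_ij}

Free parameter count: ``K * sum_j (C_j - 1) + (K - 1)``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .indicators import IndicatorMatrix

__all__ = [
    "LCAFit",
    "fit",
    "n_parameters",
    "information_criteria",
    "model_selection",
    "select",
    "assign",
    "align_classes",
]


@dataclass
class LCAFit:
    """A fitted latent class model (best start of a multi-start EM run)."""

    n_classes: int
    mixing: np.ndarray                      # (K,)
    response: dict[str, np.ndarray]         # column -> (K, C_j)
    loglik: float
    posterior: np.ndarray                   # (N, K), rows sum to 1
    n_params: int
    n_iter: int
    converged: bool
    seed: int | None
    event_ids: list[str] = field(default_factory=list)
    levels: dict[str, list[str]] = field(default_factory=dict)
    loglik_trace: np.ndarray | None = None  # per-iteration loglik of the best start
    start_logliks: np.ndarray | None = None

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(self.response)


def n_parameters(K: int, level_counts: Sequence[int]) -> int:
    """Free parameters of a K-class model with the given level counts."""
    return K * sum(c - 1 for c in level_counts) + (K - 1)


def _pattern_collapse(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Collapse duplicate response patterns; returns (unique, counts, inverse)."""
    uniq, inverse, counts = np.unique(
        codes, axis=0, return_inverse=True, return_counts=True
    )
    return uniq, counts.astype(float), inverse


def _log_component_matrix(
    uniq: np.ndarray, log_rho: list[np.ndarray]
) -> np.ndarray:
    """(U, K) matrix of log P(pattern_u | class k)."""
    U = uniq.shape[0]
    K = log_rho[0].shape[0]
    out = np.zeros((U, K))
    for j, lr in enumerate(log_rho):
        out += lr[:, uniq[:, j]].T
    return out


def _em_single(
    uniq: np.ndarray,
    counts: np.ndarray,
    level_counts: Sequence[int],
    K: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    ridge: float,
) -> tuple[np.ndarray, list[np.ndarray], float, np.ndarray, int, bool]:
    """One EM run from a Dirichlet(1,...,1) random start.

    Returns (pi, rho_list, loglik, trace, n_iter, converged).  The
    log-likelihood is checked to be nondecreasing at every iteration.
    """
    N = counts.sum()
    pi = rng.dirichlet(np.ones(K))
    rho = [rng.dirichlet(np.ones(c), size=K) for c in level_counts]

    trace = []
    prev = -np.inf
    converged = False
    it = 0
    with np.errstate(divide="ignore"):
        for it in range(1, max_iter + 1):
            log_rho = [np.log(r) for r in rho]
            log_comp = _log_component_matrix(uniq, log_rho) + np.log(pi)[None, :]
            row_ll = logsumexp(log_comp, axis=1)
            ll = float(counts @ row_ll)
            if ll < prev - 1e-8 * max(1.0, abs(prev)):
                raise RuntimeError(
                    f"EM log-likelihood decreased ({prev} -> {ll}); numerical fault"
                )
            trace.append(ll)
            if abs(ll - prev) < tol:
                converged = True
                break
            prev = ll
            # E-step: posterior over classes per unique pattern
            post = np.exp(log_comp - row_ll[:, None])
            w = post * counts[:, None]            # (U, K) weighted memberships
            class_tot = w.sum(axis=0)             # (K,)
            # M-step
            pi = class_tot / N
            for j, c in enumerate(level_counts):
                num = np.zeros((K, c))
                np.add.at(num.T, uniq[:, j], w)   # num[k, c] = sum of w over patterns
                if ridge:
                    num = num + ridge
                denom = num.sum(axis=1, keepdims=True)
                rho[j] = num / denom

    with np.errstate(divide="ignore"):
        log_rho = [np.log(r) for r in rho]
        log_comp = _log_component_matrix(uniq, log_rho) + np.log(pi)[None, :]
    row_ll = logsumexp(log_comp, axis=1)
    ll = float(counts @ row_ll)
    return pi, rho, ll, np.asarray(trace), it, converged


def fit(
    matrix: IndicatorMatrix,
    K: int,
    n_starts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-10,
    seed: int | None = None,
    ridge: float = 0.0,
) -> LCAFit:
    """Fit a K-class model by EM from ``n_starts`` random initializations.

    The start with the largest final log-likelihood is returned.  Response
    probabilities may legitimately converge to 0/1 (no smoothing by default;
    pass ``ridge`` ~1e-6 to add a tiny pseudocount for numerical stability).
    """
    N = matrix.n_events
    if N == 0:
        raise ValueError("indicator matrix is empty")
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > N:
        raise ValueError(f"K={K} exceeds the number of events N={N}")

    uniq, counts, inverse = _pattern_collapse(matrix.codes)
    level_counts = matrix.level_counts

    ss = np.random.SeedSequence(seed)
    child_rngs = [np.random.default_rng(s) for s in ss.spawn(n_starts)]

    best = None
    start_lls = np.empty(n_starts)
    for s, rng in enumerate(child_rngs):
        pi, rho, ll, trace, n_iter, converged = _em_single(
            uniq, counts, level_counts, K, rng, max_iter, tol, ridge
        )
        start_lls[s] = ll
        if best is None or ll > best[2]:
            best = (pi, rho, ll, trace, n_iter, converged)

    pi, rho, ll, trace, n_iter, converged = best
    with np.errstate(divide="ignore"):
        log_rho = [np.log(r) for r in rho]
        log_comp = _log_component_matrix(uniq, log_rho) + np.log(pi)[None, :]
    post_uniq = np.exp(log_comp - logsumexp(log_comp, axis=1)[:, None])
    posterior = post_uniq[inverse]

    return LCAFit(
        n_classes=K,
        mixing=pi,
        response={c: rho[j] for j, c in enumerate(matrix.columns)},
        loglik=ll,
        posterior=posterior,
        n_params=n_parameters(K, level_counts),
        n_iter=n_iter,
        converged=converged,
        seed=seed,
        event_ids=list(matrix.event_ids),
        levels={c: list(matrix.levels[c]) for c in matrix.columns},
        loglik_trace=trace,
        start_logliks=start_lls,
    )


def information_criteria(fit: LCAFit, N: int) -> tuple[float, float, float]:
    """(AIC, BIC, relative entropy) for a fitted model.

    ``AIC = -2 ll + 2 p`` and ``BIC = -2 ll + p ln N`` with N the number of
    events.  The entropy diagnostic is ``1 - E / (N ln K)`` where E is the
    total Shannon entropy of the posterior memberships; it equals 1 when
    classification is perfect and is defined as 1.00 for the one-class model.
    """
    aic = -2.0 * fit.loglik + 2.0 * fit.n_params
    bic = -2.0 * fit.loglik + fit.n_params * np.log(N)
    K = fit.n_classes
    if K == 1:
        entropy = 1.0
    else:
        p = fit.posterior
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log(p), 0.0)
        E = float(-plogp.sum())
        entropy = 1.0 - E / (N * np.log(K))
    return float(aic), float(bic), float(entropy)


def model_selection(
    matrix: IndicatorMatrix,
    k_min: int = 1,
    k_max: int = 5,
    n_starts: int = 10,
    max_iter: int = 500,
    tol: float = 1e-10,
    seed: int | None = None,
    ridge: float = 0.0,
) -> tuple[pd.DataFrame, dict[int, LCAFit]]:
    """Fit all class counts in ``[k_min, k_max]`` and tabulate fit statistics."""
    rows = []
    fits: dict[int, LCAFit] = {}
    for K in range(k_min, k_max + 1):
        f = fit(matrix, K, n_starts=n_starts, max_iter=max_iter, tol=tol,
                seed=None if seed is None else seed + K, ridge=ridge)
        aic, bic, ent = information_criteria(f, matrix.n_events)
        fits[K] = f
        rows.append(
            {"K": K, "loglik": f.loglik, "n_params": f.n_params,
             "AIC": aic, "BIC": bic, "entropy": ent, "converged": f.converged}
        )
    return pd.DataFrame(rows), fits


def select(table: pd.DataFrame) -> int:
    """Chosen class count: argmin BIC, ties broken toward the smaller K."""
    if len(table) == 0:
        raise ValueError("empty model selection table")
    t = table.sort_values(["BIC", "K"], kind="stable")
    return int(t.iloc[0]["K"])


def assign(fit: LCAFit) -> dict[str, int]:
    """Modal posterior class per event (1-based), ties to the lowest index."""
    hard = fit.posterior.argmax(axis=1) + 1  # argmax takes the first maximum
    ids = fit.event_ids or [str(i) for i in range(fit.posterior.shape[0])]
    return {eid: int(k) for eid, k in zip(ids, hard)}


def align_classes(
    fit: LCAFit, reference_response: Mapping[str, np.ndarray]
) -> tuple[int, ...]:
    """Resolve label switching against a reference response structure.

    Returns the permutation ``perm`` (0-based) minimizing the total absolute
    difference between fitted and reference response probabilities, such that
    fitted class ``perm[r]`` corresponds to reference class ``r``.  Exhaustive
    over K! (intended for K <= 6).
    """
    K = fit.n_classes
    cols = list(fit.response)
    for c in cols:
        ref = np.asarray(reference_response[c])
        if ref.shape != fit.response[c].shape:
            raise ValueError(
                f"reference response for {c!r} has shape {ref.shape}, "
                f"expected {fit.response[c].shape}"
            )
    # cost[r, f] = total |rho_fit[f] - rho_ref[r]| over indicators and levels
    cost = np.zeros((K, K))
    for c in cols:
        ref = np.asarray(reference_response[c])
        fitted = fit.response[c]
        cost += np.abs(ref[:, None, :] - fitted[None, :, :]).sum(axis=2)
    best_perm, best_cost = None, np.inf
    for perm in itertools.permutations(range(K)):
        total = cost[np.arange(K), perm].sum()
        if total < best_cost - 1e-15:
            best_cost = total
            best_perm = perm
    return tuple(best_perm)
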