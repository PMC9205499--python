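"""Markov random field prior over gene risk labels and its empirical-Bayes fit.

Model
-----
Latent labels S_i in {-1, +1} (risk / non-risk) on a gene network follow a
nearest-neighbor Gibbs measure

    P(S | h, tau0, tau1) propto exp{ h * #{S_i = +1}
        + tau0 * sum_{edges <i,j>} (w_i + w_j) I(S_i = -1) I(S_j = -1)
        + tau1 * sum_{edges <i,j>} (w_i + w_j) I(S_i = +1) I(S_j = +1) },

with w_i = sqrt(d_i) (or 0 in no-network mode).  The full conditional of one
label is logistic:

    logit P(S_i = +1 | S_Ni) = h + tau1 * X_i1 - tau0 * X_i0,

where X_i1 = sum_{k in N_i} (w_i + w_k) I(S_k = +1) and X_i0 is the analogous
sum over -1 neighbors.  Estimation maximizes the pseudo conditional
likelihood (PCLK): iterate (a) ridge-penalized logistic Newton-Raphson for
(h, tau0, tau1) given the labels, (b) one ICM sweep for the labels given the
parameters, (c) the closed-form relative-risk update
gamma = sum_{S_i=1} Y_i / sum_{S_i=1} 2*N*mu_i, until the labels and
parameters stabilize.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, log_expit

from . import _kernels
from .dnv_data import CountParams, GeneTable, log_emission_pair, pvalue_init_states
from .graph_io import GeneNetwork

__all__ = [
    "MrfParams",
    "FitResult",
    "ThetaFitError",
    "compute_covariates",
    "log_prior_unnormalized",
    "conditional_prob",
    "conditional_probs",
    "fit_theta0",
    "icm_update",
    "estimate_gamma",
    "pclk",
    "fit",
]

DEFAULT_RIDGE = 0.1
DEFAULT_TOL = 1e-4
DEFAULT_MAX_ITER = 100
DEFAULT_GAMMA_INIT = math.exp(3.0)


@dataclass(frozen=True)
class MrfParams:
    """Hyperparameters of the network prior.

    ``h`` sets the marginal log-odds of association for an isolated gene;
    ``tau0``/``tau1`` weight edges between pairs of non-associated /
    associated genes (nonnegative under the intended interpretation as
    affinities, though an unconstrained fit may return small negatives).
    """

    h: float
    tau0: float
    tau1: float

    def __post_init__(self):
        for name in ("h", "tau0", "tau1"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def as_tuple(self):
        return (self.h, self.tau0, self.tau1)


class ThetaFitError(RuntimeError):
    """Newton-Raphson for the prior hyperparameters failed to converge.

    Carries the last iterate and the gradient norm; typically raised for
    separable label configurations with no ridge penalty.
    """

    def __init__(self, message, last_params=None, grad_norm=None):
        super().__init__(message)
        self.last_params = last_params
        self.grad_norm = grad_norm


def _check_aligned(S, net: GeneNetwork):
    S = np.asarray(S)
    if S.shape != (net.n_nodes,):
        raise ValueError(
            f"label vector length {S.shape} does not match network size {net.n_nodes}"
        )
    if not np.all(np.isin(S, (-1, 1))):
        raise ValueError("labels must be +1 or -1")
    return S.astype(np.int64)


def _segment_sum(values: np.ndarray, indptr: np.ndarray) -> np.ndarray:
    c = np.concatenate(([0.0], np.cumsum(values)))
    return c[indptr[1:]] - c[indptr[:-1]]


def compute_covariates(S, net: GeneNetwork):
    """Neighbor covariates (X_i1, X_i0) for every gene.

    X_i1 = w_i * #{+1 neighbors} + sum of w_k over +1 neighbors, and X_i0 the
    same for -1 neighbors; X_i1 + X_i0 = w_i*d_i + sum_{k in N_i} w_k.
    """
    S = _check_aligned(S, net)
    plus = (S[net.indices] == 1).astype(float)
    w_nbr = net.weights[net.indices]
    x1 = net.weights * _segment_sum(plus, net.indptr) + _segment_sum(w_nbr * plus, net.indptr)
    x0 = net.weights * _segment_sum(1.0 - plus, net.indptr) + _segment_sum(
        w_nbr * (1.0 - plus), net.indptr
    )
    return x1, x0


def log_prior_unnormalized(S, net: GeneNetwork, params: MrfParams) -> float:
    """Log of the unnormalized Gibbs prior at label configuration S."""
    S = _check_aligned(S, net)
    u, v = net.edge_arrays()
    wsum = net.weights[u] + net.weights[v]
    both_plus = (S[u] == 1) & (S[v] == 1)
    both_minus = (S[u] == -1) & (S[v] == -1)
    return float(
        params.h * np.count_nonzero(S == 1)
        + params.tau0 * wsum[both_minus].sum()
        + params.tau1 * wsum[both_plus].sum()
    )


def conditional_probs(S, net: GeneNetwork, params: MrfParams) -> np.ndarray:
    """P(S_i = +1 | neighbor labels) for every gene (isolated genes: sigmoid(h))."""
    x1, x0 = compute_covariates(S, net)
    return expit(params.h + params.tau1 * x1 - params.tau0 * x0)


def conditional_prob(i: int, S, net: GeneNetwork, params: MrfParams) -> float:
    """P(S_i = +1 | neighbor labels) for gene index ``i``."""
    return float(conditional_probs(S, net, params)[i])


def fit_theta0(
    S,
    net: GeneNetwork,
    ridge_lambda: float = DEFAULT_RIDGE,
    *,
    nonneg: bool = True,
    fix_tau0: float | None = None,
    fix_tau1: float | None = None,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> MrfParams:
    """Maximize sum_i log P(S_i | S_Ni, theta0) - lambda*(h^2 + tau0^2 + tau1^2).

    Newton-Raphson on the logistic regression with design (1, X_i1, -X_i0)
    and response I(S_i = +1).  With ``nonneg`` (default) tau0 and tau1 are
    projected to >= 0 after each step.  Covariate columns that are
    identically zero (no-network mode, or no neighbor of the relevant sign
    anywhere) are dropped and their tau is reported as 0.  ``fix_tau0`` /
    ``fix_tau1`` pin a tau and move its contribution into an offset.
    """
    if ridge_lambda < 0:
        raise ValueError("ridge penalty must be >= 0")
    S = _check_aligned(S, net)
    x1, x0 = compute_covariates(S, net)
    y = (S == 1).astype(float)
    n = y.size
    if n == 0:
        raise ValueError("empty label vector")

    offset = np.zeros(n)
    cols = [np.ones(n)]
    names = ["h"]
    if fix_tau1 is not None:
        offset = offset + fix_tau1 * x1
    elif np.any(x1 != 0.0):
        cols.append(x1)
        names.append("tau1")
    if fix_tau0 is not None:
        offset = offset - fix_tau0 * x0
    elif np.any(x0 != 0.0):
        cols.append(-x0)
        names.append("tau0")
    X = np.column_stack(cols)
    k = X.shape[1]
    tau_idx = [j for j, nm in enumerate(names) if nm in ("tau0", "tau1")]

    lam = float(ridge_lambda)
    sgn = np.where(y == 1.0, 1.0, -1.0)

    def objective(t):
        eta = X @ t + offset
        return float(log_expit(sgn * eta).sum() - lam * (t @ t))

    def project(t):
        if nonneg:
            t = t.copy()
            for j in tau_idx:
                if t[j] < 0.0:
                    t[j] = 0.0
        return t

    def grad_and_hess(t):
        eta = X @ t + offset
        p = expit(eta)
        g = X.T @ (y - p) - 2.0 * lam * t
        W = np.clip(p * (1.0 - p), 1e-12, None)
        H = (X.T * W) @ X + 2.0 * lam * np.eye(k)
        return g, H

    def projected_grad(t, g):
        pg = g.copy()
        if nonneg:
            for j in tau_idx:
                if t[j] <= 0.0 and g[j] < 0.0:
                    pg[j] = 0.0
        return pg

    gtol = tol * max(1.0, float(n))
    theta = np.zeros(k)
    converged = False
    f_cur = objective(theta)
    gnorm = np.inf
    for _ in range(max_iter):
        grad, H = grad_and_hess(theta)
        pgrad = projected_grad(theta, grad)
        gnorm = float(np.linalg.norm(pgrad))
        if gnorm < gtol:
            converged = True
            break
        # active-set Newton: clamped taus with inward gradient stay fixed
        free = np.ones(k, dtype=bool)
        if nonneg:
            for j in tau_idx:
                if theta[j] <= 0.0 and grad[j] < 0.0:
                    free[j] = False
        step = np.zeros(k)
        try:
            step[free] = np.linalg.solve(H[np.ix_(free, free)], grad[free])
        except np.linalg.LinAlgError:
            raise ThetaFitError(
                "singular Hessian in Newton-Raphson (labels may be separable; "
                "use a positive ridge penalty)",
                last_params=_theta_to_params(theta, names, fix_tau0, fix_tau1),
                grad_norm=gnorm,
            ) from None
        # backtracking line search on the projected step
        theta_new, f_new = theta, f_cur
        t_step = 1.0
        while t_step >= 1e-12:
            cand = project(theta + t_step * step)
            f_cand = objective(cand)
            if f_cand > f_cur:
                theta_new, f_new = cand, f_cand
                break
            t_step *= 0.5
        if f_new <= f_cur:
            break  # no ascent possible; stationarity checked below
        theta, f_cur = theta_new, f_new
        if not np.all(np.isfinite(theta)) or np.linalg.norm(theta) > 1e10:
            raise ThetaFitError(
                "parameter divergence in Newton-Raphson (labels may be "
                "separable; use a positive ridge penalty)",
                last_params=_theta_to_params(theta, names, fix_tau0, fix_tau1),
                grad_norm=gnorm,
            )
    if lam == 0.0:
        # with no ridge the MLE exists only for non-separated labels; under
        # separation the fitted probabilities converge to the labels
        p = expit(X @ theta + offset)
        if np.all(np.abs(y - p) < 1e-6):
            raise ThetaFitError(
                "labels are separable: the unpenalized maximum does not "
                "exist (use a positive ridge penalty)",
                last_params=_theta_to_params(theta, names, fix_tau0, fix_tau1),
                grad_norm=gnorm,
            )
    if not converged:
        grad, _ = grad_and_hess(theta)
        gnorm = float(np.linalg.norm(projected_grad(theta, grad)))
        # line-search stagnation slightly above gtol is the float-precision
        # floor of the objective, not a modeling failure
        if gnorm >= max(gtol, 1e-3 * math.sqrt(max(1.0, float(n)))):
            raise ThetaFitError(
                f"Newton-Raphson did not converge in {max_iter} iterations "
                f"(projected gradient norm {gnorm:.3g})",
                last_params=_theta_to_params(theta, names, fix_tau0, fix_tau1),
                grad_norm=gnorm,
            )
    return _theta_to_params(theta, names, fix_tau0, fix_tau1)


def _theta_to_params(theta, names, fix_tau0, fix_tau1) -> MrfParams:
    d = dict(zip(names, theta))
    h = d.get("h", 0.0)
    tau1 = fix_tau1 if fix_tau1 is not None else d.get("tau1", 0.0)
    tau0 = fix_tau0 if fix_tau0 is not None else d.get("tau0", 0.0)
    return MrfParams(h=float(h), tau0=float(tau0), tau1=float(tau1))


def icm_update(
    S,
    net: GeneNetwork,
    params: MrfParams,
    counts: CountParams,
    table: GeneTable,
) -> np.ndarray:
    """One ICM sweep over genes in lexicographic order, immediate updates.

    Each gene is set to the state maximizing
    f(Y_i | S_i) * P(S_i | S_Ni) * prod_{k in N_i} P(S_k | S_i, S_{Nk \\ i});
    ties resolve to -1.
    """
    S = _check_aligned(S, net).copy()
    le_minus, le_plus = log_emission_pair(table, counts.gamma)
    _kernels.icm_sweep(
        net.indptr,
        net.indices,
        net.weights,
        le_minus,
        le_plus,
        params.h,
        params.tau0,
        params.tau1,
        S,
    )
    return S


def estimate_gamma(
    S, table: GeneTable, fallback_gamma: float = DEFAULT_GAMMA_INIT
) -> tuple[CountParams, bool]:
    """Closed-form relative risk given labels:
    gamma = sum_{S_i=1} Y_i / sum_{S_i=1} 2*N*mu_i, clipped below at 1.

    Returns (params, degenerate): degenerate is True when no gene is labeled
    +1, in which case ``fallback_gamma`` is returned unchanged.
    """
    S = np.asarray(S)
    mask = S == 1
    if not np.any(mask):
        return CountParams(gamma=float(fallback_gamma)), True
    raw = float(table.counts[mask].sum()) / float(table.null_rates()[mask].sum())
    return CountParams(gamma=max(1.0, raw)), False


def pclk(S, net: GeneNetwork, params: MrfParams, counts: CountParams, table: GeneTable) -> float:
    """Log pseudo conditional likelihood:
    sum_i [ log f(Y_i | S_i, gamma) + log P(S_i | S_Ni, theta0) ]."""
    S = _check_aligned(S, net)
    le_minus, le_plus = log_emission_pair(table, counts.gamma)
    emit = np.where(S == 1, le_plus, le_minus)
    x1, x0 = compute_covariates(S, net)
    eta = params.h + params.tau1 * x1 - params.tau0 * x0
    return float(emit.sum() + log_expit(S * eta).sum())


@dataclass(frozen=True)
class FitResult:
    """Outcome of the empirical-Bayes estimation loop."""

    params: MrfParams
    counts: CountParams
    states: np.ndarray
    n_iter: int
    converged: bool
    pclk_trace: np.ndarray
    warnings: tuple
    gamma_degenerate: bool


def _initial_states(table, net, init, init_seeds, init_p_cut, rng):
    if isinstance(init, np.ndarray) or isinstance(init, (list, tuple)):
        return _check_aligned(np.asarray(init, dtype=np.int64), net)
    if init == "pvalue":
        return pvalue_init_states(table, p_cut=init_p_cut)
    if init == "seeds":
        if not init_seeds:
            raise ValueError("init='seeds' requires a nonempty seed-gene list")
        seed_set = set(init_seeds)
        return np.array([1 if g in seed_set else -1 for g in table.genes], dtype=np.int64)
    if init == "random":
        # sparse random start: each gene +1 with probability 0.05
        return np.where(rng.random(table.n_genes) < 0.05, 1, -1).astype(np.int64)
    raise ValueError(f"unknown init mode {init!r}")


def fit(
    table: GeneTable,
    net: GeneNetwork,
    *,
    lambda_ridge: float = DEFAULT_RIDGE,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    init="pvalue",
    init_seeds=None,
    init_p_cut: float = 0.01,
    n_random_starts: int = 1,
    gamma_init: float = DEFAULT_GAMMA_INIT,
    fix_tau0: float | None = None,
    fix_tau1: float | None = None,
    nonneg: bool = True,
    seed: int | None = None,
) -> FitResult:
    """Empirical-Bayes estimation of (h, tau0, tau1), gamma and the labels.

    Iterates: penalized logistic fit for the prior hyperparameters given the
    labels, one ICM sweep for the labels, then the closed-form gamma update;
    stops when the labels are unchanged over a sweep and the maximum relative
    change in (h, tau0, tau1, gamma) is below ``tol``, or after ``max_iter``
    iterations (then ``converged`` is False).  With ``init='random'`` and
    ``n_random_starts > 1`` the start with the best final PCLK is kept.
    """
    if tuple(table.genes) != tuple(net.nodes):
        raise ValueError(
            "gene table and network are not aligned; use restrict_to_genes / "
            "GeneTable.restrict first"
        )
    rng = np.random.default_rng(seed)
    n_starts = n_random_starts if init == "random" else 1
    best: FitResult | None = None
    for _ in range(n_starts):
        result = _fit_single(
            table,
            net,
            _initial_states(table, net, init, init_seeds, init_p_cut, rng),
            lambda_ridge=lambda_ridge,
            tol=tol,
            max_iter=max_iter,
            gamma_init=gamma_init,
            fix_tau0=fix_tau0,
            fix_tau1=fix_tau1,
            nonneg=nonneg,
        )
        if best is None or result.pclk_trace[-1] > best.pclk_trace[-1]:
            best = result
    return best


def _fit_single(
    table,
    net,
    S0,
    *,
    lambda_ridge,
    tol,
    max_iter,
    gamma_init,
    fix_tau0,
    fix_tau1,
    nonneg,
) -> FitResult:
    S = S0.copy()
    gamma = CountParams(gamma=float(gamma_init))
    prev_vec = None
    trace = []
    warns = []
    converged = False
    ever_nonnull = bool(np.any(S == 1))
    params = MrfParams(0.0, 0.0, 0.0)
    gamma_degenerate = False
    it = 0
    for it in range(1, max_iter + 1):
        params = fit_theta0(
            S,
            net,
            lambda_ridge,
            nonneg=nonneg,
            fix_tau0=fix_tau0,
            fix_tau1=fix_tau1,
        )
        S_new = icm_update(S, net, params, gamma, table)
        gamma_new, degenerate = estimate_gamma(S_new, table, fallback_gamma=gamma.gamma)
        gamma_degenerate = degenerate
        trace.append(pclk(S_new, net, params, gamma_new, table))
        ever_nonnull = ever_nonnull or bool(np.any(S_new == 1))
        vec = np.array([params.h, params.tau0, params.tau1, gamma_new.gamma])
        s_stable = bool(np.array_equal(S_new, S))
        if prev_vec is not None:
            rel = np.max(np.abs(vec - prev_vec) / np.maximum(1.0, np.abs(prev_vec)))
        else:
            rel = np.inf
        S = S_new
        gamma = gamma_new
        prev_vec = vec
        if s_stable and rel < tol:
            converged = True
            break
    if not ever_nonnull:
        warns.append(
            "weak signal: all genes remained labeled non-risk at every "
            "iteration; estimates may be unreliable"
        )
    if gamma_degenerate:
        warns.append("no risk-labeled gene at the final iteration; gamma not updated")
    if not converged:
        warns.append(f"estimation did not converge within {max_iter} iterations")
    for w in warns:
        warnings.warn(w, stacklevel=3)
    return FitResult(
        params=params,
        counts=gamma,
        states=S,
        n_iter=it,
        converged=converged,
        pclk_trace=np.asarray(trace),
        warnings=tuple(warns),
        gamma_degenerate=gamma_degenerate,
    )
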