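"""Marginal maximum-likelihood estimation for the multi-group binary 2PL.

The latent ability is integrated out by fixed Gauss–Hermite quadrature.
Three model levels are supported:

configural
    every item's loading and threshold free in every group; factor means
    and variances fixed at 0 and 1 (groups are then independent and are
    fitted one at a time);
metric
    loadings equal across groups, thresholds free, factor variances free
    in groups 2..G (reference variance 1), factor means fixed at 0;
scalar
    loadings and thresholds equal across groups, factor means and
    variances free in groups 2..G (reference fixed at 0/1).

These identification conventions make the free-parameter *differences*
between levels equal to (G-1)(P-1) (metric vs configural) and
2(G-1)(P-1) (scalar vs configural), the degrees of freedom of the
corresponding likelihood-ratio tests.

Missing responses (NaN) simply contribute nothing to their item's
likelihood term (full-information ML under missing-at-random).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, Hashable, List, Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, log_ndtr, logsumexp, roots_hermite
from scipy.stats import chi2

from .data import ResponseData, ResponseDataError
from .model_core import LINKS, DomainError

__all__ = [
    "QuadratureSpec",
    "GroupFit",
    "ConfiguralFit",
    "ConstrainedFit",
    "LRTResult",
    "SEResult",
    "BoundaryWarning",
    "ConvergenceError",
    "NonPositiveDefiniteError",
    "marginal_loglik",
    "fit_group_2pl",
    "fit_configural",
    "fit_invariance_model",
    "free_parameter_count",
    "likelihood_ratio_test",
    "observed_information_se",
]

#: Box bounds on loadings and thresholds, guarding quasi-separated items.
PARAM_BOUND = 25.0
_LOGPSI_BOUND = 5.0
_ALPHA_BOUND = 10.0

_LEVEL_ORDER = {"scalar": 0, "metric": 1, "configural": 2}


class BoundaryWarning(UserWarning):
    """An item column is constant (all 0 or all 1) within a group."""


class ConvergenceError(RuntimeError):
    """Optimizer failed; carries the iteration trace in ``trace``."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


class NonPositiveDefiniteError(RuntimeError):
    """Observed information is not positive definite."""


@dataclass(frozen=True)
class QuadratureSpec:
    """Gauss–Hermite integration settings for the latent ability."""

    n_nodes: int = 21
    adaptive: bool = False

    def __post_init__(self):
        if self.n_nodes < 5:
            raise DomainError("quadrature needs at least 5 nodes")

    def standard_normal_nodes(self):
        """Nodes and log-weights integrating against N(0, 1)."""
        if self.adaptive:
            raise NotImplementedError("adaptive quadrature is not implemented")
        x, w = roots_hermite(self.n_nodes)
        return x * np.sqrt(2.0), np.log(w) - 0.5 * np.log(np.pi)


class _Patterns:
    """Unique response patterns with multiplicities (missing-aware)."""

    def __init__(self, y: np.ndarray):
        y = np.asarray(y, dtype=float)
        if y.ndim != 2:
            raise ResponseDataError("response block must be 2-D")
        code = np.where(np.isnan(y), 2, y).astype(np.int8)
        uniq, counts = np.unique(code, axis=0, return_counts=True)
        self.y = (uniq == 1).astype(float)
        self.mask = (uniq != 2).astype(float)
        self.my = self.mask * self.y
        self.counts = counts.astype(float)
        self.n = int(counts.sum())
        self.n_items = y.shape[1]


def _link_terms(z: np.ndarray, link: str):
    """log P, log(1-P) and the score factors d log P / dz, d log(1-P) / dz."""
    if link == "logit":
        logp1 = -np.logaddexp(0.0, -z)
        logp0 = -np.logaddexp(0.0, z)
        p = expit(z)
        m1 = 1.0 - p
        m0 = -p
    elif link == "probit":
        logp1 = log_ndtr(z)
        logp0 = log_ndtr(-z)
        logpdf = -0.5 * z * z - 0.5 * np.log(2.0 * np.pi)
        m1 = np.exp(logpdf - logp1)
        m0 = -np.exp(logpdf - logp0)
    else:
        raise DomainError(f"unknown link {link!r}; expected one of {LINKS}")
    return logp1, logp0, m1, m0


def _loglik_core(lam, tau, pat: _Patterns, eta, logqw, link, scores: bool = False):
    """Marginal log-likelihood of one group plus score aggregates.

    Returns ``(ll, Gz, S)`` where ``Gz[p, k]`` is the count-weighted sum
    over patterns of posterior-weighted scores with respect to
    ``z[p, k] = lam[p] * eta[k] - tau[p]``, and ``S`` (only when
    ``scores=True``) holds per-pattern scores with respect to
    (lam, tau) as arrays of shape (T, P).
    """
    z = lam[:, None] * eta[None, :] - tau[:, None]  # (P, K)
    logp1, logp0, m1, m0 = _link_terms(z, link)
    logf = pat.my @ logp1 + (pat.mask - pat.my) @ logp0 + logqw[None, :]  # (T, K)
    M = logsumexp(logf, axis=1)
    ll = float(pat.counts @ M)
    R = np.exp(logf - M[:, None])  # posterior quadrature weights per pattern
    A = pat.counts[:, None] * R
    W = pat.my.T @ A  # (P, K)
    V = pat.mask.T @ A
    Gz = W * (m1 - m0) + V * m0
    if not scores:
        return ll, Gz, None
    S = pat.my[:, :, None] * (m1 - m0)[None, :, :] + pat.mask[:, :, None] * m0[None, :, :]
    score_z = np.einsum("tk,tpk->tpk", R, S)  # (T, P, K)
    score_lam = score_z @ eta  # (T, P)
    score_tau = -score_z.sum(axis=2)
    return ll, Gz, (score_lam, score_tau)


def marginal_loglik(
    y: np.ndarray,
    loadings: Sequence[float],
    thresholds: Sequence[float],
    mean: float = 0.0,
    variance: float = 1.0,
    quad: QuadratureSpec = QuadratureSpec(),
    link: str = "logit",
) -> float:
    """Marginal log-likelihood of a response block at fixed parameters.

    The ability distribution is N(mean, variance); integration is by
    Gauss–Hermite quadrature after the change of variable
    ``eta = mean + sqrt(variance) * z``.
    """
    if variance <= 0:
        raise DomainError("variance must be strictly positive")
    pat = _Patterns(np.asarray(y, dtype=float))
    eta0, logqw = quad.standard_normal_nodes()
    eta = mean + np.sqrt(variance) * eta0
    lam = np.asarray(loadings, dtype=float)
    tau = np.asarray(thresholds, dtype=float)
    ll, _, _ = _loglik_core(lam, tau, pat, eta, logqw, link)
    return ll


def _start_values(y: np.ndarray) -> np.ndarray:
    """Per-item logistic regression of the item on the standardized total score."""
    n, p = y.shape
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        score = np.nanmean(y, axis=1)
    score = np.where(np.isfinite(score), score, 0.5)
    sd = score.std()
    zscore = (score - score.mean()) / sd if sd > 0 else np.zeros(n)
    lam0 = np.ones(p)
    tau0 = np.zeros(p)
    for j in range(p):
        obs = ~np.isnan(y[:, j])
        yj = y[obs, j]
        xj = np.column_stack([np.ones(obs.sum()), zscore[obs]])
        beta = np.zeros(2)
        for _ in range(25):
            pr = expit(xj @ beta)
            g = xj.T @ (yj - pr)
            wdiag = np.clip(pr * (1 - pr), 1e-6, None)
            h = xj.T @ (xj * wdiag[:, None])
            try:
                step = np.linalg.solve(h, g)
            except np.linalg.LinAlgError:
                break
            beta += step
            if np.max(np.abs(step)) < 1e-8:
                break
        lam0[j] = float(np.clip(beta[1], 0.2, 4.0))
        tau0[j] = float(np.clip(-beta[0], -4.0, 4.0))
    return np.concatenate([lam0, tau0])


def _fd_hessian(grad_fn: Callable, theta: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    """Central-difference Jacobian of an analytic gradient, symmetrized."""
    n = theta.size
    H = np.empty((n, n))
    for j in range(n):
        h = rel_step * (1.0 + abs(theta[j]))
        tp = theta.copy()
        tm = theta.copy()
        tp[j] += h
        tm[j] -= h
        H[:, j] = (grad_fn(tp) - grad_fn(tm)) / (2.0 * h)
    return 0.5 * (H + H.T)


def _try_covariance(grad_fn, theta):
    H = _fd_hessian(grad_fn, theta)
    try:
        L = np.linalg.cholesky(H)
        identity = np.eye(theta.size)
        inv = np.linalg.solve(L.T, np.linalg.solve(L, identity))
        return 0.5 * (inv + inv.T)
    except np.linalg.LinAlgError:
        return None


@dataclass
class GroupFit:
    """Converged single-group 2PL fit (configural parameterization)."""

    group: Hashable
    items: List[str]
    loadings: np.ndarray
    thresholds: np.ndarray
    loglik: float
    cov: Optional[np.ndarray]
    n: int
    link: str
    quad: QuadratureSpec
    converged: bool
    n_iter: int
    _grad_fn: Optional[Callable] = field(default=None, repr=False, compare=False)
    _score_fn: Optional[Callable] = field(default=None, repr=False, compare=False)

    @property
    def theta(self) -> np.ndarray:
        return np.concatenate([self.loadings, self.thresholds])

    @property
    def n_free(self) -> int:
        return 2 * len(self.items)

    def param_names(self) -> List[str]:
        return [f"lambda[{i}]" for i in self.items] + [f"tau[{i}]" for i in self.items]


def fit_group_2pl(
    y: np.ndarray,
    items: Optional[Sequence[str]] = None,
    quad: QuadratureSpec = QuadratureSpec(),
    link: str = "logit",
    group: Hashable = None,
    start: Optional[np.ndarray] = None,
) -> GroupFit:
    """Fit the 2PL to one group by marginal ML with ability ~ N(0, 1)."""
    y = np.asarray(y, dtype=float)
    if y.ndim != 2 or y.shape[0] < 1 or y.shape[1] < 1:
        raise ResponseDataError("response block must be a non-empty 2-D array")
    p = y.shape[1]
    if items is None:
        items = [f"Y{j + 1}" for j in range(p)]
    items = [str(i) for i in items]
    if np.any(np.all(np.isnan(y), axis=0)):
        j = int(np.flatnonzero(np.all(np.isnan(y), axis=0))[0])
        raise ResponseDataError(
            f"group {group!r}: item {items[j]!r} is missing for every respondent"
        )
    col_mean = np.nanmean(np.where(np.isnan(y), np.nan, y), axis=0)
    for j in np.flatnonzero((col_mean == 0.0) | (col_mean == 1.0)):
        warnings.warn(
            f"group {group!r}: item {items[int(j)]!r} is constant "
            f"(all {int(col_mean[int(j)])}); its threshold will drift to the bound",
            BoundaryWarning,
            stacklevel=2,
        )

    pat = _Patterns(y)
    eta, logqw = quad.standard_normal_nodes()

    def objective(theta):
        lam = theta[:p]
        tau = theta[p:]
        ll, Gz, _ = _loglik_core(lam, tau, pat, eta, logqw, link)
        d_lam = -(Gz @ eta)
        d_tau = Gz.sum(axis=1)
        return -ll, np.concatenate([d_lam, d_tau])

    def grad_fn(theta):
        return objective(theta)[1]

    def score_fn(theta):
        lam = theta[:p]
        tau = theta[p:]
        _, _, sc = _loglik_core(lam, tau, pat, eta, logqw, link, scores=True)
        return np.hstack([sc[0], sc[1]]), pat.counts

    theta0 = np.asarray(start, dtype=float) if start is not None else _start_values(y)
    bounds = [(-PARAM_BOUND, PARAM_BOUND)] * (2 * p)
    res = minimize(
        objective,
        theta0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-6},
    )
    gnorm = float(np.max(np.abs(res.jac)))
    if not res.success and gnorm > 1e-3 * max(1.0, pat.n / 100.0):
        raise ConvergenceError(
            f"group {group!r}: 2PL fit did not converge "
            f"({res.message}; iterations={res.nit}, |grad|={gnorm:.3g})",
            trace={"message": str(res.message), "nit": int(res.nit), "gnorm": gnorm},
        )
    theta = res.x
    return GroupFit(
        group=group,
        items=items,
        loadings=theta[:p].copy(),
        thresholds=theta[p:].copy(),
        loglik=-float(res.fun),
        cov=_try_covariance(grad_fn, theta),
        n=pat.n,
        link=link,
        quad=quad,
        converged=bool(res.success),
        n_iter=int(res.nit),
        _grad_fn=grad_fn,
        _score_fn=score_fn,
    )


@dataclass
class ConfiguralFit:
    """Per-group 2PL estimates with factor distributions fixed at N(0, 1).

    ``loadings`` and ``thresholds`` have shape (P, G) with column order
    matching ``groups``; ``cov_by_group[g]`` is the (2P, 2P) covariance of
    (lambda_1..lambda_P, tau_1..tau_P) in group g.
    """

    groups: List[Hashable]
    items: List[str]
    loadings: np.ndarray
    thresholds: np.ndarray
    loglik_by_group: np.ndarray
    group_sizes: np.ndarray
    link: str
    quad: QuadratureSpec
    cov_by_group: Optional[List[Optional[np.ndarray]]] = field(default=None, repr=False)
    group_fits: Optional[List[GroupFit]] = field(default=None, repr=False, compare=False)
    level: str = "configural"

    @property
    def loglik(self) -> float:
        return float(np.sum(self.loglik_by_group))

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def n_free(self) -> int:
        return free_parameter_count("configural", self.n_groups, self.n_items)

    @classmethod
    def from_params(
        cls,
        groups: Sequence[Hashable],
        items: Sequence[str],
        loadings: np.ndarray,
        thresholds: np.ndarray,
        group_sizes: Sequence[int],
        link: str = "logit",
        quad: QuadratureSpec = QuadratureSpec(),
        cov_by_group: Optional[List[Optional[np.ndarray]]] = None,
        loglik_by_group: Optional[np.ndarray] = None,
    ) -> "ConfiguralFit":
        """Build from externally supplied configural-scale parameters.

        Allows the alignment engine to run on estimates produced elsewhere
        (e.g. an analytic construction) without refitting.
        """
        loadings = np.asarray(loadings, dtype=float)
        thresholds = np.asarray(thresholds, dtype=float)
        g = len(list(groups))
        p = len(list(items))
        if loadings.shape != (p, g) or thresholds.shape != (p, g):
            raise DomainError(f"parameter arrays must have shape ({p}, {g})")
        if loglik_by_group is None:
            loglik_by_group = np.full(g, np.nan)
        return cls(
            groups=list(groups),
            items=[str(i) for i in items],
            loadings=loadings,
            thresholds=thresholds,
            loglik_by_group=np.asarray(loglik_by_group, dtype=float),
            group_sizes=np.asarray(group_sizes, dtype=int),
            link=link,
            quad=quad,
            cov_by_group=cov_by_group,
        )


def fit_configural(
    data: ResponseData,
    quad: QuadratureSpec = QuadratureSpec(),
    link: str = "logit",
) -> ConfiguralFit:
    """Fit the configural model: independent per-group 2PL fits.

    The total log-likelihood is the sum of the per-group log-likelihoods,
    since groups are independent under the configural model.
    """
    fits = []
    for label in data.groups:
        try:
            fits.append(
                fit_group_2pl(data.block(label), data.items, quad, link, group=label)
            )
        except ConvergenceError as err:
            raise ConvergenceError(
                f"configural fit failed in group {label!r}: {err}", trace=err.trace
            ) from err
    p = data.n_items
    return ConfiguralFit(
        groups=data.groups,
        items=data.items,
        loadings=np.column_stack([f.loadings for f in fits]),
        thresholds=np.column_stack([f.thresholds for f in fits]),
        loglik_by_group=np.array([f.loglik for f in fits]),
        group_sizes=np.array([f.n for f in fits]),
        link=link,
        quad=quad,
        cov_by_group=[f.cov for f in fits],
        group_fits=fits,
    )


def free_parameter_count(level: str, G: int, P: int) -> int:
    """Free parameters of a model level under this package's identification.

    configural: 2*P*G; metric: P + P*G + (G-1); scalar: 2*P + 2*(G-1).
    The configural-minus-metric difference is (G-1)(P-1) and the
    configural-minus-scalar difference is 2(G-1)(P-1).
    """
    if G < 2 or P < 2:
        raise DomainError("need at least 2 groups and 2 items")
    if level == "configural":
        return 2 * P * G
    if level == "metric":
        return P + P * G + (G - 1)
    if level == "scalar":
        return 2 * P + 2 * (G - 1)
    raise DomainError(f"unknown model level {level!r}")


@dataclass
class ConstrainedFit:
    """Joint multi-group fit under metric or scalar equality constraints."""

    level: str
    groups: List[Hashable]
    items: List[str]
    loadings: np.ndarray  # (P, G), expanded to full shape
    thresholds: np.ndarray  # (P, G)
    alphas: np.ndarray  # (G,) factor means (reference fixed at 0)
    psis: np.ndarray  # (G,) factor variances (reference fixed at 1)
    loglik: float
    n_free: int
    link: str
    quad: QuadratureSpec
    converged: bool
    n_iter: int
    group_sizes: np.ndarray
    _theta: Optional[np.ndarray] = field(default=None, repr=False, compare=False)
    _grad_fn: Optional[Callable] = field(default=None, repr=False, compare=False)
    _score_fn: Optional[Callable] = field(default=None, repr=False, compare=False)
    _param_names: Optional[List[str]] = field(default=None, repr=False, compare=False)

    @property
    def theta(self):
        return self._theta

    def param_names(self) -> List[str]:
        return list(self._param_names or [])


def _constraint_maps(level: str, G: int, P: int):
    """Index maps from full parameter arrays into the free vector.

    Entries of -1 in the distribution maps denote parameters fixed at
    their reference values (mean 0, log-variance 0).
    """
    lam_idx = np.empty((P, G), dtype=int)
    tau_idx = np.empty((P, G), dtype=int)
    alpha_idx = np.full(G, -1, dtype=int)
    s_idx = np.full(G, -1, dtype=int)
    names: List[str] = []
    if level == "metric":
        for p_ in range(P):
            lam_idx[p_, :] = p_
        names += [f"lambda[{p_}]" for p_ in range(P)]
        k = P
        for p_ in range(P):
            for g_ in range(G):
                tau_idx[p_, g_] = k
                names.append(f"tau[{p_},{g_}]")
                k += 1
        for g_ in range(1, G):
            s_idx[g_] = k
            names.append(f"log_psi[{g_}]")
            k += 1
    elif level == "scalar":
        for p_ in range(P):
            lam_idx[p_, :] = p_
            tau_idx[p_, :] = P + p_
        names += [f"lambda[{p_}]" for p_ in range(P)]
        names += [f"tau[{p_}]" for p_ in range(P)]
        k = 2 * P
        for g_ in range(1, G):
            alpha_idx[g_] = k
            names.append(f"alpha[{g_}]")
            k += 1
        for g_ in range(1, G):
            s_idx[g_] = k
            names.append(f"log_psi[{g_}]")
            k += 1
    else:
        raise DomainError(f"unsupported constrained level {level!r}")
    n_free = k
    assert n_free == free_parameter_count(level, G, P)
    return lam_idx, tau_idx, alpha_idx, s_idx, names, n_free


def fit_invariance_model(
    data: ResponseData,
    level: str,
    quad: QuadratureSpec = QuadratureSpec(),
    link: str = "logit",
    configural: Optional[ConfiguralFit] = None,
) -> ConstrainedFit:
    """Joint ML fit under metric or scalar invariance constraints.

    Starting values come from a configural fit (computed here when not
    supplied): constrained loadings/thresholds start at the across-group
    means of the configural estimates.
    """
    if level not in ("metric", "scalar"):
        raise DomainError("level must be 'metric' or 'scalar'")
    G, P = data.n_groups, data.n_items
    lam_idx, tau_idx, alpha_idx, s_idx, names, n_free = _constraint_maps(level, G, P)
    if configural is None:
        configural = fit_configural(data, quad, link)

    pats = [_Patterns(data.block(g)) for g in data.groups]
    eta0, logqw = quad.standard_normal_nodes()

    def unpack(x):
        lam = x[lam_idx]
        tau = x[tau_idx]
        alpha = np.where(alpha_idx >= 0, x[np.maximum(alpha_idx, 0)], 0.0)
        s = np.where(s_idx >= 0, x[np.maximum(s_idx, 0)], 0.0)
        return lam, tau, alpha, s

    def objective(x):
        lam, tau, alpha, s = unpack(x)
        sqrt_psi = np.exp(0.5 * s)
        nll = 0.0
        grad = np.zeros(n_free)
        for gi in range(G):
            eta = alpha[gi] + sqrt_psi[gi] * eta0
            ll, Gz, _ = _loglik_core(lam[:, gi], tau[:, gi], pats[gi], eta, logqw, link)
            nll -= ll
            d_lam = -(Gz @ eta)
            d_tau = Gz.sum(axis=1)
            np.add.at(grad, lam_idx[:, gi], d_lam)
            np.add.at(grad, tau_idx[:, gi], d_tau)
            if alpha_idx[gi] >= 0:
                grad[alpha_idx[gi]] += -float(lam[:, gi] @ Gz.sum(axis=1))
            if s_idx[gi] >= 0:
                grad[s_idx[gi]] += -float(lam[:, gi] @ (Gz @ ((eta - alpha[gi]) / 2.0)))
        return nll, grad

    def grad_fn(x):
        return objective(x)[1]

    def score_fn(x):
        lam, tau, alpha, s = unpack(x)
        sqrt_psi = np.exp(0.5 * s)
        rows = []
        counts = []
        for gi in range(G):
            eta = alpha[gi] + sqrt_psi[gi] * eta0
            _, _, sc = _loglik_core(
                lam[:, gi], tau[:, gi], pats[gi], eta, logqw, link, scores=True
            )
            score_lam, score_tau = sc  # (T, P) each
            t = score_lam.shape[0]
            block = np.zeros((t, n_free))
            np.add.at(block.T, lam_idx[:, gi], score_lam.T)
            np.add.at(block.T, tau_idx[:, gi], score_tau.T)
            # score wrt z summed over nodes is -score_tau; chain rule gives
            # d/d alpha = lam . (-score_tau), d/d log_psi uses (eta - alpha)/2
            if alpha_idx[gi] >= 0:
                block[:, alpha_idx[gi]] = -(score_tau @ lam[:, gi])
            if s_idx[gi] >= 0:
                block[:, s_idx[gi]] = (
                    (score_lam + alpha[gi] * score_tau) @ lam[:, gi]
                ) / 2.0
            rows.append(block)
            counts.append(pats[gi].counts)
        return np.vstack(rows), np.concatenate(counts)

    # starting values from the configural estimates
    x0 = np.zeros(n_free)
    lam_bar = configural.loadings.mean(axis=1)
    tau_bar = configural.thresholds.mean(axis=1)
    if level == "metric":
        x0[:P] = lam_bar
        for p_ in range(P):
            for g_ in range(G):
                x0[tau_idx[p_, g_]] = configural.thresholds[p_, g_]
    else:
        x0[:P] = lam_bar
        x0[P : 2 * P] = tau_bar

    bounds = []
    for name in names:
        if name.startswith("alpha"):
            bounds.append((-_ALPHA_BOUND, _ALPHA_BOUND))
        elif name.startswith("log_psi"):
            bounds.append((-_LOGPSI_BOUND, _LOGPSI_BOUND))
        else:
            bounds.append((-PARAM_BOUND, PARAM_BOUND))

    res = minimize(
        objective,
        x0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 3000, "ftol": 1e-12, "gtol": 1e-6},
    )
    gnorm = float(np.max(np.abs(res.jac)))
    if not res.success and gnorm > 1e-3 * max(1.0, data.n_total / 100.0):
        raise ConvergenceError(
            f"{level} fit did not converge ({res.message}; iterations={res.nit})",
            trace={"message": str(res.message), "nit": int(res.nit), "gnorm": gnorm},
        )
    lam, tau, alpha, s = unpack(res.x)
    return ConstrainedFit(
        level=level,
        groups=data.groups,
        items=data.items,
        loadings=lam.copy(),
        thresholds=tau.copy(),
        alphas=alpha.copy(),
        psis=np.exp(s),
        loglik=-float(res.fun),
        n_free=n_free,
        link=link,
        quad=quad,
        converged=bool(res.success),
        n_iter=int(res.nit),
        group_sizes=np.array([pat.n for pat in pats]),
        _theta=res.x.copy(),
        _grad_fn=grad_fn,
        _score_fn=score_fn,
        _param_names=names,
    )


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio chi-square test between two nested model levels."""

    chisq: float
    df: int
    pvalue: float


def likelihood_ratio_test(general, restricted, tol: float = 1e-6) -> LRTResult:
    """Chi-square = 2 * (loglik_general - loglik_restricted); df from counts.

    ``general`` must be strictly less constrained than ``restricted``
    (configural > metric > scalar).
    """
    lvl_g = _LEVEL_ORDER.get(getattr(general, "level", None))
    lvl_r = _LEVEL_ORDER.get(getattr(restricted, "level", None))
    if lvl_g is None or lvl_r is None or lvl_g <= lvl_r:
        raise DomainError(
            f"models are not nested in the required direction: "
            f"{getattr(general, 'level', None)!r} vs {getattr(restricted, 'level', None)!r}"
        )
    chisq = 2.0 * (general.loglik - restricted.loglik)
    if chisq < -tol * max(1.0, abs(general.loglik)):
        raise DomainError(
            f"restricted model has higher likelihood (chi-square {chisq:.4g}); "
            "check convergence"
        )
    chisq = max(chisq, 0.0)
    df = general.n_free - restricted.n_free
    return LRTResult(chisq=chisq, df=df, pvalue=float(chi2.sf(chisq, df)))


@dataclass
class SEResult:
    """Parameter covariance and standard errors from observed information."""

    cov: np.ndarray
    se: np.ndarray
    param_names: List[str]
    method: str


def observed_information_se(fit, method: str = "hessian") -> SEResult:
    """Covariance from the observed information at the estimate.

    ``method='hessian'`` inverts the negative Hessian of the marginal
    log-likelihood (computed by central finite differences of the
    analytic score).  ``method='sandwich'`` wraps the outer product of
    independent-observation scores between two inverse Hessians.
    """
    if isinstance(fit, ConfiguralFit):
        if not fit.group_fits:
            raise DomainError("configural fit carries no per-group fit objects")
        results = [observed_information_se(f, method) for f in fit.group_fits]
        cov = _block_diag([r.cov for r in results])
        names = [f"{n}@{f.group}" for f, r in zip(fit.group_fits, results) for n in r.param_names]
        return SEResult(cov=cov, se=np.sqrt(np.diag(cov)), param_names=names, method=method)

    grad_fn = getattr(fit, "_grad_fn", None)
    theta = fit.theta
    if grad_fn is None or theta is None:
        raise DomainError("fit is detached from its data; refit to compute SEs")
    names = fit.param_names()
    H = _fd_hessian(grad_fn, np.asarray(theta, dtype=float))
    eigvals, eigvecs = np.linalg.eigh(H)
    if eigvals.min() <= 0:
        j = int(np.argmin(eigvals))
        worst = int(np.argmax(np.abs(eigvecs[:, j])))
        raise NonPositiveDefiniteError(
            f"observed information is not positive definite "
            f"(min eigenvalue {eigvals.min():.3g}, dominated by {names[worst]!r})"
        )
    cov = eigvecs @ np.diag(1.0 / eigvals) @ eigvecs.T
    if method == "sandwich":
        score_fn = getattr(fit, "_score_fn", None)
        if score_fn is None:
            raise DomainError("fit does not expose per-observation scores")
        scores, counts = score_fn(np.asarray(theta, dtype=float))
        B = scores.T @ (scores * counts[:, None])
        cov = cov @ B @ cov
    elif method != "hessian":
        raise DomainError(f"unknown SE method {method!r}")
    cov = 0.5 * (cov + cov.T)
    return SEResult(cov=cov, se=np.sqrt(np.clip(np.diag(cov), 0.0, None)), param_names=names, method=method)


def _block_diag(blocks: List[np.ndarray]) -> np.ndarray:
    if any(b is None for b in blocks):
        raise DomainError("a group covariance is unavailable (singular information)")
    size = sum(b.shape[0] for b in blocks)
    out = np.zeros((size, size))
    k = 0
    for b in blocks:
        out[k : k + b.shape[0], k : k + b.shape[0]] = b
        k += b.shape[0]
    return out
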