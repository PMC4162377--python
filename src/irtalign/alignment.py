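"""Alignment of configural estimates: recover group factor means/variances.

The configural model fixes every group's factor distribution at N(0, 1),
which pushes true group differences in the latent mean and variance into
the item parameters.  For any candidate means/variances (alpha_g, psi_g)
there exist transformed item parameters giving *exactly* the configural
likelihood:

    lambda_1 = lambda_0 / sqrt(psi),
    tau_1    = tau_0 + alpha * lambda_0 / sqrt(psi).

(The intercept form nu_1 = nu_0 - alpha * lambda_0 / sqrt(psi) is the
same statement with nu = -tau.)  Alignment chooses (alpha_g, psi_g) to
minimize the total measurement non-invariance of the transformed
parameters,

    F = sum_p sum_{g1<g2} w_{g1,g2} [ f(lambda diff) + f(threshold diff) ],

with a component loss function (CLF) f that is concave in |x|, so the
optimum concentrates non-invariance in a few large differences rather
than many medium ones.  The default CLF is f(x) = (x^2 + eps)^(1/4), a
smooth surrogate of sqrt(|x|), with eps = 1e-4; the square-root form
(x^2 + eps)^(1/2) is selectable.  Pair weights default to
sqrt(N_g1 * N_g2) so larger (more precisely estimated) groups dominate.

Because alpha and psi only relabel the latent scale, the solution needs
an anchor.  The optimization always pins the reference group's mean at
0 and constrains the variances to multiply to 1 (pinning one variance
instead would let the concave loss collapse every difference by
inflating all other variances at once).  Under the default
"fixed_reference" identification the solution is afterwards re-anchored
affinely so the reference group is exactly N(0, 1); "product" reports
the raw product-constrained solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, List, Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .estimation import ConfiguralFit
from .model_core import DomainError

__all__ = [
    "AlignmentOptions",
    "AlignmentResult",
    "AlignmentError",
    "clf",
    "clf_grad",
    "pair_weights",
    "align_transform",
    "inverse_align_transform",
    "total_loss",
    "align",
    "loss_contributions",
    "pairwise_comparison_count",
]

CLF_FORMS = ("fourth_root", "square_root")
WEIGHT_MODES = ("sqrt_product", "unit")
IDENTIFICATIONS = ("fixed_reference", "product")


class AlignmentError(RuntimeError):
    """Every optimizer start failed; carries per-start diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


@dataclass(frozen=True)
class AlignmentOptions:
    """Tunable settings of the alignment optimizer."""

    epsilon: float = 1e-4
    clf_form: str = "fourth_root"
    weight_mode: str = "sqrt_product"
    identification: str = "fixed_reference"
    reference: Optional[Hashable] = None  # default: first group
    n_starts: int = 30
    perturb_mean_sd: float = 0.5
    perturb_logvar_sd: float = 0.3
    tol: float = 1e-8
    seed: int = 0

    def __post_init__(self):
        if self.epsilon <= 0:
            raise DomainError("CLF epsilon must be > 0")
        if self.n_starts < 1:
            raise DomainError("need at least one optimizer start")
        if self.clf_form not in CLF_FORMS:
            raise DomainError(f"clf_form must be one of {CLF_FORMS}")
        if self.weight_mode not in WEIGHT_MODES:
            raise DomainError(f"weight_mode must be one of {WEIGHT_MODES}")
        if self.identification not in IDENTIFICATIONS:
            raise DomainError(f"identification must be one of {IDENTIFICATIONS}")


def clf(x, epsilon: float = 1e-4, form: str = "fourth_root"):
    """Component loss function: even and strictly increasing in |x|.

    fourth_root: (x^2 + eps)^(1/4);  square_root: (x^2 + eps)^(1/2).
    At x = 0 the fourth-root form equals eps^(1/4).
    """
    if epsilon <= 0:
        raise DomainError("epsilon must be > 0")
    x = np.asarray(x, dtype=float)
    power = 0.25 if form == "fourth_root" else 0.5
    if form not in CLF_FORMS:
        raise DomainError(f"unknown CLF form {form!r}")
    out = (x * x + epsilon) ** power
    return float(out) if out.ndim == 0 else out


def clf_grad(x, epsilon: float = 1e-4, form: str = "fourth_root"):
    """Derivative of :func:`clf` (odd function of x)."""
    x = np.asarray(x, dtype=float)
    power = 0.25 if form == "fourth_root" else 0.5
    if form not in CLF_FORMS:
        raise DomainError(f"unknown CLF form {form!r}")
    out = 2.0 * power * x * (x * x + epsilon) ** (power - 1.0)
    return float(out) if out.ndim == 0 else out


def pair_weights(group_sizes: Sequence[float], mode: str = "sqrt_product") -> np.ndarray:
    """Symmetric (G, G) pairwise weight table.

    sqrt_product: w = sqrt(N_g1 * N_g2); unit: all weights 1.  The
    diagonal is zero (a group is never paired with itself).
    """
    sizes = np.asarray(group_sizes, dtype=float)
    if np.any(sizes < 1):
        raise DomainError("all group sizes must be >= 1")
    if mode == "sqrt_product":
        w = np.sqrt(np.outer(sizes, sizes))
    elif mode == "unit":
        w = np.ones((sizes.size, sizes.size))
    else:
        raise DomainError(f"unknown weight mode {mode!r}")
    np.fill_diagonal(w, 0.0)
    return w


def align_transform(loadings, thresholds, alpha, psi):
    """Transform configural-scale parameters under candidate (alpha, psi).

    Satisfies the likelihood-equality identity: the transformed
    parameters combined with ability ~ N(alpha, psi) reproduce the
    configural likelihood exactly.  ``alpha``/``psi`` broadcast over the
    trailing (group) axis of (P, G) parameter arrays.
    """
    psi = np.asarray(psi, dtype=float)
    if np.any(psi <= 0):
        raise DomainError("psi must be strictly positive")
    lam0 = np.asarray(loadings, dtype=float)
    tau0 = np.asarray(thresholds, dtype=float)
    lam1 = lam0 / np.sqrt(psi)
    tau1 = tau0 + np.asarray(alpha, dtype=float) * lam1
    return lam1, tau1


def inverse_align_transform(loadings, thresholds, alpha, psi):
    """Push invariant-scale parameters to the configural scale.

    Inverse of :func:`align_transform`: the configural model absorbs a
    group's true N(alpha, psi) ability distribution into its item
    parameters.  Used to construct analytic fixtures.
    """
    psi = np.asarray(psi, dtype=float)
    if np.any(psi <= 0):
        raise DomainError("psi must be strictly positive")
    lam1 = np.asarray(loadings, dtype=float)
    tau1 = np.asarray(thresholds, dtype=float)
    lam0 = lam1 * np.sqrt(psi)
    tau0 = tau1 - np.asarray(alpha, dtype=float) * lam1
    return lam0, tau0


def _loss_terms(lam1, tau1, weights, epsilon, form):
    """Per-item, per-unordered-pair loss terms for both parameter families.

    Returns (f_lam, f_tau) of shape (P, n_pairs) already multiplied by
    the pair weights, plus the pair index arrays.
    """
    G = lam1.shape[1]
    iu, ju = np.triu_indices(G, k=1)
    w = weights[iu, ju]
    f_lam = w * clf(lam1[:, iu] - lam1[:, ju], epsilon, form)
    f_tau = w * clf(tau1[:, iu] - tau1[:, ju], epsilon, form)
    return f_lam, f_tau, iu, ju


def total_loss(loadings, thresholds, alphas, psis, weights, options: AlignmentOptions) -> float:
    """Total simplicity/loss F of the aligned configuration.

    Sums the CLF of aligned-parameter differences over all items and
    unordered group pairs, loadings and thresholds accumulated
    separately and added.
    """
    lam1, tau1 = align_transform(loadings, thresholds, alphas, psis)
    f_lam, f_tau, _, _ = _loss_terms(lam1, tau1, weights, options.epsilon, options.clf_form)
    return float(f_lam.sum() + f_tau.sum())


def _free_layout(G: int, ref_idx: int):
    """Free-parameter layout of the optimization manifold.

    The loss is minimized over alpha_g (reference pinned at 0) and the
    log-variances subject to the product constraint prod(psi_g) = 1
    (the last group's log-variance balances the others).  Pinning a
    single variance instead would leave a degenerate descent direction:
    inflating every other variance shrinks all pairwise aligned-loading
    differences at once, and the concave CLF rewards that collapse.
    """
    alpha_free = [g for g in range(G) if g != ref_idx]
    return alpha_free, 2 * (G - 1)


def _expand(x, G: int, ref_idx: int):
    m = G - 1
    alphas = np.zeros(G)
    alpha_free = [g for g in range(G) if g != ref_idx]
    alphas[alpha_free] = x[:m]
    s = np.empty(G)
    s[: G - 1] = x[m:]
    s[G - 1] = -float(np.sum(x[m:]))
    return alphas, s


def _loss_and_grad(x, lam0, tau0, weights, options, G, ref_idx, epsilon):
    alphas, s = _expand(x, G, ref_idx)
    psis = np.exp(s)
    lam1, tau1 = align_transform(lam0, tau0, alphas, psis)
    # full antisymmetric difference matrices per item: (P, G, G)
    d_lam = lam1[:, :, None] - lam1[:, None, :]
    d_tau = tau1[:, :, None] - tau1[:, None, :]
    fl = clf(d_lam, epsilon, options.clf_form)
    ft = clf(d_tau, epsilon, options.clf_form)
    wf = weights  # zero diagonal
    loss = 0.5 * float((wf * (fl + ft)).sum(axis=0).sum())
    # T_pg = sum_h w_gh f'(lam1_pg - lam1_ph); likewise U for thresholds
    T = (wf * clf_grad(d_lam, epsilon, options.clf_form)).sum(axis=2)
    U = (wf * clf_grad(d_tau, epsilon, options.clf_form)).sum(axis=2)
    # chain rule: d lam1/d s = -lam1/2 ; d tau1/d alpha = lam1 ;
    # d tau1/d s = -alpha * lam1 / 2
    g_alpha = (U * lam1).sum(axis=0)
    g_s = (-0.5 * T * lam1 - 0.5 * U * alphas[None, :] * lam1).sum(axis=0)
    m = G - 1
    alpha_free = [g for g in range(G) if g != ref_idx]
    grad = np.empty(2 * m)
    grad[:m] = g_alpha[alpha_free]
    grad[m:] = g_s[: G - 1] - g_s[G - 1]  # chain rule through the product constraint
    return loss, grad


@dataclass
class AlignmentResult:
    """Aligned solution: group distributions, parameters and loss anatomy."""

    groups: List[Hashable]
    items: List[str]
    identification: str
    reference: Hashable
    alphas: np.ndarray  # (G,) estimated factor means
    psis: np.ndarray  # (G,) estimated factor variances
    loadings_aligned: np.ndarray  # (P, G)
    thresholds_aligned: np.ndarray  # (P, G)
    loadings_configural: np.ndarray = field(repr=False)
    thresholds_configural: np.ndarray = field(repr=False)
    weights: np.ndarray = field(repr=False)
    group_sizes: np.ndarray
    loss: float
    loss_loadings: float
    loss_thresholds: float
    loss_by_item: np.ndarray  # (P, 2): loading column, threshold column
    loss_by_group: np.ndarray  # (G,) half-share of every pair term involving g
    options: AlignmentOptions
    start_losses: List[float] = field(default_factory=list, repr=False)
    best_start: int = 0
    x_opt: Optional[np.ndarray] = field(default=None, repr=False, compare=False)


def align(fit: ConfiguralFit, options: AlignmentOptions = AlignmentOptions()) -> AlignmentResult:
    """Minimize the total loss over free group means and variances.

    Multistart quasi-Newton optimization on (alpha_g, log psi_g) with
    seeded random perturbations around the configural anchor (0, 1); the
    lowest-loss converged start wins, ties broken by start index.  A
    short continuation pass at a larger CLF epsilon precedes each start
    to tame the stiffness of the tiny-epsilon loss surface.
    """
    G = len(fit.groups)
    P = len(fit.items)
    if G < 2:
        raise DomainError("alignment needs at least 2 groups")
    lam0 = np.asarray(fit.loadings, dtype=float)
    tau0 = np.asarray(fit.thresholds, dtype=float)
    weights = pair_weights(fit.group_sizes, options.weight_mode)
    ref = options.reference if options.reference is not None else fit.groups[0]
    if ref not in fit.groups:
        raise DomainError(f"reference group {ref!r} not among groups")
    ref_idx = fit.groups.index(ref)
    _, n_free = _free_layout(G, ref_idx)

    rng = np.random.default_rng(options.seed)
    starts = [np.zeros(n_free)]
    m = G - 1
    for _ in range(options.n_starts - 1):
        x = np.zeros(n_free)
        x[:m] = rng.normal(0.0, options.perturb_mean_sd, size=m)
        x[m:] = rng.normal(0.0, options.perturb_logvar_sd, size=m)
        starts.append(x)

    # box bounds keep exp(log psi) finite during line searches
    opt_bounds = [(-10.0, 10.0)] * m + [(-5.0, 5.0)] * m

    def run(x0, epsilon):
        return minimize(
            _loss_and_grad,
            np.clip(x0, [b[0] for b in opt_bounds], [b[1] for b in opt_bounds]),
            args=(lam0, tau0, weights, options, G, ref_idx, epsilon),
            jac=True,
            method="L-BFGS-B",
            bounds=opt_bounds,
            options={"maxiter": 5000, "ftol": 1e-15, "gtol": options.tol * 1e-2},
        )

    best = None
    best_idx = -1
    start_losses: List[float] = []
    diagnostics = []
    for idx, x0 in enumerate(starts):
        try:
            if options.epsilon < 1e-2:
                warm = run(x0, 1e-2)
                res = run(warm.x, options.epsilon)
            else:
                res = run(x0, options.epsilon)
            start_losses.append(float(res.fun))
            diagnostics.append({"start": idx, "loss": float(res.fun), "nit": int(res.nit)})
            if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
                best = res
                best_idx = idx
        except (ValueError, FloatingPointError) as err:  # pragma: no cover
            start_losses.append(float("nan"))
            diagnostics.append({"start": idx, "error": str(err)})
    if best is None:
        raise AlignmentError("every alignment start failed", diagnostics=diagnostics)

    alphas, s = _expand(best.x, G, ref_idx)
    psis = np.exp(s)
    if options.identification == "fixed_reference":
        # re-anchor the latent scale so the reference group is exactly N(0, 1)
        alphas = (alphas - alphas[ref_idx]) / np.sqrt(psis[ref_idx])
        psis = psis / psis[ref_idx]
    lam1, tau1 = align_transform(lam0, tau0, alphas, psis)
    f_lam, f_tau, iu, ju = _loss_terms(lam1, tau1, weights, options.epsilon, options.clf_form)
    loss_by_item = np.column_stack([f_lam.sum(axis=1), f_tau.sum(axis=1)])
    pair_totals = (f_lam + f_tau).sum(axis=0)  # (n_pairs,)
    loss_by_group = np.zeros(G)
    np.add.at(loss_by_group, iu, 0.5 * pair_totals)
    np.add.at(loss_by_group, ju, 0.5 * pair_totals)
    return AlignmentResult(
        groups=list(fit.groups),
        items=list(fit.items),
        identification=options.identification,
        reference=ref,
        alphas=alphas,
        psis=psis,
        loadings_aligned=lam1,
        thresholds_aligned=tau1,
        loadings_configural=lam0,
        thresholds_configural=tau0,
        weights=weights,
        group_sizes=np.asarray(fit.group_sizes, dtype=int),
        loss=float(f_lam.sum() + f_tau.sum()),
        loss_loadings=float(f_lam.sum()),
        loss_thresholds=float(f_tau.sum()),
        loss_by_item=loss_by_item,
        loss_by_group=loss_by_group,
        options=options,
        start_losses=start_losses,
        best_start=best_idx,
        x_opt=best.x.copy(),
    )


def loss_contributions(result: AlignmentResult):
    """Per-item and per-group contributions to the total loss.

    Item contributions are that item's terms in the loss (loadings and
    thresholds reported separately and together); each pair term is
    split half-and-half between its two groups so that both the item
    and the group columns sum to the total loss.
    """
    import pandas as pd

    items = pd.DataFrame(
        {
            "loading": result.loss_by_item[:, 0],
            "threshold": result.loss_by_item[:, 1],
            "total": result.loss_by_item.sum(axis=1),
        },
        index=pd.Index(result.items, name="item"),
    )
    groups = pd.DataFrame(
        {"total": result.loss_by_group},
        index=pd.Index([str(g) for g in result.groups], name="group"),
    )
    return items, groups


def pairwise_comparison_count(n_groups: int) -> int:
    """Number of unordered group pairs, G(G-1)/2.

    This is the number of pairwise tests a traditional one-pair-at-a-time
    invariance search would need per item — e.g. 1225 for 50 groups —
    which is what makes alignment attractive for many groups.
    """
    if n_groups < 1:
        raise DomainError("need at least one group")
    return n_groups * (n_groups - 1) // 2
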