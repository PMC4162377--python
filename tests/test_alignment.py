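"""Tests of the alignment transformation, loss and optimizer."""

import numpy as np
import pytest

from irtalign.alignment import (
    AlignmentOptions,
    align,
    align_transform,
    clf,
    clf_grad,
    inverse_align_transform,
    loss_contributions,
    pair_weights,
    pairwise_comparison_count,
    total_loss,
)
from irtalign.estimation import ConfiguralFit, marginal_loglik
from irtalign.model_core import DomainError


# ---------------------------------------------------------------- CLF


@pytest.mark.parametrize(
    "x,form,expected",
    [
        (0.0, "fourth_root", 0.1),  # eps^(1/4) at eps = 1e-4
        (1.0, "fourth_root", 1.0000250),
        (0.0, "square_root", 0.01),
        (3.0, "square_root", np.sqrt(9.0001)),
    ],
)
def test_clf_values(x, form, expected):
    assert clf(x, 1e-4, form) == pytest.approx(expected, abs=1e-6)


def test_clf_even_and_increasing_in_magnitude():
    rng = np.random.default_rng(4)
    x = rng.uniform(-5, 5, 100)
    for form in ("fourth_root", "square_root"):
        assert np.allclose(clf(x, 1e-4, form), clf(-x, 1e-4, form))
        grid = np.linspace(0, 5, 200)
        assert np.all(np.diff(clf(grid, 1e-4, form)) > 0)


def test_clf_gradient_matches_finite_difference():
    x = np.linspace(-2, 2, 21)
    h = 1e-7
    for form in ("fourth_root", "square_root"):
        fd = (clf(x + h, 1e-4, form) - clf(x - h, 1e-4, form)) / (2 * h)
        assert np.allclose(clf_grad(x, 1e-4, form), fd, atol=1e-5)


def test_clf_requires_positive_epsilon():
    with pytest.raises(DomainError):
        clf(1.0, 0.0)


# ------------------------------------------------------------- weights


def test_pair_weights_modes_and_symmetry():
    w = pair_weights([100, 100, 100], "sqrt_product")
    off = w[~np.eye(3, dtype=bool)]
    assert np.allclose(off, 100.0)  # sqrt(N * N) = N
    u = pair_weights([10, 999], "unit")
    assert u[0, 1] == u[1, 0] == 1.0
    rng = np.random.default_rng(0)
    sizes = rng.integers(1, 5000, size=6)
    w = pair_weights(sizes, "sqrt_product")
    assert np.allclose(w, w.T)
    with pytest.raises(DomainError):
        pair_weights([0, 10], "sqrt_product")


def test_pairwise_comparison_count():
    assert pairwise_comparison_count(50) == 1225
    assert pairwise_comparison_count(2) == 1


# ------------------------------------------------------- transformation


def test_transform_is_identity_at_standard_distribution():
    rng = np.random.default_rng(1)
    lam = rng.uniform(0.5, 2, (4, 3))
    tau = rng.uniform(-1, 1, (4, 3))
    lam1, tau1 = align_transform(lam, tau, np.zeros(3), np.ones(3))
    assert np.array_equal(lam1, lam)
    assert np.array_equal(tau1, tau)


def test_transform_round_trip_with_inverse():
    rng = np.random.default_rng(2)
    lam = rng.uniform(0.5, 2, (10, 2))
    tau = rng.uniform(-1, 1, (10, 2))
    alphas = np.array([0.0, -1.0])
    psis = np.array([1.0, 2.0])
    lam0, tau0 = inverse_align_transform(lam, tau, alphas, psis)
    lam1, tau1 = align_transform(lam0, tau0, alphas, psis)
    assert np.allclose(lam1, lam, atol=1e-10)
    assert np.allclose(tau1, tau, atol=1e-10)


def test_transform_preserves_likelihood():
    """Foundational identity: transformed parameters plus N(alpha, psi)
    ability reproduce the configural likelihood."""
    rng = np.random.default_rng(6)
    y = (rng.random((60, 4)) < 0.55).astype(float)
    y[5, 1] = np.nan
    lam0 = rng.uniform(0.5, 2, 4)
    tau0 = rng.uniform(-1, 1, 4)
    base = marginal_loglik(y, lam0, tau0)
    for _ in range(100):
        a = rng.normal(0, 1.5)
        p = rng.uniform(0.2, 4.0)
        lam1, tau1 = align_transform(lam0, tau0, a, p)
        assert marginal_loglik(y, lam1, tau1, mean=a, variance=p) == pytest.approx(
            base, abs=1e-8
        )


def test_transform_rejects_nonpositive_variance():
    with pytest.raises(DomainError):
        align_transform(np.ones((2, 2)), np.zeros((2, 2)), np.zeros(2), np.array([1.0, 0.0]))


# ------------------------------------------------------------ total loss


def brute_force_loss(lam0, tau0, alphas, psis, weights, epsilon, form):
    """Naive double-loop oracle over items and unordered group pairs."""
    P, G = lam0.shape
    lam1 = lam0 / np.sqrt(psis)
    tau1 = tau0 + alphas * lam1
    total = 0.0
    for p in range(P):
        for g1 in range(G):
            for g2 in range(g1 + 1, G):
                w = weights[g1, g2]
                total += w * clf(lam1[p, g1] - lam1[p, g2], epsilon, form)
                total += w * clf(tau1[p, g1] - tau1[p, g2], epsilon, form)
    return total


def test_total_loss_matches_brute_force_oracle():
    rng = np.random.default_rng(7)
    for form in ("fourth_root", "square_root"):
        lam0 = rng.uniform(0.3, 2.5, (6, 4))
        tau0 = rng.uniform(-2, 2, (6, 4))
        alphas = rng.normal(0, 1, 4)
        psis = rng.uniform(0.3, 3, 4)
        weights = pair_weights(rng.integers(50, 5000, 4), "sqrt_product")
        opts = AlignmentOptions(clf_form=form)
        ours = total_loss(lam0, tau0, alphas, psis, weights, opts)
        oracle = brute_force_loss(lam0, tau0, alphas, psis, weights, 1e-4, form)
        assert ours == pytest.approx(oracle, abs=1e-10 * max(1, abs(oracle)))


def test_loss_floor_at_perfect_invariance():
    """With identical aligned parameters the loss is exactly the floor
    2 * P * G(G-1)/2 * f(0) under unit weights, and never below it."""
    P, G = 5, 4
    lam0 = np.tile(np.linspace(0.8, 1.6, P)[:, None], (1, G))
    tau0 = np.tile(np.linspace(-1, 1, P)[:, None], (1, G))
    weights = pair_weights([100] * G, "unit")
    opts = AlignmentOptions(weight_mode="unit")
    floor = 2 * P * (G * (G - 1) / 2) * clf(0.0)
    f = total_loss(lam0, tau0, np.zeros(G), np.ones(G), weights, opts)
    assert f == pytest.approx(floor, abs=1e-10)
    rng = np.random.default_rng(8)
    for _ in range(20):
        alphas = rng.normal(0, 1, G)
        psis = rng.uniform(0.3, 3, G)
        assert total_loss(lam0, tau0, alphas, psis, weights, opts) >= floor - 1e-12


def test_perturbing_one_threshold_increases_loss():
    rng = np.random.default_rng(9)
    lam0 = np.tile(rng.uniform(0.5, 2, 5)[:, None], (1, 3))
    tau0 = np.tile(rng.uniform(-1, 1, 5)[:, None], (1, 3))
    weights = pair_weights([100] * 3, "unit")
    opts = AlignmentOptions()
    base = total_loss(lam0, tau0, np.zeros(3), np.ones(3), weights, opts)
    tau0[2, 1] += 0.5
    assert total_loss(lam0, tau0, np.zeros(3), np.ones(3), weights, opts) > base


# ------------------------------------------------------------- optimizer


def test_align_recovers_two_group_distributions(two_group_scenario):
    """Configural scale built from group distributions (0,1)/(-1,2) of a
    fully invariant bank: alignment must recover mean -1, variance 2."""
    res = align(two_group_scenario["fit"], AlignmentOptions(seed=3))
    assert res.alphas[0] == 0.0 and res.psis[0] == 1.0
    assert res.alphas[1] == pytest.approx(-1.0, abs=1e-3)
    assert res.psis[1] == pytest.approx(2.0, abs=1e-3)
    # invariant inputs: the final loss sits on the theoretical floor
    n_pairs = 1
    floor = 2 * 10 * n_pairs * res.weights[0, 1] * clf(0.0)
    assert res.loss == pytest.approx(floor, abs=1e-6 * floor)


def test_align_deterministic_under_seed(two_group_scenario):
    r1 = align(two_group_scenario["fit"], AlignmentOptions(seed=11))
    r2 = align(two_group_scenario["fit"], AlignmentOptions(seed=11))
    assert np.array_equal(r1.alphas, r2.alphas)
    assert np.array_equal(r1.psis, r2.psis)
    assert r1.loss == r2.loss and r1.best_start == r2.best_start


def test_align_improves_on_configural_anchor(small_fit):
    res = align(small_fit, AlignmentOptions(n_starts=5, seed=0))
    opts = res.options
    at_start = total_loss(
        res.loadings_configural,
        res.thresholds_configural,
        np.zeros(len(res.groups)),
        np.ones(len(res.groups)),
        res.weights,
        opts,
    )
    assert res.loss <= at_start + 1e-9


def test_align_decomposition_sums_to_total(small_fit):
    res = align(small_fit, AlignmentOptions(n_starts=5, seed=0))
    assert res.loss_by_item.sum() == pytest.approx(res.loss, abs=1e-9 * res.loss)
    assert res.loss_by_group.sum() == pytest.approx(res.loss, abs=1e-9 * res.loss)
    assert res.loss_loadings + res.loss_thresholds == pytest.approx(res.loss, abs=1e-9)


def test_alignment_consistency_errors_shrink_with_sample_size():
    """Consistency on invariant data: estimation errors of the group
    means and variances shrink as group sizes grow, and at n = 2000 the
    means are usually within 0.1 and variances within 0.15 of truth."""
    from irtalign.estimation import fit_configural
    from irtalign.simulate import generate_responses, make_population

    pop = make_population(
        G=5,
        P=15,
        seed=88,
        alphas=[0.0, 0.15, 0.25, 0.4, 0.5],
        psis=[1.0, 1.2, 0.9, 1.1, 1.0],
    )
    reps = 12
    err_alpha = {}
    err_psi = {}
    hits_alpha = hits_psi = 0
    for n in (250, 2000):
        ea = []
        ep = []
        for r in range(reps):
            data = generate_responses(pop, n, seed=5000 + r)
            fit = fit_configural(data)
            res = align(fit, AlignmentOptions(n_starts=3, seed=r))
            ea.append(np.abs(res.alphas - pop.alphas).mean())
            ep.append(np.abs(res.psis - pop.psis).mean())
            if n == 2000:
                hits_alpha += np.all(np.abs(res.alphas - pop.alphas) < 0.1)
                hits_psi += np.all(np.abs(res.psis - pop.psis) < 0.15)
        err_alpha[n] = np.mean(ea)
        err_psi[n] = np.mean(ep)
    assert err_alpha[2000] < err_alpha[250]
    assert err_psi[2000] < err_psi[250]
    assert hits_alpha >= 8
    assert hits_psi >= 7


def test_align_reference_reanchoring_exact_on_invariant_construction(two_group_scenario):
    fit = two_group_scenario["fit"]
    r1 = align(fit, AlignmentOptions(seed=3, reference="g1"))
    r2 = align(fit, AlignmentOptions(seed=3, reference="g2"))
    # re-anchor r2 onto g1: means shift and rescale, variances rescale
    a2, p2 = r2.alphas, r2.psis
    re_alpha = (a2 - a2[0]) / np.sqrt(p2[0])
    re_psi = p2 / p2[0]
    assert np.allclose(re_alpha, r1.alphas, atol=1e-4)
    assert np.allclose(re_psi, r1.psis, atol=1e-4)


def test_align_reference_reanchoring_approximate_on_fitted_data(small_fit):
    r1 = align(small_fit, AlignmentOptions(n_starts=5, seed=0, reference="G1"))
    r2 = align(small_fit, AlignmentOptions(n_starts=5, seed=0, reference="G2"))
    re_alpha = (r2.alphas - r2.alphas[0]) / np.sqrt(r2.psis[0])
    re_psi = r2.psis / r2.psis[0]
    # on noisy fitted data the anchoring choice shifts the optimum a
    # little (the concave loss is not affine-equivariant); agreement is
    # approximate at sampling scale rather than exact
    assert np.allclose(re_alpha, r1.alphas, atol=0.2)
    assert np.allclose(re_psi, r1.psis, atol=0.2)


def test_align_product_identification(small_fit):
    res = align(small_fit, AlignmentOptions(n_starts=5, seed=0, identification="product"))
    assert np.prod(res.psis) == pytest.approx(1.0, abs=1e-8)
    assert res.alphas[0] == 0.0


def test_align_requires_two_groups():
    fit = ConfiguralFit.from_params(
        groups=["only"],
        items=["Y1", "Y2"],
        loadings=np.ones((2, 1)),
        thresholds=np.zeros((2, 1)),
        group_sizes=[50],
    )
    with pytest.raises(DomainError):
        align(fit)


# -------------------------------------------------------- contributions


def test_contributions_conserve_and_localize_dif():
    rng = np.random.default_rng(13)
    P, G = 5, 4
    lam = np.tile(rng.uniform(0.8, 1.8, P)[:, None], (1, G))
    tau = np.tile(rng.uniform(-1, 1, P)[:, None], (1, G))
    tau[2, 3] += 1.2  # inject DIF on item 3 in the last group
    fit = ConfiguralFit.from_params(
        groups=[f"g{i}" for i in range(G)],
        items=[f"Y{i + 1}" for i in range(P)],
        loadings=lam,
        thresholds=tau,
        group_sizes=[500] * G,
    )
    res = align(fit, AlignmentOptions(seed=2, weight_mode="unit"))
    items, groups = loss_contributions(res)
    assert items["total"].sum() == pytest.approx(res.loss, abs=1e-9 * res.loss)
    assert groups["total"].sum() == pytest.approx(res.loss, abs=1e-9 * res.loss)
    # the DIF item dominates; invariant items sit at their floor value
    assert items["total"].idxmax() == "Y3"
    floor_item = 2 * (G * (G - 1) / 2) * clf(0.0)
    for item in ("Y1", "Y2", "Y4", "Y5"):
        assert items.loc[item, "total"] == pytest.approx(floor_item, rel=1e-3)
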