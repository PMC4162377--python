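"""Tests of marginal ML estimation, model constraints and the LRT."""

import numpy as np
import pytest

from irtalign.data import ResponseData, ResponseDataError
from irtalign.estimation import (
    BoundaryWarning,
    ConfiguralFit,
    QuadratureSpec,
    fit_configural,
    fit_group_2pl,
    fit_invariance_model,
    free_parameter_count,
    likelihood_ratio_test,
    marginal_loglik,
    observed_information_se,
)
from irtalign.model_core import DomainError
from irtalign.simulate import generate_responses, make_population


def brute_force_loglik(y, lam, tau):
    """Independent oracle: per-respondent adaptive quadrature over the
    ability, with explicit loops and no shared code path."""
    from scipy.integrate import quad
    from scipy.stats import norm

    def integrand(e, row):
        prod = norm.pdf(e)
        for j, v in enumerate(row):
            if np.isnan(v):
                continue
            p = 1.0 / (1.0 + np.exp(-(lam[j] * e - tau[j])))
            prod *= p if v == 1 else (1.0 - p)
        return prod

    total = 0.0
    for row in y:
        like, _ = quad(integrand, -12, 12, args=(row,), epsabs=1e-12, epsrel=1e-12)
        total += np.log(like)
    return total


def test_marginal_loglik_matches_brute_force_oracle():
    y = np.array(
        [[1, 0], [0, 0], [1, 1], [0, 1], [1, np.nan]], dtype=float
    )
    lam = np.array([1.2, 0.7])
    tau = np.array([-0.3, 0.5])
    ours = marginal_loglik(y, lam, tau, quad=QuadratureSpec(n_nodes=201))
    oracle = brute_force_loglik(y, lam, tau)
    assert ours == pytest.approx(oracle, abs=1e-6)


def test_duplicating_respondents_doubles_loglik():
    rng = np.random.default_rng(3)
    y = (rng.random((40, 3)) < 0.5).astype(float)
    lam = np.array([1.0, 1.5, 0.8])
    tau = np.array([0.2, -0.4, 0.0])
    single = marginal_loglik(y, lam, tau)
    double = marginal_loglik(np.vstack([y, y]), lam, tau)
    assert double == pytest.approx(2.0 * single, abs=1e-9)


def test_group_fit_recovers_generating_parameters():
    """n = 2000 estimates should sit within 3 SEs of the truth."""
    pop = make_population(G=2, P=5, seed=17, alphas=[0.0, 0.0], psis=[1.0, 1.0])
    data = generate_responses(pop, 2000, seed=8)
    fit = fit_group_2pl(data.block("G1"), data.items, group="G1")
    se = np.sqrt(np.diag(fit.cov))
    truth = np.concatenate([pop.loadings[:, 0], pop.thresholds[:, 0]])
    est = np.concatenate([fit.loadings, fit.thresholds])
    assert np.all(np.abs(est - truth) < 3.0 * se + 1e-9)


def test_constant_item_column_warns():
    y = np.zeros((30, 2))
    y[:, 1] = (np.arange(30) % 2).astype(float)
    with pytest.warns(BoundaryWarning, match="Y1"):
        fit_group_2pl(y)


def test_all_missing_item_rejected():
    y = np.array([[1.0, np.nan], [0.0, np.nan], [1.0, np.nan]])
    with pytest.raises(ResponseDataError, match="missing for every respondent"):
        fit_group_2pl(y)


def test_configural_total_is_sum_of_groups_and_permutation_invariant(small_data, small_fit):
    assert small_fit.loglik == pytest.approx(small_fit.loglik_by_group.sum(), abs=1e-10)
    # permute group order: total loglik unchanged
    reordered = ResponseData(
        items=small_data.items,
        blocks={g: small_data.block(g) for g in reversed(small_data.groups)},
    )
    refit = fit_configural(reordered)
    assert refit.loglik == pytest.approx(small_fit.loglik, abs=1e-6)


def test_quadrature_refinement_changes_little(small_data):
    """Doubling the node count barely moves the fitted total loglik."""
    f21 = fit_configural(small_data, quad=QuadratureSpec(n_nodes=21))
    f42 = fit_configural(small_data, quad=QuadratureSpec(n_nodes=42))
    assert abs(f21.loglik - f42.loglik) < 1e-5 * abs(f21.loglik)


@pytest.mark.parametrize(
    "G,P,level,expected_diff",
    [
        (14, 17, "metric", 208),
        (14, 17, "scalar", 416),
        (28, 17, "metric", 432),
        (28, 17, "scalar", 864),
    ],
)
def test_free_parameter_count_differences(G, P, level, expected_diff):
    diff = free_parameter_count("configural", G, P) - free_parameter_count(level, G, P)
    assert diff == expected_diff


def test_free_parameter_count_formulas():
    assert free_parameter_count("configural", 14, 17) == 2 * 17 * 14
    with pytest.raises(DomainError):
        free_parameter_count("configural", 1, 17)
    with pytest.raises(DomainError):
        free_parameter_count("bayesian", 3, 5)


def test_nesting_chain_and_lrt(small_data, small_fit):
    metric = fit_invariance_model(small_data, "metric", configural=small_fit)
    scalar = fit_invariance_model(small_data, "scalar", configural=small_fit)
    assert small_fit.loglik >= metric.loglik >= scalar.loglik
    # identification: reference group pinned at N(0, 1) exactly
    assert scalar.alphas[0] == 0.0 and scalar.psis[0] == 1.0
    lrt_m = likelihood_ratio_test(small_fit, metric)
    lrt_s = likelihood_ratio_test(small_fit, scalar)
    G, P = small_data.n_groups, small_data.n_items
    assert lrt_m.df == (G - 1) * (P - 1)
    assert lrt_s.df == 2 * (G - 1) * (P - 1)
    assert 0.0 <= lrt_m.pvalue <= 1.0
    # scalar truth here (invariant population): scalar should not be
    # rejected overwhelmingly often; just check the statistic is modest
    assert lrt_s.chisq < 3.0 * lrt_s.df


def test_lrt_identical_fits_and_nesting_errors(small_fit):
    class Fake:
        level = "metric"
        loglik = small_fit.loglik
        n_free = small_fit.n_free - 8

    assert likelihood_ratio_test(small_fit, Fake()).chisq == pytest.approx(0.0)
    assert likelihood_ratio_test(small_fit, Fake()).pvalue == pytest.approx(1.0)
    with pytest.raises(DomainError):
        likelihood_ratio_test(Fake(), small_fit)  # wrong direction
    with pytest.raises(DomainError):
        likelihood_ratio_test(small_fit, small_fit)  # same level


def test_scalar_fit_recovers_group_means(small_data, small_fit, invariant_pop):
    scalar = fit_invariance_model(small_data, "scalar", configural=small_fit)
    assert np.all(np.abs(scalar.alphas - invariant_pop.alphas) < 0.15)


def test_observed_information_matches_loglik_hessian_oracle():
    """Covariance equals the inverse numerical Hessian of the loglik."""
    pop = make_population(G=2, P=3, seed=33, alphas=[0.0, 0.0], psis=[1.0, 1.0])
    data = generate_responses(pop, 500, seed=9)
    fit = fit_group_2pl(data.block("G1"), data.items, group="G1")
    theta = fit.theta
    lam, tau = theta[:3], theta[3:]

    def ll(t):
        return marginal_loglik(data.block("G1"), t[:3], t[3:])

    n = theta.size
    H = np.empty((n, n))
    h = 1e-4
    base = ll(theta)
    for i in range(n):
        for j in range(i, n):
            ei = np.eye(n)[i] * h
            ej = np.eye(n)[j] * h
            H[i, j] = H[j, i] = (
                ll(theta + ei + ej) - ll(theta + ei - ej)
                - ll(theta - ei + ej) + ll(theta - ei - ej)
            ) / (4 * h * h)
    oracle_cov = np.linalg.inv(-H)
    res = observed_information_se(fit)
    assert np.allclose(res.cov, oracle_cov, rtol=1e-4, atol=1e-8)
    assert np.all(np.diag(res.cov) >= 0)


def test_standard_errors_shrink_with_root_n():
    pop = make_population(G=2, P=4, seed=51, alphas=[0.0, 0.0], psis=[1.0, 1.0])
    small = generate_responses(pop, 500, seed=1)
    big = generate_responses(pop, 2000, seed=2)
    f_small = fit_group_2pl(small.block("G1"), small.items)
    f_big = fit_group_2pl(big.block("G1"), big.items)
    ratio = np.sqrt(np.diag(f_small.cov)) / np.sqrt(np.diag(f_big.cov))
    # quadrupling n should halve the SEs; the median ratio stays within
    # 15 percent of 2, individual parameters within sampling slack
    assert abs(np.median(ratio) - 2.0) < 0.3
    assert np.all((ratio > 1.2) & (ratio < 3.2))


def test_sandwich_variant_is_same_scale(small_data):
    fit = fit_group_2pl(small_data.block("G1"), small_data.items)
    hess = observed_information_se(fit, method="hessian")
    sand = observed_information_se(fit, method="sandwich")
    ratio = sand.se / hess.se
    assert np.all((ratio > 0.5) & (ratio < 2.0))


def test_quadrature_spec_validation():
    with pytest.raises(DomainError):
        QuadratureSpec(n_nodes=3)
    with pytest.raises(NotImplementedError):
        QuadratureSpec(n_nodes=21, adaptive=True).standard_normal_nodes()


def test_configural_from_params_shape_validation():
    with pytest.raises(DomainError):
        ConfiguralFit.from_params(
            groups=["a", "b"],
            items=["Y1", "Y2"],
            loadings=np.ones((3, 2)),
            thresholds=np.ones((2, 2)),
            group_sizes=[10, 10],
        )
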