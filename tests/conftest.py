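"""Shared fixtures: analytic constructions and seeded simulated fits.

Everything is generated programmatically; session scope shares the
expensive fits across tests.  Seeds are fixture constants.
"""

import numpy as np
import pytest

from irtalign.alignment import AlignmentOptions, align, inverse_align_transform
from irtalign.estimation import ConfiguralFit, fit_configural
from irtalign.report import aligned_standard_errors
from irtalign.simulate import generate_responses, make_population


@pytest.fixture(scope="session")
def two_group_scenario():
    """Invariant 10-item bank pushed to the configural scale under
    group distributions N(0,1) and N(-1,2)."""
    rng = np.random.default_rng(5)
    P = 10
    lam = rng.uniform(0.8, 2.0, P)
    tau = rng.uniform(-1.5, 1.5, P) * lam
    alphas = np.array([0.0, -1.0])
    psis = np.array([1.0, 2.0])
    lam_inv = np.tile(lam[:, None], (1, 2))
    tau_inv = np.tile(tau[:, None], (1, 2))
    lam0, tau0 = inverse_align_transform(lam_inv, tau_inv, alphas, psis)
    fit = ConfiguralFit.from_params(
        groups=["g1", "g2"],
        items=[f"Y{i + 1}" for i in range(P)],
        loadings=lam0,
        thresholds=tau0,
        group_sizes=[1000, 1000],
    )
    return {
        "fit": fit,
        "lam_invariant": lam_inv,
        "tau_invariant": tau_inv,
        "alphas": alphas,
        "psis": psis,
    }


@pytest.fixture(scope="session")
def invariant_pop():
    """Fully invariant 3-group, 5-item population with means 0/1/2."""
    return make_population(G=3, P=5, seed=21)


@pytest.fixture(scope="session")
def small_data(invariant_pop):
    return generate_responses(invariant_pop, 1000, seed=2)


@pytest.fixture(scope="session")
def small_fit(small_data):
    return fit_configural(small_data)


@pytest.fixture(scope="session")
def small_result(small_fit):
    return align(small_fit, AlignmentOptions(n_starts=5, seed=0))


@pytest.fixture(scope="session")
def small_ses(small_result, small_fit):
    return aligned_standard_errors(small_result, small_fit, n_boot=100, seed=4)
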