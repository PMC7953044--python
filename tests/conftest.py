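"""Shared fixtures: the synthetic study dataset (n = 3868 continuous
responses from the printed three-factor truth set) and the expensive model
fits reused across test modules."""

import numpy as np
import pytest

import bayescfa as b

FIXTURE_N = 3868
CHAIN_KW = dict(n_chains=3, n_warmup=1000, n_kept=1000)


@pytest.fixture(scope="session")
def gp():
    return b.default_generating_parameters()


@pytest.fixture(scope="session")
def specs():
    return b.mspss_specs()


@pytest.fixture(scope="session")
def fixture_data(gp):
    """The synthetic analogue of the study dataset: n = 3868 complete
    continuous responses generated from the printed parameter estimates."""
    rm = b.generate_responses(gp, FIXTURE_N, mode="continuous", seed=101)
    return rm, b.compute_sample_moments(rm)


@pytest.fixture(scope="session")
def three_factor_fit(fixture_data, specs):
    _, sm = fixture_data
    return b.run_chains(sm, specs["three_factor"], seed=202, **CHAIN_KW)


@pytest.fixture(scope="session")
def one_factor_fit(fixture_data, specs):
    _, sm = fixture_data
    return b.run_chains(sm, specs["one_factor"], seed=303, **CHAIN_KW)


@pytest.fixture(scope="session")
def independence_fit(fixture_data):
    _, sm = fixture_data
    return b.fit_independence_model(sm, seed=404, **CHAIN_KW)


@pytest.fixture(scope="session")
def standardized_draws(three_factor_fit, specs):
    """Per-iteration completely standardized loadings (12), factor
    correlations (3) as flat arrays over all kept draws."""
    spec = specs["three_factor"]
    n = three_factor_fit.n_chains * three_factor_fit.n_kept
    lam = np.empty((n, 12))
    corr = np.empty((n, 3))
    triu = np.triu_indices(3, k=1)
    for i, params in enumerate(three_factor_fit.iter_parameters()):
        std = b.standardize(params, spec)
        lam[i] = std.lam.sum(axis=1)
        corr[i] = std.factor_corr[triu]
    return lam, corr


@pytest.fixture(scope="session")
def ppp_true_model_reps(gp, specs):
    """PPP of the three-factor model fitted to 20 independent datasets
    generated from itself at n = 500 (reduced chain protocol)."""
    spec = specs["three_factor"]
    ppps = []
    for rep in range(20):
        rm = b.generate_responses(gp, 500, mode="continuous", seed=1000 + rep)
        sm = b.compute_sample_moments(rm)
        draws = b.run_chains(sm, spec, seed=2000 + rep, n_chains=2,
                             n_warmup=400, n_kept=400, n_starts=2)
        _, _, ppp = b.posterior_predictive(draws, sm, spec, seed=3000 + rep)
        ppps.append(ppp)
    return np.array(ppps)


@pytest.fixture(scope="session")
def coverage_runs(gp, specs):
    """95% credible-interval coverage of the generating standardized loadings
    and factor correlations over 20 replications at n = 1000."""
    spec = specs["three_factor"]
    triu = np.triu_indices(3, k=1)
    truth = np.concatenate([gp.loadings, gp.factor_correlations[triu]])
    hits, total = 0, 0
    for rep in range(20):
        rm = b.generate_responses(gp, 1000, mode="continuous", seed=5000 + rep)
        sm = b.compute_sample_moments(rm)
        draws = b.run_chains(sm, spec, seed=6000 + rep, n_chains=2,
                             n_warmup=400, n_kept=400, n_starts=2)
        n = draws.n_chains * draws.n_kept
        vals = np.empty((n, 15))
        for i, params in enumerate(draws.iter_parameters()):
            std = b.standardize(params, spec)
            vals[i] = np.concatenate([std.lam.sum(axis=1), std.factor_corr[triu]])
        lo, hi = np.quantile(vals, [0.025, 0.975], axis=0)
        hits += int(np.sum((truth >= lo) & (truth <= hi)))
        total += truth.size
    return hits, total
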