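"""Beta-binomial inference: conjugate oracle, MH sampler, diagnostics."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cinvecon import (
    BetaPrior,
    BinomialObservation,
    DegenerateChainError,
    PosteriorChain,
    SamplerSettings,
    conjugate_posterior,
    diagnose,
    mh_sample,
    summarize,
)
from conftest import TABLE2


@pytest.mark.parametrize(
    "obs, prior, expected_shape, expected_mean",
    [
        ((45, 88), (178, 114), (223, 157), 223 / 380),
        ((0, 0), (1, 1), (1, 1), 0.5),
        ((4, 43), (33, 191), (37, 230), 37 / 267),
    ],
)
def test_conjugate_posterior_shapes_and_means(obs, prior, expected_shape, expected_mean):
    post = conjugate_posterior(BinomialObservation(*obs), BetaPrior(*prior))
    assert (post.alpha, post.beta) == expected_shape
    assert post.mean == pytest.approx(expected_mean)


def test_conjugate_means_round_to_published_table():
    for row in TABLE2.values():
        post = conjugate_posterior(
            BinomialObservation(row["events"], row["total"]),
            BetaPrior(row["alpha"], row["beta"]),
        )
        assert post.mean == pytest.approx(row["mean"], abs=0.0015)


def test_observation_and_prior_invariants():
    with pytest.raises(ValueError):
        BinomialObservation(5, 3)
    with pytest.raises(ValueError):
        BinomialObservation(-1, 3)
    with pytest.raises(ValueError):
        BetaPrior(0.0, 1.0)
    with pytest.raises(ValueError):
        SamplerSettings(iterations=100, burn_in=100)


@pytest.mark.parametrize("name", list(TABLE2))
def test_mh_chain_mean_matches_conjugate_oracle(name):
    """Chain mean agrees with the closed form within 3 Monte-Carlo errors."""
    row = TABLE2[name]
    obs = BinomialObservation(row["events"], row["total"])
    prior = BetaPrior(row["alpha"], row["beta"])
    chain = mh_sample(obs, prior, SamplerSettings(seed=7))
    oracle = conjugate_posterior(obs, prior).mean
    ess = diagnose(chain).effective_sample_size
    mc_error = chain.draws.std() / math.sqrt(ess)
    assert abs(chain.mean - oracle) < 3 * mc_error


def test_mh_cycle2_continuation_matches_published_value():
    """Posterior continuation probability at day 22 is 94.7% (CI 91.7–97%)."""
    chain = mh_sample(
        BinomialObservation(86, 88), BetaPrior(160, 12), SamplerSettings(seed=11)
    )
    summary = summarize(chain)
    assert summary.mean == pytest.approx(0.947, abs=0.005)
    assert summary.ci_low == pytest.approx(0.917, abs=0.01)
    assert summary.ci_high == pytest.approx(0.970, abs=0.01)


def test_mh_flat_prior_small_sample():
    chain = mh_sample(
        BinomialObservation(0, 10), BetaPrior(1, 1), SamplerSettings(seed=3)
    )
    assert ((chain.draws > 0) & (chain.draws < 1)).all()
    ess = diagnose(chain).effective_sample_size
    assert chain.mean == pytest.approx(1 / 12, abs=3 * chain.draws.std() / math.sqrt(ess))


def test_mh_is_deterministic_given_seed():
    obs, prior = BinomialObservation(45, 88), BetaPrior(178, 114)
    settings = SamplerSettings(seed=42)
    a = mh_sample(obs, prior, settings)
    b = mh_sample(obs, prior, settings)
    assert np.array_equal(a.draws, b.draws)
    assert a.acceptance_rate == b.acceptance_rate


def test_mh_degenerate_proposal_raises():
    with pytest.raises(DegenerateChainError):
        mh_sample(
            BinomialObservation(45, 88),
            BetaPrior(178, 114),
            SamplerSettings(seed=0, proposal_scale=1e9, adapt=False,
                            iterations=2000, burn_in=100),
        )


@given(
    events=st.integers(0, 50),
    total=st.integers(1, 50),
    alpha=st.floats(0.5, 200),
    beta=st.floats(0.5, 200),
)
def test_posterior_mean_shrinks_between_prior_and_data(events, total, alpha, beta):
    """The conjugate mean lies strictly between prior mean and observed rate."""
    events = min(events, total)
    obs = BinomialObservation(events, total)
    prior = BetaPrior(alpha, beta)
    post_mean = conjugate_posterior(obs, prior).mean
    lo, hi = sorted((prior.mean, obs.proportion))
    if lo < hi:
        assert lo < post_mean < hi
    else:
        assert post_mean == pytest.approx(prior.mean)


def _constant_chain(value: float, n: int = 100) -> PosteriorChain:
    settings = SamplerSettings(iterations=n, burn_in=0, seed=0)
    return PosteriorChain(np.full(n, value), acceptance_rate=0.5, settings=settings)


def test_summarize_degenerate_chain_collapses():
    summary = summarize(_constant_chain(0.3))
    assert summary.mean == summary.median == summary.ci_low == summary.ci_high == 0.3


def test_summarize_rejects_bad_level(chains):
    with pytest.raises(ValueError):
        summarize(chains["p_high_risk"], level=1.0)
    with pytest.raises(ValueError):
        summarize(chains["p_high_risk"], level=0.0)


def test_diagnose_iid_chain_has_unit_efficiency():
    rng = np.random.default_rng(5)
    settings = SamplerSettings(iterations=10_000, burn_in=0, seed=5)
    chain = PosteriorChain(rng.beta(223, 157, size=10_000), 1.0, settings)
    diag = diagnose(chain)
    assert diag.autocorrelations[0] == 1.0
    assert diag.efficiency == pytest.approx(1.0, abs=0.15)


def test_diagnose_constant_chain_is_fully_correlated():
    diag = diagnose(_constant_chain(0.4), max_lag=10)
    assert np.allclose(diag.autocorrelations, 1.0)


def test_diagnose_mh_chain_efficiency_in_range(chains):
    for chain in chains.values():
        diag = diagnose(chain)
        assert 0.0 < diag.efficiency <= 1.1


def test_diagnose_agrees_with_arviz_ess(chains):
    """Hand-written autocorrelation-sum ESS tracks the arviz estimator."""
    az = pytest.importorskip("arviz")
    chain = chains["p_high_risk"]
    ours = diagnose(chain).effective_sample_size
    reference = float(az.ess(chain.draws[None, :]))
    assert 0.5 < ours / reference < 2.0
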