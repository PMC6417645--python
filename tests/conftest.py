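import pytest
from hypothesis import HealthCheck, settings

from cinvecon import ProbabilityVector, default_config
from cinvecon.reporting import posterior_mean_vector, run_inference

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

# Published posterior summary table, for reference assertions.
TABLE2 = {
    "p_high_risk": dict(events=45, total=88, alpha=178, beta=114,
                        mean=0.587, ci=(0.538, 0.634)),
    "p_cinv": dict(events=4, total=43, alpha=33, beta=191,
                   mean=0.139, ci=(0.100, 0.181)),
    "p_cycle2": dict(events=86, total=88, alpha=160, beta=12,
                     mean=0.947, ci=(0.917, 0.970)),
    "p_cycle3_given_cycle2": dict(events=64, total=86, alpha=120, beta=40,
                                  mean=0.748, ci=(0.692, 0.800)),
}


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def chains(config):
    """The four default-configuration MH chains (12,500 iters, 2,500 burn-in)."""
    return run_inference(config)


@pytest.fixture(scope="session")
def pv_chain_means(chains):
    return posterior_mean_vector(chains)


@pytest.fixture(scope="session")
def pv_printed_means():
    """The probability vector at the published (rounded) posterior means."""
    return ProbabilityVector(
        p_high_risk=0.587, p_cinv=0.139, p_cycle2=0.947, p_cycle3_given_cycle2=0.748
    )
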