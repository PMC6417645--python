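"""Beta-binomial posterior inference by Metropolis-Hastings MCMC.

Each probability node of the decision model is a Bernoulli success rate p
with a Beta(alpha, beta) prior (pseudo event / non-event counts from
published cohorts) and a Binomial(n, k) observation.  The posterior is the
conjugate Beta(alpha + k, beta + n - k); :func:`conjugate_posterior` gives
that closed form and serves as the exact oracle for the sampler.

:func:`mh_sample` draws from the same posterior with a Gaussian random-walk
Metropolis-Hastings sampler on the logit of p, with step-size adaptation
during burn-in towards ~44% acceptance (the classic one-dimensional
random-walk optimum).  Working on the logit scale keeps every draw strictly
inside (0, 1) without rejection tricks; the log-Jacobian of the transform
is folded into the target density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "BinomialObservation",
    "BetaPrior",
    "SamplerSettings",
    "PosteriorChain",
    "PosteriorSummary",
    "ChainDiagnostics",
    "DegenerateChainError",
    "conjugate_posterior",
    "mh_sample",
    "summarize",
    "diagnose",
]

_ADAPT_WINDOW = 50
_TARGET_ACCEPTANCE = 0.44


class DegenerateChainError(RuntimeError):
    """The sampler stopped mixing (acceptance rate 0 or 1 after adaptation)."""


@dataclass(frozen=True)
class BinomialObservation:
    """Observed events out of total trials for one probability node."""

    events: int
    total: int

    def __post_init__(self) -> None:
        if not 0 <= self.events <= self.total:
            raise ValueError(
                f"require 0 <= events <= total, got events={self.events}, total={self.total}"
            )

    @property
    def proportion(self) -> float:
        """Observed event proportion; NaN for an empty observation."""
        return self.events / self.total if self.total else math.nan


@dataclass(frozen=True)
class BetaPrior:
    """Beta(alpha, beta) prior expressed as pseudo event / non-event counts.

    Also used for posterior shape parameters, since the family is conjugate.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError(f"alpha and beta must be positive, got ({self.alpha}, {self.beta})")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


@dataclass(frozen=True)
class SamplerSettings:
    """Metropolis-Hastings run configuration.

    ``iterations`` counts every proposal; the first ``burn_in`` draws are
    discarded, leaving ``iterations - burn_in`` retained draws.  The default
    12,500 / 2,500 split retains an MCMC sample of 10,000.
    ``proposal_scale`` is the random-walk standard deviation on the logit
    scale; with ``adapt`` it is tuned during burn-in and then frozen.
    """

    iterations: int = 12_500
    burn_in: int = 2_500
    seed: int = 0
    proposal_scale: float = 0.5
    adapt: bool = True

    def __post_init__(self) -> None:
        if self.iterations <= 0:
            raise ValueError(f"iterations must be positive, got {self.iterations}")
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError(
                f"require 0 <= burn_in < iterations, got burn_in={self.burn_in}, "
                f"iterations={self.iterations}"
            )
        if not self.proposal_scale > 0:
            raise ValueError(f"proposal_scale must be positive, got {self.proposal_scale}")

    @property
    def retained(self) -> int:
        return self.iterations - self.burn_in


@dataclass(frozen=True)
class PosteriorChain:
    """Retained MCMC draws for one probability, with sampler metadata."""

    draws: np.ndarray
    acceptance_rate: float
    settings: SamplerSettings

    def __post_init__(self) -> None:
        draws = np.asarray(self.draws, dtype=float)
        object.__setattr__(self, "draws", draws)
        if draws.ndim != 1 or len(draws) != self.settings.retained:
            raise ValueError(
                f"chain must hold iterations - burn_in = {self.settings.retained} draws, "
                f"got shape {draws.shape}"
            )
        if not ((draws > 0) & (draws < 1)).all():
            raise ValueError("all draws must lie strictly inside (0, 1)")

    @property
    def mean(self) -> float:
        return float(self.draws.mean())


@dataclass(frozen=True)
class PosteriorSummary:
    """Mean, median and equal-tailed credible interval of a chain."""

    mean: float
    median: float
    ci_low: float
    ci_high: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if not self.ci_low <= self.median <= self.ci_high:
            raise ValueError(
                f"require ci_low <= median <= ci_high, got "
                f"({self.ci_low}, {self.median}, {self.ci_high})"
            )


@dataclass(frozen=True)
class ChainDiagnostics:
    """Autocorrelation-based mixing diagnostics for a single chain."""

    effective_sample_size: float
    efficiency: float
    autocorrelations: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "autocorrelations", np.asarray(self.autocorrelations, dtype=float)
        )


def conjugate_posterior(obs: BinomialObservation, prior: BetaPrior) -> BetaPrior:
    """Closed-form Beta posterior: (alpha + events, beta + total - events)."""
    return BetaPrior(prior.alpha + obs.events, prior.beta + (obs.total - obs.events))


def _log_target(theta: float, a: float, b: float) -> float:
    # Posterior density on the logit scale, Jacobian included:
    # pi(theta) ∝ sigmoid(theta)^a * sigmoid(-theta)^b
    return -a * np.logaddexp(0.0, -theta) - b * np.logaddexp(0.0, theta)


def mh_sample(
    obs: BinomialObservation,
    prior: BetaPrior,
    settings: SamplerSettings | None = None,
) -> PosteriorChain:
    """Sample the beta-binomial posterior with random-walk MH on logit(p).

    The chain is started at the logit of the conjugate posterior mean.  With
    ``settings.adapt`` the proposal scale is multiplicatively adjusted every
    50 burn-in iterations towards 44% acceptance and frozen afterwards, so
    the retained chain is a plain time-homogeneous Metropolis-Hastings run.
    Identical settings (including seed) reproduce the chain bit-for-bit.
    """
    if settings is None:
        settings = SamplerSettings()
    post = conjugate_posterior(obs, prior)
    a, b = post.alpha, post.beta

    rng = np.random.default_rng(settings.seed)
    innovations = rng.standard_normal(settings.iterations)
    log_uniforms = np.log(rng.random(settings.iterations))

    scale = settings.proposal_scale
    theta = math.log(post.mean / (1.0 - post.mean))
    log_p = _log_target(theta, a, b)

    draws = np.empty(settings.retained)
    accepted_after_burn_in = 0
    window_accepts = 0

    for i in range(settings.iterations):
        proposal = theta + scale * innovations[i]
        log_p_prop = _log_target(proposal, a, b)
        accept = log_uniforms[i] < log_p_prop - log_p
        if accept:
            theta, log_p = proposal, log_p_prop
        if i < settings.burn_in:
            if settings.adapt:
                window_accepts += accept
                if (i + 1) % _ADAPT_WINDOW == 0:
                    rate = window_accepts / _ADAPT_WINDOW
                    scale = float(np.clip(scale * math.exp(rate - _TARGET_ACCEPTANCE), 1e-3, 50.0))
                    window_accepts = 0
        else:
            draws[i - settings.burn_in] = expit(theta)
            accepted_after_burn_in += accept

    acceptance_rate = accepted_after_burn_in / settings.retained
    if acceptance_rate in (0.0, 1.0):
        raise DegenerateChainError(
            f"chain degenerated: post-burn-in acceptance rate {acceptance_rate:.0%} "
            f"(proposal scale {scale:.3g})"
        )
    return PosteriorChain(draws=draws, acceptance_rate=acceptance_rate, settings=settings)


def summarize(chain: PosteriorChain, level: float = 0.95) -> PosteriorSummary:
    """Mean, median and equal-tailed percentile interval of the retained draws."""
    if not 0.0 < level < 1.0:
        raise ValueError(f"credible level must lie in (0, 1), got {level}")
    if len(chain.draws) == 0:
        raise ValueError("cannot summarize an empty chain")
    tail = (1.0 - level) / 2.0
    lo, hi = np.quantile(chain.draws, [tail, 1.0 - tail])
    return PosteriorSummary(
        mean=float(chain.draws.mean()),
        median=float(np.median(chain.draws)),
        ci_low=float(lo),
        ci_high=float(hi),
        level=level,
    )


def diagnose(chain: PosteriorChain, max_lag: int = 50) -> ChainDiagnostics:
    """Sample autocorrelation function, effective sample size and efficiency.

    ESS uses the standard truncated autocorrelation-sum estimator
    ``n / (1 + 2 * sum(rho_k))``, summing lags until the first negative
    autocorrelation (or ``max_lag``).  Efficiency is ESS over retained draws
    and may exceed 1 slightly for anticorrelated chains (estimator noise).
    """
    x = chain.draws
    n = len(x)
    if n <= max_lag:
        raise ValueError(f"chain length {n} must exceed max_lag {max_lag}")
    if np.all(x == x[0]):
        # Constant chain: perfectly correlated by convention.
        rho = np.ones(max_lag + 1)
    else:
        centred = x - x.mean()
        gamma0 = float(centred @ centred) / n
        rho = np.empty(max_lag + 1)
        rho[0] = 1.0
        for lag in range(1, max_lag + 1):
            rho[lag] = float(centred[:-lag] @ centred[lag:]) / (n * gamma0)
    tail = rho[1:]
    negative = np.nonzero(tail < 0.0)[0]
    cutoff = int(negative[0]) if negative.size else len(tail)
    tau = 1.0 + 2.0 * float(tail[:cutoff].sum())
    ess = n / tau
    return ChainDiagnostics(
        effective_sample_size=ess, efficiency=ess / n, autocorrelations=rho
    )
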