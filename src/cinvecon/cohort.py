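"""Synthetic patient cohorts with the statistical structure the model assumes.

Each patient is a set of independent Bernoulli draws: carrier status of the
high-risk genotype (``p_high_risk``), a grade >=3 nausea/vomiting indicator
per evaluation phase (``p_cinv``, constant across phases), receipt of
cycle 2 (``p_cycle2``) and receipt of cycle 3 conditional on cycle 2
(``p_cycle3_given_cycle2``).  Aggregating a cohort yields the four binomial
observations the inference layer consumes, using the same denominator
conventions as the source data: the toxicity denominator is the evaluable
subset (configurable fraction, default all patients), and the cycle-3
denominator is the number of cycle-2 receivers.

:func:`parameter_recovery` closes the loop — generate, aggregate, infer,
summarise — and reports posterior-mean bias and credible-interval coverage,
the calibration surface for the whole inference stack.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .inference import (
    BetaPrior,
    BinomialObservation,
    SamplerSettings,
    mh_sample,
    summarize,
)
from .tree import ProbabilityVector

__all__ = [
    "TrueParameters",
    "PatientRecord",
    "RecoveryReport",
    "generate_cohort",
    "aggregate",
    "parameter_recovery",
    "cohort_to_csv",
    "cohort_from_csv",
]

N_EVALUATION_PHASES = 2  # toxicity is assessed after cycle 1 and after cycle 2

_MAX_SEED = 2**31 - 1


@dataclass(frozen=True)
class TrueParameters:
    """Ground truth for a synthetic cohort."""

    pv: ProbabilityVector
    n_patients: int
    seed: int
    evaluable_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError(f"n_patients must be at least 1, got {self.n_patients}")
        if not 0.0 < self.evaluable_fraction <= 1.0:
            raise ValueError(
                f"evaluable_fraction must lie in (0, 1], got {self.evaluable_fraction}"
            )


@dataclass(frozen=True)
class PatientRecord:
    """One simulated patient's genotype, toxicity and continuation flags."""

    high_risk: bool
    cinv_by_phase: tuple[bool, ...]
    received_cycle2: bool
    received_cycle3: bool
    evaluable: bool = True

    def __post_init__(self) -> None:
        if self.received_cycle3 and not self.received_cycle2:
            raise ValueError("received_cycle3 requires received_cycle2")


@dataclass(frozen=True)
class RecoveryReport:
    """Bias and empirical interval coverage per probability."""

    replicates: int
    bias: dict[str, float]
    coverage: dict[str, float]
    posterior_means: dict[str, np.ndarray] = field(repr=False)


def generate_cohort(params: TrueParameters) -> list[PatientRecord]:
    """Draw an independent cohort, reproducible from ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    n = params.n_patients
    pv = params.pv
    high_risk = rng.random(n) < pv.p_high_risk
    cinv = rng.random((n, N_EVALUATION_PHASES)) < pv.p_cinv
    cycle2 = rng.random(n) < pv.p_cycle2
    cycle3 = cycle2 & (rng.random(n) < pv.p_cycle3_given_cycle2)
    evaluable = rng.random(n) < params.evaluable_fraction
    return [
        PatientRecord(
            high_risk=bool(high_risk[i]),
            cinv_by_phase=tuple(bool(v) for v in cinv[i]),
            received_cycle2=bool(cycle2[i]),
            received_cycle3=bool(cycle3[i]),
            evaluable=bool(evaluable[i]),
        )
        for i in range(n)
    ]


def aggregate(records: Sequence[PatientRecord]) -> dict[str, BinomialObservation]:
    """Collapse a cohort into the four binomial observations.

    The toxicity observation counts first-phase events among evaluable
    patients (the per-phase rate is constant, so one phase identifies it);
    the cycle-3 observation is conditional on cycle-2 receipt.
    """
    if not records:
        raise ValueError("cannot aggregate an empty cohort")
    n = len(records)
    evaluable = [r for r in records if r.evaluable]
    cycle2 = [r for r in records if r.received_cycle2]
    return {
        "p_high_risk": BinomialObservation(sum(r.high_risk for r in records), n),
        "p_cinv": BinomialObservation(
            sum(r.cinv_by_phase[0] for r in evaluable), len(evaluable)
        ),
        "p_cycle2": BinomialObservation(len(cycle2), n),
        "p_cycle3_given_cycle2": BinomialObservation(
            sum(r.received_cycle3 for r in cycle2), len(cycle2)
        ),
    }


def parameter_recovery(
    true_pv: ProbabilityVector,
    n_patients: int,
    priors: Mapping[str, BetaPrior],
    replicates: int = 200,
    seed: int = 0,
    settings: SamplerSettings | None = None,
    level: float = 0.95,
) -> RecoveryReport:
    """Simulation calibration of the full generate → infer pipeline.

    For each replicate a fresh cohort is generated and aggregated, one MH
    chain is run per probability, and the posterior mean and equal-tailed
    interval are recorded.  Reported per probability: mean posterior-mean
    bias (posterior mean minus truth) and the fraction of replicates whose
    interval covers the truth.  Default sampler settings are shortened to
    3,000 iterations with 500 burn-in, plenty for a one-dimensional chain.
    """
    if replicates < 1:
        raise ValueError(f"replicates must be at least 1, got {replicates}")
    if settings is None:
        settings = SamplerSettings(iterations=3_000, burn_in=500)
    missing = [name for name in ProbabilityVector.FIELDS if name not in priors]
    if missing:
        raise KeyError(f"missing priors for {missing}")

    master = np.random.default_rng(seed)
    cohort_seeds = master.integers(_MAX_SEED, size=replicates)
    chain_seeds = master.integers(_MAX_SEED, size=(replicates, len(ProbabilityVector.FIELDS)))

    truth = {name: getattr(true_pv, name) for name in ProbabilityVector.FIELDS}
    means = {name: np.empty(replicates) for name in ProbabilityVector.FIELDS}
    covered = {name: np.zeros(replicates, dtype=bool) for name in ProbabilityVector.FIELDS}

    for r in range(replicates):
        cohort = generate_cohort(
            TrueParameters(pv=true_pv, n_patients=n_patients, seed=int(cohort_seeds[r]))
        )
        observations = aggregate(cohort)
        for j, name in enumerate(ProbabilityVector.FIELDS):
            chain = mh_sample(
                observations[name],
                priors[name],
                SamplerSettings(
                    iterations=settings.iterations,
                    burn_in=settings.burn_in,
                    seed=int(chain_seeds[r, j]),
                    proposal_scale=settings.proposal_scale,
                    adapt=settings.adapt,
                ),
            )
            summary = summarize(chain, level=level)
            means[name][r] = summary.mean
            covered[name][r] = summary.ci_low <= truth[name] <= summary.ci_high

    return RecoveryReport(
        replicates=replicates,
        bias={name: float(means[name].mean() - truth[name]) for name in means},
        coverage={name: float(covered[name].mean()) for name in covered},
        posterior_means=means,
    )


_CSV_COLUMNS = ("high_risk", "cinv_phase1", "cinv_phase2", "received_cycle2",
                "received_cycle3", "evaluable")


def cohort_to_csv(records: Iterable[PatientRecord], path: str | Path) -> None:
    """Write one row per patient with boolean columns as 0/1."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(_CSV_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    int(r.high_risk),
                    int(r.cinv_by_phase[0]),
                    int(r.cinv_by_phase[1]) if len(r.cinv_by_phase) > 1 else 0,
                    int(r.received_cycle2),
                    int(r.received_cycle3),
                    int(r.evaluable),
                ]
            )


def cohort_from_csv(path: str | Path) -> list[PatientRecord]:
    """Read a cohort written by :func:`cohort_to_csv` (or real tabular data
    in the same schema)."""
    records: list[PatientRecord] = []
    with open(path, newline="") as handle:
        for row in csv.DictReader(handle):
            records.append(
                PatientRecord(
                    high_risk=bool(int(row["high_risk"])),
                    cinv_by_phase=(
                        bool(int(row["cinv_phase1"])),
                        bool(int(row["cinv_phase2"])),
                    ),
                    received_cycle2=bool(int(row["received_cycle2"])),
                    received_cycle3=bool(int(row["received_cycle3"])),
                    evaluable=bool(int(row.get("evaluable", 1))),
                )
            )
    return records
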