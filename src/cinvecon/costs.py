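"""Genotyping cost engine: per-test batch costs, branch totals, break-even.

Costs are modelled in USD for one year of service.  A real-time PCR run
processes ``n`` patient samples together with four controls (one negative,
three positive), so reagent and material costs per sample scale as
``(n + 4) / n`` while staff time for the run is split ``1 / n`` ways; the
DNA-extraction reagent is strictly per sample.  The PCR machine is a fixed
investment amortised linearly at a yearly rate.

Economic outputs come in two dose-accounting conventions (see
:mod:`cinvecon.tree`): per-patient figures and break-even thresholds use
intent-to-treat, annual branch totals use dropout-adjusted cycle weights.
:func:`propagate_uncertainty` pushes paired posterior draws through every
economic quantity to obtain equal-tailed credible intervals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .inference import PosteriorChain
from .tree import (
    DoseConvention,
    ProbabilityVector,
    expected_doses_genotyping,
    expected_doses_standard,
)

__all__ = [
    "UnitCosts",
    "BatchCost",
    "ScenarioCost",
    "ThresholdResult",
    "EconomicSummary",
    "NeverBreaksEvenError",
    "per_test_cost",
    "annual_amortization",
    "scenario_costs",
    "drug_cost_reduction",
    "breakeven_threshold",
    "per_patient_difference_percent",
    "propagate_uncertainty",
]

PLANNED_CYCLES = 3


class NeverBreaksEvenError(ValueError):
    """Genotyping can never undercut universal prophylaxis at any volume."""


@dataclass(frozen=True)
class UnitCosts:
    """Every monetary and time parameter of the cost model (USD).

    Defaults reproduce the published price list: fosaprepitant $81.08 per
    150 mg dose; DNA-extraction reagents $1.46 per sample; PCR reagent and
    material prices per *reaction* (a single-sample run is 1 sample + 4
    controls = 5 reactions, so the $8.56 / $1.07 single-test lines divide
    by 5); staff at $1,585.65 per 160-hour month; stage durations 3 h 56 m
    (extraction), 2 h 20 m (PCR), 20 m (reporting); a $36,364.86 machine
    amortised at 20%/year.  The 10% reagent-loss uplift is already folded
    into the unit prices.  ``initial_investment`` is carried for reporting
    only; amortization is computed from ``machine_cost``.
    """

    fosaprepitant_per_dose: float = 81.08
    dna_reagent_per_sample: float = 1.46
    pcr_reagent_per_reaction: float = 8.56 / 5
    pcr_material_per_reaction: float = 1.07 / 5
    controls_per_run: int = 4
    manpower_rate_per_hour: float = 1585.65 / 160
    stage_hours_extraction: float = 3 + 56 / 60
    stage_hours_pcr: float = 2 + 20 / 60
    stage_hours_reporting: float = 20 / 60
    machine_cost: float = 36_364.86
    amortization_rate: float = 0.20
    initial_investment: float = 39_379.97

    def __post_init__(self) -> None:
        monetary = (
            "fosaprepitant_per_dose",
            "dna_reagent_per_sample",
            "pcr_reagent_per_reaction",
            "pcr_material_per_reaction",
            "manpower_rate_per_hour",
            "machine_cost",
            "initial_investment",
        )
        for name in monetary:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.controls_per_run < 0:
            raise ValueError("controls_per_run must be nonnegative")
        if not 0.0 < self.amortization_rate <= 1.0:
            raise ValueError(
                f"amortization_rate must lie in (0, 1], got {self.amortization_rate}"
            )

    @property
    def total_stage_hours(self) -> float:
        return self.stage_hours_extraction + self.stage_hours_pcr + self.stage_hours_reporting


@dataclass(frozen=True)
class BatchCost:
    """Per-sample cost breakdown for one run of ``n_samples`` samples.

    Components are kept at full precision; ``total_per_sample`` is their sum
    rounded to cents last, and is the price used by all downstream
    economics.
    """

    n_samples: int
    manpower_per_sample: float
    dna_reagent_per_sample: float
    pcr_reagent_per_sample: float
    pcr_material_per_sample: float
    total_per_sample: float

    @property
    def component_sum(self) -> float:
        return (
            self.manpower_per_sample
            + self.dna_reagent_per_sample
            + self.pcr_reagent_per_sample
            + self.pcr_material_per_sample
        )


@dataclass(frozen=True)
class ScenarioCost:
    """Annual branch totals for one (cohort size, batch size, convention)."""

    n_patients: int
    batch_size: int
    convention: DoseConvention
    standard_total: float
    genotyping_total: float
    savings: float
    standard_per_patient: float
    genotyping_per_patient: float


@dataclass(frozen=True)
class ThresholdResult:
    """Break-even patient volume with its credible interval."""

    n_star: int
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not self.ci_low <= self.n_star <= self.ci_high:
            raise ValueError(
                f"require ci_low <= n_star <= ci_high, got "
                f"({self.ci_low}, {self.n_star}, {self.ci_high})"
            )


@dataclass(frozen=True)
class EconomicSummary:
    """Point estimate with equal-tailed credible interval for one quantity.

    The point estimate is the quantity evaluated at the posterior-mean
    probabilities; the interval comes from per-draw evaluation, so the point
    sits inside the interval only up to Monte-Carlo noise.
    """

    point_estimate: float
    ci_low: float
    ci_high: float
    quantity_tag: str


def per_test_cost(n_samples: int, costs: UnitCosts | None = None) -> BatchCost:
    """Per-sample genotyping cost when ``n_samples`` share one run.

    Staff time for the run is divided ``1/n`` ways; PCR reagent and material
    cover ``n + controls`` reactions split across the ``n`` billable
    samples; the extraction reagent is constant per sample.
    """
    if costs is None:
        costs = UnitCosts()
    if n_samples < 1:
        raise ValueError(f"n_samples must be at least 1, got {n_samples}")
    if n_samples > 6:
        warnings.warn(
            f"batch size {n_samples} exceeds the 6-sample weekly throughput the "
            "cost model was calibrated for",
            stacklevel=2,
        )
    reactions_per_sample = (n_samples + costs.controls_per_run) / n_samples
    manpower = costs.total_stage_hours * costs.manpower_rate_per_hour / n_samples
    pcr_reagent = costs.pcr_reagent_per_reaction * reactions_per_sample
    pcr_material = costs.pcr_material_per_reaction * reactions_per_sample
    total = manpower + costs.dna_reagent_per_sample + pcr_reagent + pcr_material
    return BatchCost(
        n_samples=n_samples,
        manpower_per_sample=manpower,
        dna_reagent_per_sample=costs.dna_reagent_per_sample,
        pcr_reagent_per_sample=pcr_reagent,
        pcr_material_per_sample=pcr_material,
        total_per_sample=round(total, 2),
    )


def annual_amortization(costs: UnitCosts | None = None) -> float:
    """Yearly linear amortization of the PCR machine."""
    if costs is None:
        costs = UnitCosts()
    return costs.machine_cost * costs.amortization_rate


def scenario_costs(
    pv: ProbabilityVector,
    n_patients: int,
    batch_size: int,
    costs: UnitCosts | None = None,
    convention: DoseConvention = DoseConvention.DROPOUT_ADJUSTED,
) -> ScenarioCost:
    """Annual totals for both branches and the resulting savings.

    Standard branch: drug only.  Genotyping branch: drug plus one test per
    patient at the batch price plus the machine amortization (a fixed yearly
    floor that is charged even for zero patients).
    """
    if costs is None:
        costs = UnitCosts()
    if n_patients < 0:
        raise ValueError(f"n_patients must be nonnegative, got {n_patients}")
    price = costs.fosaprepitant_per_dose
    test = per_test_cost(batch_size, costs).total_per_sample
    standard_pp = float(expected_doses_standard(pv, convention)) * price
    genotyping_drug_pp = float(expected_doses_genotyping(pv, convention)) * price
    standard_total = n_patients * standard_pp
    genotyping_total = n_patients * (genotyping_drug_pp + test) + annual_amortization(costs)
    return ScenarioCost(
        n_patients=n_patients,
        batch_size=batch_size,
        convention=convention,
        standard_total=standard_total,
        genotyping_total=genotyping_total,
        savings=standard_total - genotyping_total,
        standard_per_patient=standard_pp if n_patients else math.nan,
        genotyping_per_patient=genotyping_total / n_patients if n_patients else math.nan,
    )


def _itt_drug_costs(pv: ProbabilityVector, costs: UnitCosts):
    """(standard, genotyping) per-patient drug costs, intent-to-treat."""
    price = costs.fosaprepitant_per_dose
    convention = DoseConvention.INTENT_TO_TREAT
    return (
        expected_doses_standard(pv, convention) * price,
        expected_doses_genotyping(pv, convention) * price,
    )


def drug_cost_reduction(pv: ProbabilityVector, costs: UnitCosts | None = None) -> EconomicSummary:
    """Percent reduction in per-patient drug spend from genotype guidance."""
    if costs is None:
        costs = UnitCosts()
    standard, genotyping = _itt_drug_costs(pv, costs)
    point = float(100.0 * (1.0 - genotyping / standard))
    return EconomicSummary(
        point_estimate=point, ci_low=point, ci_high=point, quantity_tag="reduction percent"
    )


def breakeven_threshold(
    pv: ProbabilityVector, batch_size: int, costs: UnitCosts | None = None
) -> int:
    """Smallest annual patient count at which genotyping becomes cheaper.

    The per-patient margin (standard drug cost minus genotyping drug cost
    minus per-test cost, intent-to-treat) must accumulate past the annual
    amortization: ``n_star = ceil(amortization / margin)``, at least 1.

    Raises :class:`NeverBreaksEvenError` when the margin is nonpositive.
    """
    if costs is None:
        costs = UnitCosts()
    standard, genotyping = _itt_drug_costs(pv, costs)
    margin = float(standard - genotyping) - per_test_cost(batch_size, costs).total_per_sample
    if margin <= 0.0:
        raise NeverBreaksEvenError(
            f"per-patient margin is {margin:.2f} USD; the genotyping branch never "
            "recovers the fixed amortization"
        )
    return max(1, math.ceil(annual_amortization(costs) / margin))


def per_patient_difference_percent(
    pv: ProbabilityVector,
    n_patients: int,
    batch_size: int,
    costs: UnitCosts | None = None,
) -> float:
    """Percent difference in overall (drug + test + amortization share)
    per-patient cost between the branches, intent-to-treat."""
    if costs is None:
        costs = UnitCosts()
    if n_patients <= 0:
        raise ValueError(f"n_patients must be positive, got {n_patients}")
    standard, genotyping = _itt_drug_costs(pv, costs)
    overall = (
        genotyping
        + per_test_cost(batch_size, costs).total_per_sample
        + annual_amortization(costs) / n_patients
    )
    return float(100.0 * (1.0 - overall / standard))


def _paired_draws(chains: Mapping[str, PosteriorChain]) -> ProbabilityVector:
    """Assemble a draw-indexed ProbabilityVector from four equal-length chains."""
    missing = [name for name in ProbabilityVector.FIELDS if name not in chains]
    if missing:
        raise KeyError(f"missing chains for {missing}")
    lengths = {name: len(chains[name].draws) for name in ProbabilityVector.FIELDS}
    if len(set(lengths.values())) != 1:
        raise ValueError(f"chains must have equal retained length, got {lengths}")
    return ProbabilityVector(**{name: chains[name].draws for name in ProbabilityVector.FIELDS})


def propagate_uncertainty(
    chains: Mapping[str, PosteriorChain],
    n_patients: int,
    batch_size: int,
    costs: UnitCosts | None = None,
    level: float = 0.95,
) -> dict[str, EconomicSummary]:
    """Push paired posterior draws through every economic output.

    Draws are paired by index across the four chains (sub-seeded chains are
    independent).  For each draw the per-patient genotyping drug cost, the
    drug-spend reduction, the break-even threshold and the per-patient
    overall difference are evaluated; each is summarised by an equal-tailed
    interval at ``level``, with the point estimate taken at the
    posterior-mean probabilities.  Draws whose margin never breaks even
    contribute an infinite threshold counted in the upper tail.
    """
    if costs is None:
        costs = UnitCosts()
    if not 0.0 < level < 1.0:
        raise ValueError(f"credible level must lie in (0, 1), got {level}")
    if n_patients <= 0:
        raise ValueError(f"n_patients must be positive, got {n_patients}")

    pv_draws = _paired_draws(chains)
    pv_mean = ProbabilityVector(
        **{name: chains[name].mean for name in ProbabilityVector.FIELDS}
    )
    test = per_test_cost(batch_size, costs).total_per_sample
    amort = annual_amortization(costs)

    standard, genotyping = _itt_drug_costs(pv_draws, costs)
    reduction = 100.0 * (1.0 - genotyping / standard)
    margin = standard - genotyping - test
    with np.errstate(divide="ignore"):
        threshold = np.where(margin > 0.0, np.maximum(np.ceil(amort / margin), 1.0), np.inf)
    overall_diff = 100.0 * (1.0 - (genotyping + test + amort / n_patients) / standard)

    std_point, geno_point = _itt_drug_costs(pv_mean, costs)
    tail = (1.0 - level) / 2.0
    quantiles = (tail, 1.0 - tail)

    def summary(draws: np.ndarray, point: float, tag: str, *, integer: bool = False) -> EconomicSummary:
        # inverted_cdf picks order statistics, which is right for the
        # integer-valued threshold and keeps infinite draws in the tail
        method = "inverted_cdf" if integer else "linear"
        lo, hi = np.quantile(draws, quantiles, method=method)
        return EconomicSummary(
            point_estimate=float(point), ci_low=float(lo), ci_high=float(hi), quantity_tag=tag
        )

    try:
        threshold_point: float = float(breakeven_threshold(pv_mean, batch_size, costs))
    except NeverBreaksEvenError:
        threshold_point = math.inf
    return {
        "genotyping_drug_cost_per_patient": summary(
            genotyping, float(geno_point), "per-patient drug cost"
        ),
        "drug_cost_reduction_percent": summary(
            reduction, float(100.0 * (1.0 - geno_point / std_point)), "reduction percent"
        ),
        "breakeven_threshold": summary(threshold, threshold_point, "threshold", integer=True),
        "per_patient_difference_percent": summary(
            overall_diff,
            per_patient_difference_percent(pv_mean, n_patients, batch_size, costs),
            "per-patient overall difference percent",
        ),
    }
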