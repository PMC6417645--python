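"""Cost engine: batch per-test costs, branch totals, break-even thresholds."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cinvecon import (
    DoseConvention,
    NeverBreaksEvenError,
    PosteriorChain,
    ProbabilityVector,
    SamplerSettings,
    UnitCosts,
    annual_amortization,
    breakeven_threshold,
    drug_cost_reduction,
    per_patient_difference_percent,
    per_test_cost,
    propagate_uncertainty,
    scenario_costs,
)

ITT = DoseConvention.INTENT_TO_TREAT
DROPOUT = DoseConvention.DROPOUT_ADJUSTED

# Published per-test totals by batch size (the n=4 cell carries the source
# table's own +-$0.01 rounding drift).
PUBLISHED_TOTALS = {1: 76.50, 2: 39.94, 3: 27.76, 4: 21.67, 5: 18.01, 6: 15.57}


@pytest.mark.parametrize("n_samples, expected", sorted(PUBLISHED_TOTALS.items()))
def test_per_test_total_matches_published_table(n_samples, expected):
    assert per_test_cost(n_samples).total_per_sample == pytest.approx(expected, abs=0.011)


def test_single_test_component_breakdown():
    batch = per_test_cost(1)
    costs = UnitCosts()
    rate = costs.manpower_rate_per_hour
    assert costs.stage_hours_extraction * rate == pytest.approx(38.98, abs=0.01)
    assert costs.stage_hours_pcr * rate == pytest.approx(23.12, abs=0.01)
    assert costs.stage_hours_reporting * rate == pytest.approx(3.30, abs=0.01)
    assert batch.dna_reagent_per_sample == pytest.approx(1.46)
    assert batch.pcr_reagent_per_sample == pytest.approx(8.56, abs=0.01)
    assert batch.pcr_material_per_sample == pytest.approx(1.07, abs=0.01)
    assert batch.total_per_sample == pytest.approx(round(batch.component_sum, 2))


def test_per_test_cost_scaling_laws():
    """Manpower splits 1/n; reagents cover (n + 4 controls)/n reactions."""
    one = per_test_cost(1)
    for n in range(2, 7):
        batch = per_test_cost(n)
        assert batch.manpower_per_sample == pytest.approx(one.manpower_per_sample / n)
        assert batch.pcr_reagent_per_sample == pytest.approx(
            one.pcr_reagent_per_sample * (n + 4) / (5 * n)
        )
        assert batch.dna_reagent_per_sample == one.dna_reagent_per_sample
    totals = [per_test_cost(n).total_per_sample for n in range(1, 7)]
    assert all(a > b for a, b in zip(totals, totals[1:]))


def test_per_test_cost_large_batch_limit_and_errors():
    with pytest.raises(ValueError):
        per_test_cost(0)
    with pytest.warns(UserWarning):
        huge = per_test_cost(100_000)
    # manpower and control overhead amortize away, leaving pure reagent cost
    assert huge.total_per_sample == pytest.approx(1.46 + 8.56 / 5 + 1.07 / 5, abs=0.01)


def test_annual_amortization():
    assert round(annual_amortization(), 2) == 7272.97
    assert annual_amortization(UnitCosts(amortization_rate=1.0)) == pytest.approx(36_364.86)
    assert round(annual_amortization(UnitCosts(amortization_rate=0.10)), 2) == 3636.49


def test_scenario_totals_match_published_figures(pv_printed_means):
    two = scenario_costs(pv_printed_means, 300, 2, convention=DROPOUT)
    assert two.standard_total == pytest.approx(64_569.75, rel=1e-3)
    assert two.genotyping_total == pytest.approx(60_314.65, rel=1e-3)
    assert two.savings == pytest.approx(4_255.10, rel=2e-3)
    six = scenario_costs(pv_printed_means, 300, 6, convention=DROPOUT)
    assert six.genotyping_total == pytest.approx(53_003.72, rel=1e-3)
    assert six.savings == pytest.approx(11_566.02, rel=2e-3)
    assert two.savings == pytest.approx(two.standard_total - two.genotyping_total)


def test_scenario_zero_patients_hits_amortization_floor(pv_printed_means):
    empty = scenario_costs(pv_printed_means, 0, 2, convention=DROPOUT)
    assert empty.standard_total == 0.0
    assert empty.genotyping_total == pytest.approx(annual_amortization())
    assert math.isnan(empty.standard_per_patient)


def test_drug_cost_reduction_examples(pv_printed_means):
    assert drug_cost_reduction(pv_printed_means).point_estimate == pytest.approx(
        35.83, abs=0.3
    )
    all_high = ProbabilityVector(1 - 1e-12, 0.139, 0.947, 0.748)
    assert drug_cost_reduction(all_high).point_estimate == pytest.approx(0.0, abs=1e-6)
    nobody = ProbabilityVector(1e-12, 1e-12, 0.947, 0.748)
    assert drug_cost_reduction(nobody).point_estimate == pytest.approx(100.0, abs=1e-6)


def test_breakeven_thresholds_match_published(pv_printed_means):
    assert breakeven_threshold(pv_printed_means, 2) == 155
    assert breakeven_threshold(pv_printed_means, 6) == 102


def test_breakeven_without_fixed_cost_is_one(pv_printed_means):
    free_machine = UnitCosts(machine_cost=0.0)
    assert breakeven_threshold(pv_printed_means, 2, free_machine) == 1


def test_breakeven_never_breaks_even():
    nearly_all_high = ProbabilityVector(0.999, 0.9, 0.947, 0.748)
    with pytest.raises(NeverBreaksEvenError):
        breakeven_threshold(nearly_all_high, 1)


@given(
    pv=st.builds(
        ProbabilityVector,
        st.floats(0.05, 0.9), st.floats(0.01, 0.5),
        st.floats(0.5, 0.99), st.floats(0.5, 0.99),
    ),
    batch=st.integers(1, 6),
)
def test_threshold_consistency_with_scenario_totals(pv, batch):
    """At n_star the genotyping branch is no dearer; at n_star - 1 it is."""
    try:
        n_star = breakeven_threshold(pv, batch)
    except NeverBreaksEvenError:
        return
    at = scenario_costs(pv, n_star, batch, convention=ITT)
    assert at.genotyping_total <= at.standard_total + 1e-6
    if n_star > 1:
        below = scenario_costs(pv, n_star - 1, batch, convention=ITT)
        assert below.genotyping_total > below.standard_total


def test_threshold_monotone_in_fixed_and_test_costs(pv_printed_means):
    base = breakeven_threshold(pv_printed_means, 2)
    pricier_machine = UnitCosts(machine_cost=50_000.0)
    assert breakeven_threshold(pv_printed_means, 2, pricier_machine) >= base
    assert breakeven_threshold(pv_printed_means, 1) >= base  # dearer per-test


def test_per_patient_difference_examples(pv_printed_means):
    assert per_patient_difference_percent(pv_printed_means, 300, 6) == pytest.approx(
        19.46, abs=0.2
    )
    assert per_patient_difference_percent(pv_printed_means, 300, 2) == pytest.approx(
        9.45, abs=0.2
    )
    # with free testing and no machine the difference is the drug reduction
    free = UnitCosts(
        dna_reagent_per_sample=0.0, pcr_reagent_per_reaction=0.0,
        pcr_material_per_reaction=0.0, manpower_rate_per_hour=0.0, machine_cost=0.0,
    )
    assert per_patient_difference_percent(pv_printed_means, 300, 2, free) == pytest.approx(
        drug_cost_reduction(pv_printed_means, free).point_estimate
    )


def _degenerate_chains(pv: ProbabilityVector, n: int = 50):
    settings = SamplerSettings(iterations=n, burn_in=0, seed=0)
    return {
        name: PosteriorChain(np.full(n, getattr(pv, name)), 0.5, settings)
        for name in ProbabilityVector.FIELDS
    }


def test_propagation_collapses_for_degenerate_chains(pv_printed_means):
    summaries = propagate_uncertainty(_degenerate_chains(pv_printed_means), 300, 2)
    for summary in summaries.values():
        assert summary.ci_low == pytest.approx(summary.point_estimate, abs=1e-9)
        assert summary.ci_high == pytest.approx(summary.point_estimate, abs=1e-9)
    assert summaries["breakeven_threshold"].point_estimate == 155


def test_propagation_counts_never_breakeven_draws_as_infinite(pv_printed_means):
    dear_test = UnitCosts(dna_reagent_per_sample=300.0)
    summaries = propagate_uncertainty(
        _degenerate_chains(pv_printed_means), 300, 2, costs=dear_test
    )
    assert math.isinf(summaries["breakeven_threshold"].ci_high)


def test_propagation_input_validation(chains):
    with pytest.raises(KeyError):
        propagate_uncertainty({"p_high_risk": chains["p_high_risk"]}, 300, 2)
    with pytest.raises(ValueError):
        propagate_uncertainty(chains, 300, 2, level=1.5)
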