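"""End-to-end pipeline: inference, economics, tables and figure data.

Every public function is a thin orchestration of the library modules; the
report bundle mirrors the published result tables — a posterior summary
table, a per-test batch-cost table, scenario totals, break-even thresholds
with credible intervals, chain diagnostics and a run manifest.  Identical
configuration (including the seed) reproduces every table byte for byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import AnalysisConfig, config_hash
from .costs import (
    EconomicSummary,
    NeverBreaksEvenError,
    ThresholdResult,
    annual_amortization,
    breakeven_threshold,
    per_test_cost,
    propagate_uncertainty,
    scenario_costs,
)
from .inference import PosteriorChain, diagnose, mh_sample, summarize
from .tree import DoseConvention, ProbabilityVector, expected_doses_genotyping

__all__ = ["RunReport", "run_inference", "posterior_mean_vector", "run_full_analysis",
           "figure_data"]

logger = logging.getLogger("cinvecon")

_SUBSEED_BOUND = 2**31 - 1


@dataclass
class RunReport:
    """In-memory handles to everything a full run produced."""

    chains: dict[str, PosteriorChain]
    posterior_table: pd.DataFrame
    batch_costs: pd.DataFrame
    scenarios: pd.DataFrame
    thresholds: dict[int, ThresholdResult]
    economics: dict[int, dict[str, EconomicSummary]]
    diagnostics: dict[str, dict[str, float]]
    manifest: dict


def run_inference(config: AnalysisConfig) -> dict[str, PosteriorChain]:
    """Run one MH chain per probability with deterministic sub-seeds.

    The four chains are mutually independent but jointly reproducible: the
    config's master seed feeds a generator that hands each probability its
    own sub-seed.
    """
    rng = np.random.default_rng(config.sampler.seed)
    sub_seeds = rng.integers(_SUBSEED_BOUND, size=len(ProbabilityVector.FIELDS))
    chains: dict[str, PosteriorChain] = {}
    for name, sub_seed in zip(ProbabilityVector.FIELDS, sub_seeds):
        start = time.perf_counter()
        chains[name] = mh_sample(
            config.observations[name],
            config.priors[name],
            replace(config.sampler, seed=int(sub_seed)),
        )
        logger.info(
            "stage=infer probability=%s sub_seed=%d elapsed=%.3fs",
            name, int(sub_seed), time.perf_counter() - start,
        )
    return chains


def posterior_mean_vector(chains: dict[str, PosteriorChain]) -> ProbabilityVector:
    """Posterior means of the four chains as one probability vector."""
    return ProbabilityVector(**{name: chains[name].mean for name in ProbabilityVector.FIELDS})


def posterior_table(config: AnalysisConfig, chains: dict[str, PosteriorChain]) -> pd.DataFrame:
    rows = []
    for name in ProbabilityVector.FIELDS:
        obs, prior = config.observations[name], config.priors[name]
        summary = summarize(chains[name], level=config.credible_level)
        rows.append(
            {
                "probability": name,
                "events": obs.events,
                "total": obs.total,
                "prior_alpha": prior.alpha,
                "prior_beta": prior.beta,
                "mean": summary.mean,
                "median": summary.median,
                "ci_low": summary.ci_low,
                "ci_high": summary.ci_high,
            }
        )
    return pd.DataFrame(rows)


def batch_cost_table(config: AnalysisConfig, max_batch: int = 6) -> pd.DataFrame:
    """Per-test cost components (rows) by batch size (columns 1..max_batch)."""
    components = {
        "extraction_manpower": [], "extraction_reagents": [], "pcr_manpower": [],
        "pcr_material": [], "pcr_reagents": [], "reporting_manpower": [], "total": [],
    }
    costs = config.unit_costs
    manpower_total = costs.total_stage_hours
    for n in range(1, max_batch + 1):
        batch = per_test_cost(n, costs)
        # split the pooled manpower back into the three stage lines
        for stage, hours in (
            ("extraction_manpower", costs.stage_hours_extraction),
            ("pcr_manpower", costs.stage_hours_pcr),
            ("reporting_manpower", costs.stage_hours_reporting),
        ):
            components[stage].append(batch.manpower_per_sample * hours / manpower_total)
        components["extraction_reagents"].append(batch.dna_reagent_per_sample)
        components["pcr_reagents"].append(batch.pcr_reagent_per_sample)
        components["pcr_material"].append(batch.pcr_material_per_sample)
        components["total"].append(batch.total_per_sample)
    frame = pd.DataFrame(components, index=range(1, max_batch + 1)).T
    frame.columns = [f"n={n}" for n in frame.columns]
    frame.index.name = "component"
    return frame


def scenario_table(config: AnalysisConfig, pv: ProbabilityVector) -> pd.DataFrame:
    rows = []
    for n in config.n_patients:
        for batch in config.batch_sizes:
            for convention in config.conventions:
                sc = scenario_costs(pv, n, batch, config.unit_costs, convention)
                rows.append(
                    {
                        "n_patients": sc.n_patients,
                        "batch_size": sc.batch_size,
                        "convention": sc.convention.value,
                        "standard_total": sc.standard_total,
                        "genotyping_total": sc.genotyping_total,
                        "savings": sc.savings,
                        "standard_per_patient": sc.standard_per_patient,
                        "genotyping_per_patient": sc.genotyping_per_patient,
                    }
                )
    return pd.DataFrame(rows)


def _economics_json(economics: dict[int, dict[str, EconomicSummary]]) -> dict:
    return {
        f"batch_{batch}": {
            key: {
                "point_estimate": summary.point_estimate,
                "ci_low": summary.ci_low,
                "ci_high": summary.ci_high,
                "quantity_tag": summary.quantity_tag,
            }
            for key, summary in per_batch.items()
        }
        for batch, per_batch in economics.items()
    }


def run_full_analysis(config: AnalysisConfig, output_dir: str | Path | None = None) -> RunReport:
    """Run the whole pipeline and write the report bundle.

    Writes ``posterior_table.csv``, ``batch_costs.csv``, ``scenarios.csv``,
    ``summary.json``, ``diagnostics.json`` and ``manifest.json`` under the
    output directory.
    """
    out = Path(output_dir if output_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []

    chains = run_inference(config)
    pv = posterior_mean_vector(chains)

    diagnostics: dict[str, dict[str, float]] = {}
    for name, chain in chains.items():
        diag = diagnose(chain, max_lag=min(50, len(chain.draws) - 1))
        diagnostics[name] = {
            "effective_sample_size": diag.effective_sample_size,
            "efficiency": diag.efficiency,
            "acceptance_rate": chain.acceptance_rate,
        }
        if diag.efficiency < 0.01:
            warnings.append(f"chain {name}: efficiency {diag.efficiency:.4f} below 1%")

    table = posterior_table(config, chains)
    batch_costs = batch_cost_table(config)
    scenarios = scenario_table(config, pv)

    thresholds: dict[int, ThresholdResult] = {}
    economics: dict[int, dict[str, EconomicSummary]] = {}
    n_reference = max(config.n_patients)
    for batch in config.batch_sizes:
        start = time.perf_counter()
        summaries = propagate_uncertainty(
            chains, n_reference, batch, config.unit_costs, config.credible_level
        )
        economics[batch] = summaries
        try:
            n_star = breakeven_threshold(pv, batch, config.unit_costs)
        except NeverBreaksEvenError as exc:
            warnings.append(f"batch {batch}: {exc}")
            continue
        thr = summaries["breakeven_threshold"]
        thresholds[batch] = ThresholdResult(
            n_star=n_star, ci_low=thr.ci_low, ci_high=thr.ci_high
        )
        logger.info(
            "stage=economics batch=%d threshold=%d elapsed=%.3fs",
            batch, n_star, time.perf_counter() - start,
        )

    manifest = {
        "package": "cinvecon",
        "version": __version__,
        "seed": config.sampler.seed,
        "config_hash": config_hash(config),
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "credible_level": config.credible_level,
        "annual_amortization": round(annual_amortization(config.unit_costs), 2),
        "warnings": warnings,
    }

    table.to_csv(out / "posterior_table.csv", index=False)
    batch_costs.to_csv(out / "batch_costs.csv")
    scenarios.to_csv(out / "scenarios.csv", index=False)
    (out / "summary.json").write_text(
        json.dumps(
            {
                "posterior_means": {k: chains[k].mean for k in chains},
                "thresholds": {
                    f"batch_{b}": {"n_star": t.n_star, "ci_low": t.ci_low, "ci_high": t.ci_high}
                    for b, t in thresholds.items()
                },
                "economics": _economics_json(economics),
            },
            indent=2,
        )
    )
    (out / "diagnostics.json").write_text(json.dumps(diagnostics, indent=2))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    for name, chain in chains.items():
        np.savetxt(out / f"draws_{name}.csv", chain.draws, header=name, comments="# ")

    return RunReport(
        chains=chains,
        posterior_table=table,
        batch_costs=batch_costs,
        scenarios=scenarios,
        thresholds=thresholds,
        economics=economics,
        diagnostics=diagnostics,
        manifest=manifest,
    )


def figure_data(
    config: AnalysisConfig,
    chains: dict[str, PosteriorChain] | None = None,
    output_dir: str | Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Tabular series behind the result figures.

    * ``savings_by_batch_size`` — annual savings versus batch size (1..6),
      dropout-adjusted totals at the largest configured cohort;
    * ``cumulative_costs`` — branch totals versus annual patient count for
      each configured batch size;
    * ``per_patient_costs`` — overall per-patient cost versus patient count
      with the credible band from the posterior draws, intent-to-treat.
    """
    if chains is None:
        chains = run_inference(config)
    pv = posterior_mean_vector(chains)
    costs = config.unit_costs
    n_max = max(config.n_patients)

    savings = pd.DataFrame(
        {
            "batch_size": list(range(1, 7)),
            "annual_savings": [
                scenario_costs(pv, n_max, b, costs, DoseConvention.DROPOUT_ADJUSTED).savings
                for b in range(1, 7)
            ],
        }
    )

    patient_axis = np.arange(1, n_max + 1)
    cumulative = {"n_patients": patient_axis}
    per_patient = {"n_patients": patient_axis}
    std_pp_itt = 3.0 * costs.fosaprepitant_per_dose
    per_patient["standard_per_patient"] = np.full(n_max, std_pp_itt)
    amort = annual_amortization(costs)
    pv_draws = ProbabilityVector(**{k: chains[k].draws for k in ProbabilityVector.FIELDS})
    drug_draws = costs.fosaprepitant_per_dose * np.asarray(
        expected_doses_genotyping(pv_draws, DoseConvention.INTENT_TO_TREAT)
    )
    drug_point = costs.fosaprepitant_per_dose * expected_doses_genotyping(
        pv, DoseConvention.INTENT_TO_TREAT
    )
    tail = (1.0 - config.credible_level) / 2.0
    for batch in config.batch_sizes:
        test = per_test_cost(batch, costs).total_per_sample
        sc = [
            scenario_costs(pv, int(n), batch, costs, DoseConvention.DROPOUT_ADJUSTED)
            for n in patient_axis
        ]
        cumulative[f"standard_total_batch{batch}"] = [s.standard_total for s in sc]
        cumulative[f"genotyping_total_batch{batch}"] = [s.genotyping_total for s in sc]
        overall_point = drug_point + test + amort / patient_axis
        lo_drug, hi_drug = np.quantile(drug_draws, [tail, 1.0 - tail])
        per_patient[f"genotyping_per_patient_batch{batch}"] = overall_point
        per_patient[f"genotyping_ci_low_batch{batch}"] = lo_drug + test + amort / patient_axis
        per_patient[f"genotyping_ci_high_batch{batch}"] = hi_drug + test + amort / patient_axis

    frames = {
        "savings_by_batch_size": savings,
        "cumulative_costs": pd.DataFrame(cumulative),
        "per_patient_costs": pd.DataFrame(per_patient),
    }
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, frame in frames.items():
            frame.to_csv(out / f"{name}.csv", index=False)
    return frames
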