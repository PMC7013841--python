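"""Replicated simulation experiments over the full analysis chain.

These drive the package's validation story: plant known effect sizes with
the synthetic generator, run the estimation pipeline, and check that the
estimates recover the truth.  Exposure is drawn at the daily level with no
outages here so the experiments measure the estimator, not the imputation
stage (which has its own tests).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .aggregation import build_daily_exposure
from .breakpoints import load_breakpoint_table
from .indices import add_indices
from .linkage import match_visits
from .models import fit_ladder
from .simulate import (
    PollutantGenParams,
    RegistryGenParams,
    scale_patients,
    simulate_daily_exposure,
    simulate_hourly_pollutants,
    simulate_registry,
)

#: Five calendar years of daily exposure, the study's observation span.
STUDY_DAYS = 1826


def _replicate_seeds(base_seed: int, replicate: int) -> tuple[int, int]:
    state = np.random.SeedSequence([base_seed, replicate]).generate_state(2)
    return int(state[0] % (2**31)), int(state[1] % (2**31))


def recovery_estimates(
    response: str,
    term: str,
    n_replicates: int,
    base_seed: int,
    *,
    target_visits: int = 9875,
    true_effects: dict | None = None,
    model: str = "M4",
) -> np.ndarray:
    """Fitted coefficient for ``term`` across independent replicates.

    Each replicate draws fresh exposure (complete, five years, six
    governorates) and a fresh registry with the planted effects, links
    them, computes the indices and fits the requested model.
    """
    estimates = []
    for replicate in range(1, n_replicates + 1):
        exp_seed, reg_seed = _replicate_seeds(base_seed, replicate)
        exposure = simulate_daily_exposure(
            PollutantGenParams(seed=exp_seed, missing_rates={}), STUDY_DAYS
        )
        params = scale_patients(
            RegistryGenParams(planted_response=response, seed=reg_seed),
            target_visits,
        )
        if true_effects is not None:
            params = replace(params, true_effects=true_effects)
        registry = simulate_registry(params, exposure)
        linked, _ = match_visits(add_indices(registry), exposure)
        fit = fit_ladder(linked, response, [model])[model]
        estimates.append(float(fit.coefficient(term).beta))
    return np.asarray(estimates)


def null_coverage(
    term: str,
    n_replicates: int,
    base_seed: int,
    *,
    target_visits: int = 2000,
    response: str = "das28",
) -> float:
    """Fraction of replicates whose 95% CI covers zero under null effects.

    Pollutant effects are set to zero while the clinical effects stay at
    their defaults, so the pollutant columns are pure noise predictors.
    """
    effects = {k: dict(v) for k, v in RegistryGenParams().true_effects.items()}
    for key in ("no2", "o3", "so2", "co", "pm10"):
        effects[response][key] = 0.0
    covered = 0
    for replicate in range(1, n_replicates + 1):
        exp_seed, reg_seed = _replicate_seeds(base_seed, replicate)
        exposure = simulate_daily_exposure(
            PollutantGenParams(seed=exp_seed, missing_rates={}), STUDY_DAYS
        )
        params = scale_patients(
            RegistryGenParams(
                planted_response=response, true_effects=effects, seed=reg_seed
            ),
            target_visits,
        )
        registry = simulate_registry(params, exposure)
        linked, _ = match_visits(add_indices(registry), exposure)
        fit = fit_ladder(linked, response, ["M3"])["M3"]
        row = fit.coefficient(term)
        if row.ci_low <= 0.0 <= row.ci_high:
            covered += 1
    return covered / n_replicates


def generator_correlation(
    pollutant_a: str,
    pollutant_b: str,
    n_days: int,
    seed: int,
) -> tuple[float, int]:
    """Daily-AQI Pearson correlation through the hourly pipeline.

    Simulates hourly readings at default calibration for one station,
    aggregates to daily AQI and correlates the two pollutant series on
    pairwise-complete days.  Returns (r, number of complete pairs).
    """
    table = load_breakpoint_table()
    hourly = simulate_hourly_pollutants(
        PollutantGenParams(seed=seed), n_days, governorates=("Farwaniya",),
        breakpoint_table=table,
    )
    exposure = build_daily_exposure(hourly, table)
    pair = exposure[[f"aqi_{pollutant_a}", f"aqi_{pollutant_b}"]].dropna()
    r = float(np.corrcoef(pair.iloc[:, 0], pair.iloc[:, 1])[0, 1])
    return r, len(pair)
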