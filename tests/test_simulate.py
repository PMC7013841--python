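"""Synthetic generator: determinism, calibration and planted structure."""

import numpy as np
import pandas as pd
import pytest

from aqra.aggregation import build_daily_exposure
from aqra.indices import add_indices
from aqra.linkage import match_visits
from aqra.models import fit_ladder
from aqra.simulate import (
    GOVERNORATES,
    POLLUTANT_ORDER,
    PollutantGenParams,
    RegistryGenParams,
    latent_correlation,
    scale_patients,
    simulate_daily_exposure,
    simulate_hourly_pollutants,
    simulate_registry,
)


class TestHourlyGenerator:
    def test_counts_single_day(self, kuwait_table):
        params = PollutantGenParams(seed=0, missing_rates={})
        hourly = simulate_hourly_pollutants(
            params, 1, governorates=("Ahmadi",), breakpoint_table=kuwait_table
        )
        assert len(hourly) == 24 * 5
        assert hourly["concentration"].notna().all()

    def test_deterministic_given_seed(self, kuwait_table):
        params = PollutantGenParams(seed=5)
        a = simulate_hourly_pollutants(params, 30, governorates=("Jahra",))
        b = simulate_hourly_pollutants(params, 30, governorates=("Jahra",))
        pd.testing.assert_frame_equal(a, b)

    def test_masking_rate_recovered_daily(self, kuwait_table):
        params = PollutantGenParams(seed=21)
        hourly = simulate_hourly_pollutants(
            params, 1500, governorates=("Farwaniya",), breakpoint_table=kuwait_table
        )
        exposure = build_daily_exposure(hourly, kuwait_table)
        so2_missing = exposure["aqi_SO2"].isna().mean()
        assert so2_missing == pytest.approx(0.484, abs=0.05)

    def test_aggregation_recovers_drawn_daily_values(self, kuwait_table):
        """The hourly expansion is exact for the 24-h mean pollutants."""
        params = PollutantGenParams(seed=9, missing_rates={})
        hourly = simulate_hourly_pollutants(
            params, 200, governorates=("Hawally",), breakpoint_table=kuwait_table
        )
        direct = simulate_daily_exposure(
            params, 200, governorates=("Hawally",), breakpoint_table=kuwait_table
        )
        aggregated = build_daily_exposure(hourly, kuwait_table)
        for pollutant in ("PM10", "NO2", "SO2"):
            np.testing.assert_allclose(
                aggregated[f"aqi_{pollutant}"].to_numpy(),
                direct[f"aqi_{pollutant}"].to_numpy(),
                atol=1e-9,
            )

    def test_diurnal_cycle_preserves_daily_mean(self, kuwait_table):
        flat = PollutantGenParams(seed=4, missing_rates={})
        wavy = PollutantGenParams(seed=4, missing_rates={}, diurnal_amplitude=0.3)
        exp_flat = build_daily_exposure(
            simulate_hourly_pollutants(flat, 50, governorates=("Ahmadi",)),
            kuwait_table,
        )
        exp_wavy = build_daily_exposure(
            simulate_hourly_pollutants(wavy, 50, governorates=("Ahmadi",)),
            kuwait_table,
        )
        np.testing.assert_allclose(
            exp_flat["aqi_PM10"], exp_wavy["aqi_PM10"], rtol=1e-9
        )


class TestDailyGenerator:
    def test_latent_correlation_is_positive_definite(self):
        latent = latent_correlation(PollutantGenParams())
        eigvals = np.linalg.eigvalsh(latent.to_numpy())
        assert eigvals.min() > 0

    def test_marginal_calibration(self):
        """Daily AQI mean/SD approximate the declared targets."""
        params = PollutantGenParams(seed=77, missing_rates={})
        daily = simulate_daily_exposure(params, 8000, governorates=("Ahmadi",))
        for pollutant in ("NO2", "SO2", "O3", "CO"):
            col = daily[f"aqi_{pollutant}"]
            assert col.mean() == pytest.approx(
                params.aqi_mean[pollutant], rel=0.05
            )
            assert col.std() == pytest.approx(params.aqi_sd[pollutant], rel=0.10)

    def test_correlation_calibration(self):
        params = PollutantGenParams(seed=31, missing_rates={})
        daily = simulate_daily_exposure(params, 10_000, governorates=("Ahmadi",))
        r = np.corrcoef(daily["aqi_NO2"], daily["aqi_SO2"])[0, 1]
        assert r == pytest.approx(0.51, abs=0.03)

    def test_masking_fractions(self):
        params = PollutantGenParams(seed=13)
        daily = simulate_daily_exposure(params, 6000, governorates=("Ahmadi",))
        for pollutant, rate in params.missing_rates.items():
            assert daily[f"aqi_{pollutant}"].isna().mean() == pytest.approx(
                rate, abs=0.02
            )

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            PollutantGenParams(missing_rates={"SO2": 1.2})
        with pytest.raises(ValueError):
            simulate_daily_exposure(PollutantGenParams(), 0)


class TestRegistryGenerator:
    def test_single_patient_single_visit(self, complete_exposure):
        params = RegistryGenParams(n_patients=1, visit_geometric_p=0.999, seed=2)
        registry = simulate_registry(params, complete_exposure)
        assert len(registry) >= 1
        row = registry.iloc[0]
        assert 0 <= row["tjc28"] <= 28
        assert row["governorate"] in GOVERNORATES

    def test_deterministic_given_seed(self, complete_exposure):
        params = RegistryGenParams(n_patients=50, seed=8)
        a = simulate_registry(params, complete_exposure)
        b = simulate_registry(params, complete_exposure)
        pd.testing.assert_frame_equal(a, b)

    def test_component_ranges_respected(self, complete_exposure):
        for response in ("das28", "cdai"):
            params = RegistryGenParams(
                n_patients=400, planted_response=response, seed=6
            )
            registry = simulate_registry(params, complete_exposure)
            assert registry["tjc28"].between(0, 28).all()
            assert registry["sjc28"].between(0, 28).all()
            assert registry["gh"].between(0, 100).all()
            assert registry["pagh"].between(0, 10).all()
            assert registry["prgh"].between(0, 10).all()
            assert (registry["esr"] > 0).all()
            assert (registry["crp"] > 0).all()

    def test_demographic_marginals(self, complete_exposure):
        params = scale_patients(RegistryGenParams(seed=41), 9875)
        registry = simulate_registry(params, complete_exposure)
        assert len(registry) == pytest.approx(9875, rel=0.1)
        assert (registry["gender"] == "female").mean() == pytest.approx(
            0.608, abs=0.02
        )
        assert (registry["nationality"] == "Kuwaiti").mean() == pytest.approx(
            0.586, abs=0.02
        )
        assert (registry["rf_status"] == "positive").mean() == pytest.approx(
            0.746, abs=0.02
        )

    def test_visits_per_patient_within_registry_range(self, complete_exposure):
        params = RegistryGenParams(n_patients=800, seed=14)
        registry = simulate_registry(params, complete_exposure)
        counts = registry.groupby("patient_id").size()
        assert counts.min() >= 1
        assert counts.max() <= 49

    def test_null_effects_yield_null_pollutant_coefficients(self, complete_exposure):
        """With zero planted pollutant effects, M3 estimates center on 0."""
        effects = {k: dict(v) for k, v in RegistryGenParams().true_effects.items()}
        for key in ("no2", "o3", "so2", "co", "pm10"):
            effects["das28"][key] = 0.0
        estimates = []
        for seed in range(20):
            params = RegistryGenParams(
                n_patients=300, true_effects=effects, seed=seed
            )
            registry = simulate_registry(params, complete_exposure)
            linked, _ = match_visits(add_indices(registry), complete_exposure)
            fit = fit_ladder(linked, "das28", ["M3"])["M3"]
            estimates.append(fit.coefficient("aqi_NO2").beta)
        estimates = np.array(estimates)
        se = estimates.std(ddof=1) / np.sqrt(len(estimates))
        assert abs(estimates.mean()) < 3 * se + 1e-4

    def test_coverage_gap_rejected(self, complete_exposure):
        gappy = complete_exposure[
            complete_exposure["governorate"] != "Jahra"
        ]
        with pytest.raises(ValueError, match="Jahra"):
            simulate_registry(RegistryGenParams(n_patients=5, seed=1), gappy)
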