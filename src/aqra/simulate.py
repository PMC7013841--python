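"""Synthetic monitor streams and visit registry with planted structure.

The generator emulates the two confidential sources the analysis needs:

* **Exposure** — daily AQI values per governorate are drawn from a
  multivariate lognormal whose marginal mean/SD and pairwise Pearson
  correlations are declared calibration targets (defaults: the observed
  exposure distribution and pollutant correlation structure).  Latent
  log-scale parameters are derived in closed form: moment matching for
  the marginals and the bivariate-lognormal identity

      corr(X_i, X_j) = (exp(rho_ij s_i s_j) - 1)
                       / sqrt((exp(s_i^2) - 1)(exp(s_j^2) - 1))

  inverted for the latent correlation ``rho_ij``.  Drawn index values are
  realized as physical concentrations through the inverse breakpoint
  conversion and expanded to hourly readings, so the aggregation pipeline
  recovers the drawn daily values.  Whole-day monitor outages are masked
  completely at random at per-pollutant rates.

* **Registry** — patients with demographic marginals matching the study
  population make a geometric number of visits (1--49).  Clinical
  components are drawn from skewed distributions, and the tender-joint
  count is then solved from the structural index equation so that the
  chosen response satisfies a linear generative model
  ``response = intercept + sum(beta_k x_k) + noise`` with planted
  exposure coefficients.  The two composite indices share components, so
  a dataset plants the linear model for one response at a time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .breakpoints import (
    BreakpointTable,
    concentration_for_index,
    load_breakpoint_table,
)

POLLUTANT_ORDER = ("PM10", "NO2", "SO2", "O3", "CO")

GOVERNORATES = (
    "Ahmadi",
    "Farwaniya",
    "Hawally",
    "Jahra",
    "Kuwait City",
    "Mubarak Alkabeer",
)

#: One fixed monitoring station per governorate.
STATIONS = {g: f"KEPA-{g.replace(' ', '')[:4].upper()}" for g in GOVERNORATES}

#: Observed share of visits per governorate (patient home address).
GOVERNORATE_WEIGHTS = {
    "Ahmadi": 356 / 9875,
    "Farwaniya": 4378 / 9875,
    "Hawally": 1272 / 9875,
    "Jahra": 226 / 9875,
    "Kuwait City": 3007 / 9875,
    "Mubarak Alkabeer": 636 / 9875,
}

#: Daily-AQI calibration targets: marginal mean/SD per pollutant.
DEFAULT_AQI_MEAN = {"PM10": 144.87, "NO2": 43.74, "SO2": 14.26, "O3": 17.19, "CO": 1.39}
DEFAULT_AQI_SD = {"PM10": 100.64, "NO2": 23.13, "SO2": 15.42, "O3": 9.90, "CO": 0.66}

#: Daily-AQI pairwise Pearson correlation targets.
DEFAULT_AQI_CORRELATION = {
    ("NO2", "O3"): -0.12,
    ("NO2", "SO2"): 0.51,
    ("NO2", "CO"): 0.22,
    ("NO2", "PM10"): -0.12,
    ("O3", "SO2"): -0.09,
    ("O3", "CO"): 0.02,
    ("O3", "PM10"): 0.08,
    ("SO2", "CO"): 0.07,
    ("SO2", "PM10"): -0.03,
    ("CO", "PM10"): -0.05,
}

#: Daily missing fractions per pollutant (whole-day monitor outages).
DEFAULT_MISSING_RATES = {
    "PM10": 0.058,
    "NO2": 0.016,
    "SO2": 0.484,
    "O3": 0.053,
    "CO": 0.065,
}

#: Planted linear effects per response; keys name registry/exposure terms.
DEFAULT_TRUE_EFFECTS = {
    "das28": {
        "intercept": 1.506,
        "swollen": 0.226,
        "rf_positive": 0.004,
        "acpa_positive": 0.007,
        "esr": 0.035,
        "crp": 0.001,
        "no2": 0.003,
        "o3": 0.003,
        "so2": 0.003,
        "co": -0.001,
        "pm10": 0.00003,
    },
    "cdai": {
        "intercept": 2.540,
        "swollen": 3.035,
        "rf_positive": -0.066,
        "acpa_positive": -0.594,
        "esr": 0.085,
        "crp": -0.171,
        "no2": 0.048,
        "o3": 0.039,
        "so2": 0.044,
        "co": 0.185,
        "pm10": 0.0004,
    },
}

_EFFECT_COLUMNS = {
    "swollen": "sjc28",
    "rf_positive": "_rf_ind",
    "acpa_positive": "_acpa_ind",
    "esr": "esr",
    "crp": "crp",
    "no2": "aqi_NO2",
    "o3": "aqi_O3",
    "so2": "aqi_SO2",
    "co": "aqi_CO",
    "pm10": "aqi_PM10",
}


@dataclass(frozen=True)
class PollutantGenParams:
    """Calibration targets and nuisance knobs of the exposure generator."""

    aqi_mean: dict = field(default_factory=lambda: dict(DEFAULT_AQI_MEAN))
    aqi_sd: dict = field(default_factory=lambda: dict(DEFAULT_AQI_SD))
    aqi_correlation: dict = field(
        default_factory=lambda: dict(DEFAULT_AQI_CORRELATION)
    )
    missing_rates: dict = field(default_factory=lambda: dict(DEFAULT_MISSING_RATES))
    diurnal_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p, rate in self.missing_rates.items():
            if not (0 <= rate < 1):
                raise ValueError(f"missing rate for {p} must be in [0, 1)")
        if not (0 <= self.diurnal_amplitude < 1):
            raise ValueError("diurnal_amplitude must be in [0, 1)")


@dataclass(frozen=True)
class RegistryGenParams:
    """Marginals, component distributions and planted effects."""

    n_patients: int = 1651
    visit_geometric_p: float = 0.167
    max_visits: int = 49
    female_rate: float = 0.608
    kuwaiti_rate: float = 0.586
    rf_positive_rate: float = 0.746
    acpa_positive_rate: float = 0.605
    comorbidity_rate: float = 0.546
    biologics_rate: float = 0.528
    governorate_weights: dict = field(
        default_factory=lambda: dict(GOVERNORATE_WEIGHTS)
    )
    duration_mean: float = 9.82
    duration_sd: float = 6.48
    # Component distributions (skewed, zero-inflated where the observed
    # marginals are): see docs/methods.md for the parameterization.
    sjc_positive_rate: float = 0.35
    sjc_positive_mean: float = 2.0
    esr_mean: float = 27.19
    esr_sd: float = 21.79
    crp_mean: float = 6.32
    crp_sd: float = 4.85
    pagh_positive_rate: float = 0.35
    pagh_positive_mean: float = 4.7
    prgh_positive_rate: float = 0.30
    prgh_positive_mean: float = 3.5
    # Baseline tender-joint level; chosen so the structural solve stays in
    # the 0--28 count range with probability > 99%.
    tjc_base_mean: float = 7.0
    tjc_base_sd: float = 2.0
    true_effects: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TRUE_EFFECTS.items()}
    )
    noise_sd: dict = field(default_factory=lambda: {"das28": 0.9, "cdai": 2.0})
    planted_response: str = "das28"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "female_rate", "kuwaiti_rate", "rf_positive_rate",
            "acpa_positive_rate", "comorbidity_rate", "biologics_rate",
        ):
            rate = getattr(self, name)
            if not (0 <= rate <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        for response, sd in self.noise_sd.items():
            if sd <= 0:
                raise ValueError(f"noise_sd[{response!r}] must be > 0")
        if self.planted_response not in self.true_effects:
            raise ValueError(
                f"no true_effects entry for planted response "
                f"{self.planted_response!r}"
            )


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Moment-matched (mu, sigma) of a lognormal with the given mean/SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def latent_correlation(params: PollutantGenParams) -> pd.DataFrame:
    """Log-scale latent correlation matrix hitting the AQI-scale targets.

    Inverts the bivariate-lognormal correlation identity per pair, then
    projects to the nearest symmetric positive-definite matrix if the
    assembled matrix has non-positive eigenvalues.
    """
    sigmas = {
        p: _lognormal_params(params.aqi_mean[p], params.aqi_sd[p])[1]
        for p in POLLUTANT_ORDER
    }
    n = len(POLLUTANT_ORDER)
    latent = np.eye(n)
    for (a, b), target in params.aqi_correlation.items():
        sa, sb = sigmas[a], sigmas[b]
        scale = np.sqrt(np.expm1(sa**2) * np.expm1(sb**2))
        inner = 1.0 + target * scale
        if inner <= 0:
            raise ValueError(
                f"correlation target {target} for ({a}, {b}) is unattainable "
                "under lognormal marginals"
            )
        rho = np.log(inner) / (sa * sb)
        i, j = POLLUTANT_ORDER.index(a), POLLUTANT_ORDER.index(b)
        latent[i, j] = latent[j, i] = rho
    eigvals = np.linalg.eigvalsh(latent)
    if eigvals.min() <= 1e-10:
        values, vectors = np.linalg.eigh(latent)
        values = np.clip(values, 1e-8, None)
        latent = vectors @ np.diag(values) @ vectors.T
        d = np.sqrt(np.diag(latent))
        latent = latent / np.outer(d, d)
    return pd.DataFrame(latent, index=POLLUTANT_ORDER, columns=POLLUTANT_ORDER)


def _roundtrip_index(
    pollutant: str, indices: np.ndarray, table: BreakpointTable
) -> np.ndarray:
    """Index values as the pipeline would reproduce them.

    Indices above the top of the scale clip to the top; values inside an
    index discretization gap snap to the next row's lower bound, mirroring
    the concentration gap rule.
    """
    rows = table.rows_for(pollutant)
    out = np.full_like(indices, np.nan, dtype=float)
    remaining = np.ones(indices.shape, dtype=bool)
    for row in rows:
        in_row = remaining & (indices >= row.index_low) & (indices <= row.index_high)
        out[in_row] = indices[in_row]
        remaining &= ~in_row
    top = rows[-1].index_high
    above = remaining & (indices > top)
    out[above] = top
    remaining &= ~above
    for row in rows:  # gap values
        gap = remaining & (indices < row.index_low)
        out[gap] = row.index_low
        remaining &= ~gap
    return out


def _draw_daily_aqi(
    params: PollutantGenParams,
    n_days: int,
    governorates: tuple[str, ...],
    rng: np.random.Generator,
    table: BreakpointTable,
) -> pd.DataFrame:
    """True (pre-masking) daily AQI values, one row per (date, governorate)."""
    latent = latent_correlation(params).to_numpy()
    chol = np.linalg.cholesky(latent)
    n = n_days * len(governorates)
    z = rng.standard_normal(size=(n, len(POLLUTANT_ORDER))) @ chol.T
    columns = {}
    for j, pollutant in enumerate(POLLUTANT_ORDER):
        mu, sigma = _lognormal_params(
            params.aqi_mean[pollutant], params.aqi_sd[pollutant]
        )
        drawn = np.exp(mu + sigma * z[:, j])
        columns[f"aqi_{pollutant}"] = _roundtrip_index(pollutant, drawn, table)
    dates = pd.date_range("2013-01-01", periods=n_days, freq="D")
    frame = pd.DataFrame(
        {
            "date": np.tile(dates.date, len(governorates)),
            "governorate": np.repeat(list(governorates), n_days),
        }
    )
    return pd.concat([frame, pd.DataFrame(columns)], axis=1)


def _mask_days(
    frame: pd.DataFrame, params: PollutantGenParams, rng: np.random.Generator
) -> pd.DataFrame:
    """MCAR whole-day outages per pollutant at the configured rates."""
    out = frame.copy()
    for pollutant in POLLUTANT_ORDER:
        rate = params.missing_rates.get(pollutant, 0.0)
        if rate > 0:
            mask = rng.random(len(out)) < rate
            out.loc[mask, f"aqi_{pollutant}"] = np.nan
    return out


def simulate_daily_exposure(
    params: PollutantGenParams,
    n_days: int,
    governorates: tuple[str, ...] = GOVERNORATES,
    breakpoint_table: BreakpointTable | None = None,
) -> pd.DataFrame:
    """Daily exposure table drawn directly at the daily level.

    Equivalent in distribution to simulating hourly readings and running
    the aggregation stage (the hourly expansion is deterministic given the
    daily draws); used where the hourly detour is not itself under test.
    Completeness is 1 for observed days and 0 for masked outage days.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    table = breakpoint_table or load_breakpoint_table()
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    frame = _draw_daily_aqi(params, n_days, tuple(governorates), rng, table)
    frame = _mask_days(frame, params, rng)
    for pollutant in POLLUTANT_ORDER:
        frame[f"completeness_{pollutant}"] = np.where(
            frame[f"aqi_{pollutant}"].notna(), 1.0, 0.0
        )
    return frame


def _diurnal_shape(amplitude: float, window: int) -> np.ndarray:
    """Hour-of-day multipliers with the daily metric normalized to one.

    A cosine peaking mid-afternoon; normalized so the 24-h mean (24-h
    pollutants) or the best 8-h window mean (8-h pollutants) of the shape
    is exactly 1.
    """
    hours = np.arange(24)
    shape = 1.0 + amplitude * np.cos(2 * np.pi * (hours - 15) / 24.0)
    if window == 24:
        return shape / shape.mean()
    window_means = [shape[np.arange(s, s + 8) % 24].mean() for s in range(24)]
    return shape / max(window_means)


def simulate_hourly_pollutants(
    params: PollutantGenParams,
    n_days: int,
    governorates: tuple[str, ...] = GOVERNORATES,
    breakpoint_table: BreakpointTable | None = None,
) -> pd.DataFrame:
    """Hourly concentration readings for the monitoring stations.

    Daily AQI draws are inverted through the breakpoint table to physical
    concentrations and expanded to 24 hourly readings (optionally shaped
    by a normalized diurnal cycle).  Masked outage days carry missing
    concentrations for all 24 hours, so the aggregation stage reproduces
    both the drawn values and the daily missingness pattern.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    table = breakpoint_table or load_breakpoint_table()
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    daily = _draw_daily_aqi(params, n_days, tuple(governorates), rng, table)
    daily = _mask_days(daily, params, rng)
    frames = []
    hours = np.arange(24)
    for pollutant in POLLUTANT_ORDER:
        window = table.rows_for(pollutant)[0].averaging_window
        shape = _diurnal_shape(params.diurnal_amplitude, window)
        aqi = daily[f"aqi_{pollutant}"].to_numpy()
        conc = np.array(
            [
                np.nan
                if np.isnan(v)
                else concentration_for_index(pollutant, float(v), table)
                for v in aqi
            ]
        )
        base_dates = pd.to_datetime(daily["date"])
        timestamps = (
            base_dates.to_numpy(dtype="datetime64[h]")[:, None]
            + hours.astype("timedelta64[h]")[None, :]
        )
        values = conc[:, None] * shape[None, :]
        if window == 8:
            # An outage day must stay missing after aggregation even
            # though 8-h windows may cross midnight: extend the outage 7
            # hours into the following day of the same station.
            gov_arr = daily["governorate"].to_numpy()
            masked = np.isnan(conc)
            extend = np.where(masked[:-1] & (gov_arr[:-1] == gov_arr[1:]))[0] + 1
            values[extend, :7] = np.nan
        frames.append(
            pd.DataFrame(
                {
                    "station_id": np.repeat(
                        daily["governorate"].map(STATIONS).to_numpy(), 24
                    ),
                    "governorate": np.repeat(daily["governorate"].to_numpy(), 24),
                    "timestamp": timestamps.ravel(),
                    "pollutant": pollutant,
                    "concentration": values.ravel(),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(
        ["governorate", "pollutant", "timestamp"], ignore_index=True
    )


def _zero_inflated(
    rng: np.random.Generator,
    n: int,
    positive_rate: float,
    positive_mean: float,
    *,
    integer: bool,
    upper: float,
) -> np.ndarray:
    """Zero-inflated positive component: geometric counts or exponential."""
    positive = rng.random(n) < positive_rate
    if integer:
        p = 1.0 / positive_mean
        draws = rng.geometric(p, size=n).astype(float)
    else:
        draws = rng.exponential(positive_mean, size=n)
    return np.clip(np.where(positive, draws, 0.0), 0.0, upper)


def simulate_registry(
    params: RegistryGenParams,
    exposure: pd.DataFrame,
) -> pd.DataFrame:
    """Visit registry with covariates, components and planted outcomes.

    ``exposure`` must provide complete AQI values for the five pollutants
    on every (date, governorate) it offers; visit dates are sampled from
    that complete support per governorate.  The tender-joint count is
    solved from the structural equation of ``params.planted_response`` so
    that the response follows the planted linear model.
    """
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    aqi_cols = [f"aqi_{p}" for p in POLLUTANT_ORDER]
    exp = exposure.copy()
    exp["date"] = pd.to_datetime(exp["date"]).dt.date
    complete = exp[exp[aqi_cols].notna().all(axis=1)]
    dates_by_gov = {
        g: block for g, block in complete.groupby("governorate", sort=True)
    }
    gov_names = list(params.governorate_weights)
    weights = np.array([params.governorate_weights[g] for g in gov_names])
    weights = weights / weights.sum()
    for g in gov_names:
        if g not in dates_by_gov or dates_by_gov[g].empty:
            raise ValueError(f"no complete exposure coverage for governorate {g!r}")

    n_visits_per_patient = np.clip(
        rng.geometric(params.visit_geometric_p, size=params.n_patients),
        1,
        params.max_visits,
    )
    n_visits = int(n_visits_per_patient.sum())
    patient_idx = np.repeat(np.arange(params.n_patients), n_visits_per_patient)

    patient_gov = rng.choice(len(gov_names), size=params.n_patients, p=weights)
    patient_female = rng.random(params.n_patients) < params.female_rate
    patient_kuwaiti = rng.random(params.n_patients) < params.kuwaiti_rate
    patient_rf = rng.random(params.n_patients) < params.rf_positive_rate
    patient_acpa = rng.random(params.n_patients) < params.acpa_positive_rate
    patient_comorbid = rng.random(params.n_patients) < params.comorbidity_rate
    patient_bio = rng.random(params.n_patients) < params.biologics_rate
    patient_duration = np.clip(
        rng.normal(params.duration_mean, params.duration_sd, params.n_patients),
        0.2,
        45.0,
    )

    visits = pd.DataFrame(
        {
            "patient_id": [f"P{int(i):05d}" for i in patient_idx],
            "governorate": [gov_names[patient_gov[i]] for i in patient_idx],
            "gender": np.where(patient_female[patient_idx], "female", "male"),
            "nationality": np.where(
                patient_kuwaiti[patient_idx], "Kuwaiti", "non-Kuwaiti"
            ),
            "disease_duration": patient_duration[patient_idx],
            "comorbidity": np.where(patient_comorbid[patient_idx], "Yes", "No"),
            "treatment_class": np.where(
                patient_bio[patient_idx], "biologics", "cDMARDs"
            ),
            "rf_status": np.where(patient_rf[patient_idx], "positive", "negative"),
            "acpa_status": np.where(
                patient_acpa[patient_idx], "positive", "negative"
            ),
        }
    )

    # Visit dates uniform over the complete exposure support per governorate.
    visit_dates = np.empty(n_visits, dtype=object)
    gov_array = visits["governorate"].to_numpy()
    for g in gov_names:
        rows = np.where(gov_array == g)[0]
        if rows.size:
            pool = dates_by_gov[g]["date"].to_numpy()
            visit_dates[rows] = rng.choice(pool, size=rows.size)
    visits["visit_date"] = visit_dates

    # Clinical components.
    visits["sjc28"] = _zero_inflated(
        rng, n_visits, params.sjc_positive_rate, params.sjc_positive_mean,
        integer=True, upper=28,
    )
    mu, sigma = _lognormal_params(params.esr_mean, params.esr_sd)
    visits["esr"] = np.clip(rng.lognormal(mu, sigma, n_visits), 1.0, 140.0)
    mu, sigma = _lognormal_params(params.crp_mean, params.crp_sd)
    visits["crp"] = np.clip(rng.lognormal(mu, sigma, n_visits), 0.1, 50.0)
    visits["pagh"] = _zero_inflated(
        rng, n_visits, params.pagh_positive_rate, params.pagh_positive_mean,
        integer=False, upper=10,
    )
    visits["prgh"] = _zero_inflated(
        rng, n_visits, params.prgh_positive_rate, params.prgh_positive_mean,
        integer=False, upper=10,
    )
    visits["gh"] = np.clip(
        10.0 * visits["pagh"].to_numpy() + rng.normal(0.0, 5.0, n_visits), 0.0, 100.0
    )

    # Exposure at the visit date, for the planted linear predictor.
    merged = visits.merge(
        complete[["date", "governorate"] + aqi_cols],
        left_on=["visit_date", "governorate"],
        right_on=["date", "governorate"],
        how="left",
    )
    if merged[aqi_cols].isna().any().any():
        raise ValueError("exposure coverage gap for a sampled visit date")

    response = params.planted_response
    effects = params.true_effects[response]
    merged["_rf_ind"] = (merged["rf_status"] == "positive").astype(float)
    merged["_acpa_ind"] = (merged["acpa_status"] == "positive").astype(float)
    target = np.full(n_visits, float(effects.get("intercept", 0.0)))
    for key, beta in effects.items():
        if key == "intercept":
            continue
        column = _EFFECT_COLUMNS.get(key)
        if column is None:
            raise ValueError(f"unknown planted-effect key {key!r}")
        target = target + float(beta) * merged[column].to_numpy(dtype=float)
    target = target + rng.normal(0.0, params.noise_sd[response], n_visits)

    # Solve the structural index equation so the response follows the
    # planted linear model.  The baseline tender level keeps the solved
    # quantities inside their count ranges (clipping would attenuate the
    # planted slopes).
    sjc = merged["sjc28"].to_numpy(dtype=float)
    tjc_base = rng.gamma(
        (params.tjc_base_mean / params.tjc_base_sd) ** 2,
        params.tjc_base_sd**2 / params.tjc_base_mean,
        n_visits,
    )
    if response == "das28":
        residual_target = (
            target
            - 0.28 * sjc
            - 0.70 * np.log(merged["esr"].to_numpy(dtype=float))
            - 0.014 * merged["gh"].to_numpy(dtype=float)
        ) / 0.56
        visits["tjc28"] = np.clip(np.rint(tjc_base + residual_target), 0, 28)
    else:
        # CDAI is a plain sum, so the target total (minus the swollen
        # count) is allocated exactly across TJC28 + PaGH + PrGH; their
        # joint 0--48 range makes clipping negligible and the continuous
        # global assessments absorb the integer rounding of TJC28.
        total = np.clip(target + tjc_base - sjc, 0.0, 48.0)
        tjc = np.clip(np.floor(0.7 * total), 0, 28)
        remainder = total - tjc
        pagh = np.clip(0.6 * remainder, 0.0, 10.0)
        prgh = np.clip(remainder - pagh, 0.0, 10.0)
        visits["tjc28"] = tjc
        visits["pagh"] = pagh
        visits["prgh"] = prgh
        visits["gh"] = np.clip(
            10.0 * pagh + rng.normal(0.0, 5.0, n_visits), 0.0, 100.0
        )
    column_order = [
        "patient_id", "visit_date", "governorate", "gender", "nationality",
        "disease_duration", "comorbidity", "treatment_class", "rf_status",
        "acpa_status", "tjc28", "sjc28", "esr", "crp", "gh", "pagh", "prgh",
    ]
    return visits[column_order]


def scale_patients(params: RegistryGenParams, target_visits: int) -> RegistryGenParams:
    """Adjust ``n_patients`` so the expected visit count matches a target."""
    mean_visits = 1.0 / params.visit_geometric_p
    return replace(params, n_patients=max(1, round(target_visits / mean_visits)))
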