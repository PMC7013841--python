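"""Correlation screen and the M1--M4 regression ladder.

The analysis proceeds in two stages.  A pairwise-complete Pearson screen
flags associations among pollutants, disease-activity indices and clinical
markers, with significance stars at p < 0.1 / 0.05 / 0.01 / 0.001.  Four
nested-in-spirit linear models are then fitted per response (DAS-28 or
CDAI):

* M1 — demographics (gender, disease duration, nationality, governorate,
  comorbidity);
* M2 — M1 plus treatment class and clinical RA factors (swollen/tender
  counts, RF, ACPA, global assessments, ESR, CRP);
* M3 — the five pollutant AQI series alone;
* M4 — pollutants plus swollen count, RF, ACPA, ESR and CRP.

Fits are ordinary least squares with fixed governorate effects (Ahmadi is
the reference level), normal-theory Wald 95% intervals and deviance
reported as -2 log-likelihood, which supports the deviance-based model
comparison.  A random governorate intercept is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

STAR_BANDS = ((0.001, "****"), (0.01, "***"), (0.05, "**"), (0.1, "*"))

POLLUTANT_TERMS = ["aqi_NO2", "aqi_O3", "aqi_SO2", "aqi_CO", "aqi_PM10"]

#: Categorical predictors with fixed, documented reference levels.
_CATEGORICAL = {
    "gender": "female",
    "nationality": "Kuwaiti",
    "governorate": "Ahmadi",
    "comorbidity": "No",
    "treatment_class": "biologics",
    "rf_status": "negative",
    "acpa_status": "negative",
}

MODEL_PREDICTORS = {
    "M1": ["gender", "disease_duration", "nationality", "governorate", "comorbidity"],
    "M2": [
        "gender", "disease_duration", "nationality", "governorate", "comorbidity",
        "treatment_class", "sjc28", "tjc28", "rf_status", "acpa_status",
        "pagh", "prgh", "esr", "crp",
    ],
    "M3": list(POLLUTANT_TERMS),
    "M4": POLLUTANT_TERMS + ["sjc28", "rf_status", "acpa_status", "esr", "crp"],
}


def star_code(p_value: float) -> str:
    """Significance stars for a two-sided p-value (strict band edges)."""
    if not (0 <= p_value <= 1):
        raise ValueError(f"p-value must be in [0, 1], got {p_value!r}")
    for cut, stars in STAR_BANDS:
        if p_value < cut:
            return stars
    return ""


@dataclass(frozen=True)
class CorrelationResult:
    var_a: str
    var_b: str
    rp: float
    p_value: float
    n: int
    star_code: str


@dataclass(frozen=True)
class ModelSpec:
    """One rung of the ladder: response plus a named predictor set."""

    label: str
    response: str
    predictors: tuple[str, ...]

    @classmethod
    def standard(cls, label: str, response: str) -> "ModelSpec":
        if label not in MODEL_PREDICTORS:
            raise ValueError(f"unknown model label {label!r}")
        if response not in ("das28", "cdai"):
            raise ValueError(f"response must be 'das28' or 'cdai', got {response!r}")
        return cls(label, response, tuple(MODEL_PREDICTORS[label]))

    def formula(self) -> str:
        terms = []
        for p in self.predictors:
            if p in _CATEGORICAL:
                terms.append(f"C({p}, Treatment(reference={_CATEGORICAL[p]!r}))")
            else:
                terms.append(p)
        return f"{self.response} ~ " + " + ".join(terms)


@dataclass
class FitResult:
    label: str
    response: str
    coefficients: pd.DataFrame = field(repr=False)
    r_squared: float
    adj_r_squared: float
    deviance: float
    n_obs: int
    n_dropped: int
    predictors: tuple[str, ...] = ()

    def coefficient(self, name: str) -> pd.Series:
        """Look up a coefficient row by exact or substring term match."""
        if name in self.coefficients.index:
            return self.coefficients.loc[name]
        hits = [t for t in self.coefficients.index if name in t]
        if len(hits) != 1:
            raise KeyError(f"term {name!r} matches {hits} in {self.label}")
        return self.coefficients.loc[hits[0]]


def pearson_matrix(
    table: pd.DataFrame, variables: list[str]
) -> tuple[pd.DataFrame, list[CorrelationResult]]:
    """Pairwise-complete Pearson correlations with p-values and stars.

    Returns the symmetric correlation matrix and the flat list of results
    for the lower triangle.  A variable that is constant on some complete
    pair set has no defined correlation and raises.
    """
    results: list[CorrelationResult] = []
    matrix = pd.DataFrame(np.eye(len(variables)), index=variables, columns=variables)
    for i, a in enumerate(variables):
        for b in variables[i + 1 :]:
            pair = table[[a, b]].dropna()
            if len(pair) < 3:
                raise ValueError(f"fewer than 3 complete pairs for ({a}, {b})")
            x = pair[a].to_numpy(dtype=float)
            y = pair[b].to_numpy(dtype=float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                raise ValueError(f"constant column in pair ({a}, {b}); r undefined")
            r, p = stats.pearsonr(x, y)
            results.append(
                CorrelationResult(a, b, float(r), float(p), len(pair), star_code(p))
            )
            matrix.loc[a, b] = matrix.loc[b, a] = float(r)
    return matrix, results


def fit_model(
    table: pd.DataFrame,
    spec: ModelSpec,
    *,
    random_governorate_intercept: bool = False,
) -> FitResult:
    """Fit one ladder model by least squares with listwise deletion.

    The optional mixed-model variant replaces the governorate dummies with
    a random intercept per governorate (restricted maximum likelihood).
    """
    needed = [spec.response] + list(spec.predictors)
    if random_governorate_intercept and "governorate" not in needed:
        needed.append("governorate")
    missing_cols = [c for c in needed if c not in table.columns]
    if missing_cols:
        raise ValueError(f"table lacks columns {missing_cols} for {spec.label}")
    data = table[needed].dropna()
    n_dropped = len(table) - len(data)
    if random_governorate_intercept:
        predictors = tuple(p for p in spec.predictors if p != "governorate")
        formula = ModelSpec(spec.label, spec.response, predictors).formula()
        fit = smf.mixedlm(formula, data, groups=data["governorate"]).fit(reml=True)
        params = fit.params.drop(labels=["Group Var"], errors="ignore")
        conf = fit.conf_int().loc[params.index]
        coef = pd.DataFrame(
            {
                "beta": params,
                "ci_low": conf[0],
                "ci_high": conf[1],
                "p_value": fit.pvalues.loc[params.index],
            }
        )
        return FitResult(
            label=spec.label,
            response=spec.response,
            coefficients=coef,
            r_squared=float("nan"),
            adj_r_squared=float("nan"),
            deviance=float(-2.0 * fit.llf),
            n_obs=int(fit.nobs),
            n_dropped=n_dropped,
            predictors=spec.predictors,
        )
    model = smf.ols(spec.formula(), data)
    if model.exog.shape[0] <= model.exog.shape[1]:
        raise ValueError(
            f"{spec.label}: n_obs={model.exog.shape[0]} <= "
            f"n_params={model.exog.shape[1]}"
        )
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        u, s, vt = np.linalg.svd(model.exog)
        aliased = [
            model.exog_names[j]
            for j in np.where(np.abs(vt[-1]) > 1e-8)[0]
        ]
        raise ValueError(f"rank-deficient design in {spec.label}; aliased: {aliased}")
    fit = model.fit()
    conf = fit.conf_int(alpha=0.05)
    coef = pd.DataFrame(
        {
            "beta": fit.params,
            "ci_low": conf[0],
            "ci_high": conf[1],
            "p_value": fit.pvalues,
        }
    )
    return FitResult(
        label=spec.label,
        response=spec.response,
        coefficients=coef,
        r_squared=float(fit.rsquared),
        adj_r_squared=float(fit.rsquared_adj),
        deviance=float(-2.0 * fit.llf),
        n_obs=int(fit.nobs),
        n_dropped=n_dropped,
        predictors=spec.predictors,
    )


def fit_ladder(
    table: pd.DataFrame,
    response: str,
    labels: list[str] | None = None,
    *,
    random_governorate_intercept: bool = False,
) -> dict[str, FitResult]:
    """Fit the requested rungs of the ladder for one response."""
    labels = labels or ["M1", "M2", "M3", "M4"]
    return {
        label: fit_model(
            table,
            ModelSpec.standard(label, response),
            random_governorate_intercept=random_governorate_intercept,
        )
        for label in labels
    }


@dataclass(frozen=True)
class DevianceComparison:
    preferred: str
    delta: float
    lr_statistic: float | None
    lr_df: int | None
    lr_p_value: float | None
    note: str = ""


def compare_deviance(fit_a: FitResult, fit_b: FitResult) -> DevianceComparison:
    """Compare two fits by deviance; LR test when one nests the other.

    Both fits must model the same response on the same observation set.
    Lower deviance is preferred; equal deviance is a tie.
    """
    if fit_a.response != fit_b.response:
        raise ValueError("fits model different responses")
    if fit_a.n_obs != fit_b.n_obs:
        raise ValueError(
            f"fits use different observation sets ({fit_a.n_obs} vs {fit_b.n_obs})"
        )
    delta = fit_a.deviance - fit_b.deviance
    if abs(delta) < 1e-12:
        preferred, note = "tie", "equal deviance"
    else:
        preferred = fit_b.label if delta > 0 else fit_a.label
        note = ""
    set_a, set_b = set(fit_a.predictors), set(fit_b.predictors)
    lr_stat = lr_df = lr_p = None
    if set_a < set_b or set_b < set_a:
        small, large = (fit_a, fit_b) if set_a < set_b else (fit_b, fit_a)
        lr_stat = max(small.deviance - large.deviance, 0.0)
        lr_df = len(large.coefficients) - len(small.coefficients)
        lr_p = float(stats.chi2.sf(lr_stat, lr_df)) if lr_df > 0 else None
    else:
        note = (note + "; " if note else "") + "non-nested fits: LR test suppressed"
    return DevianceComparison(
        preferred=preferred,
        delta=float(delta),
        lr_statistic=lr_stat,
        lr_df=lr_df,
        lr_p_value=lr_p,
        note=note,
    )


def pool_fits(fits: list[FitResult]) -> pd.DataFrame:
    """Rubin's rules across fits of the same spec on multiply-imputed data.

    Combines coefficients as the across-fit mean with total variance
    W + (1 + 1/m) B, where W is the mean squared standard error and B the
    between-fit variance of the estimates.
    """
    if not fits:
        raise ValueError("no fits to pool")
    m = len(fits)
    betas = pd.concat([f.coefficients["beta"] for f in fits], axis=1)
    # Wald SE back-solved from the 95% interval half-width.
    halfwidth = pd.concat(
        [(f.coefficients["ci_high"] - f.coefficients["ci_low"]) / 2 for f in fits],
        axis=1,
    )
    se = halfwidth / stats.norm.ppf(0.975)
    qbar = betas.mean(axis=1)
    w = (se**2).mean(axis=1)
    b = betas.var(axis=1, ddof=1) if m > 1 else 0.0 * qbar
    total = w + (1 + 1 / m) * b
    z = stats.norm.ppf(0.975)
    return pd.DataFrame(
        {
            "beta": qbar,
            "ci_low": qbar - z * np.sqrt(total),
            "ci_high": qbar + z * np.sqrt(total),
            "se": np.sqrt(total),
        }
    )
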