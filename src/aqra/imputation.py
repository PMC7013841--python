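"""Multiple imputation by chained equations for daily exposure series.

Missing daily pollutant values are filled by iterating univariate normal
linear regressions: each incomplete column is regressed (on the log scale
by default, since pollutant series are positively skewed) on every other
column plus calendar covariates, and its missing cells are replaced by the
linear prediction plus a normal residual draw.  Running the chain ``m``
times with independent seeds yields ``m`` completed datasets whose spread
reflects imputation uncertainty.  Observed cells are never modified.

The default downstream combination averages the ``m`` completed exposure
values into a single analysis dataset; Rubin pooling of per-dataset model
fits is available in :mod:`aqra.models` as the orthodox alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

_LOG_EPSILON = 1e-6


@dataclass(frozen=True)
class ImputationConfig:
    """Knobs of the chained-equation sampler.

    ``n_imputations`` (m) and ``n_iterations`` default to conventional
    values; ``log_scale`` fits the per-column regressions on log-transformed
    values; ``combine_rule`` selects how completed datasets feed the
    analysis stage.
    """

    n_imputations: int = 5
    n_iterations: int = 10
    log_scale: bool = True
    seed: int = 0
    combine_rule: str = "mean_of_completed"
    method: str = "normal"
    pmm_donors: int = 5

    def __post_init__(self) -> None:
        if self.n_imputations < 1:
            raise ValueError("n_imputations must be >= 1")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.combine_rule not in ("mean_of_completed", "rubin_pooling"):
            raise ValueError(f"unknown combine_rule {self.combine_rule!r}")
        if self.method not in ("normal", "pmm"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.pmm_donors < 1:
            raise ValueError("pmm_donors must be >= 1")


@dataclass
class CompletedDataset:
    """One completed copy of the input plus the mask of filled cells."""

    values: pd.DataFrame
    imputation_index: int
    imputed_mask: pd.DataFrame = field(repr=False)


def missingness_summary(table: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Per-column missing fraction and counts.

    Returns a frame with ``column``, ``n``, ``n_missing``, ``fraction``.
    """
    cols = columns if columns is not None else list(table.columns)
    rows = []
    for col in cols:
        n = len(table)
        n_missing = int(table[col].isna().sum())
        rows.append(
            {
                "column": col,
                "n": n,
                "n_missing": n_missing,
                "fraction": n_missing / n if n else 0.0,
            }
        )
    return pd.DataFrame(rows)


def _to_fit_scale(values: np.ndarray, log_scale: bool) -> np.ndarray:
    if not log_scale:
        return values
    out = values.copy()
    nonpos = out <= 0
    if np.any(nonpos & ~np.isnan(out)):
        warnings.warn(
            "non-positive values under log_scale; shifting by epsilon "
            f"{_LOG_EPSILON}",
            stacklevel=3,
        )
        out = np.where(~np.isnan(out) & nonpos, _LOG_EPSILON, out)
    return np.log(out)


def _design(matrix: np.ndarray, skip: int, aux: np.ndarray | None) -> np.ndarray:
    others = np.delete(matrix, skip, axis=1)
    parts = [np.ones((matrix.shape[0], 1)), others]
    if aux is not None:
        parts.append(aux)
    return np.hstack(parts)


def _chained_pass(
    work: np.ndarray,
    observed: np.ndarray,
    aux: np.ndarray | None,
    config: "ImputationConfig",
    rng: np.random.Generator,
) -> None:
    """One sweep of the chain: refit and redraw every incomplete column."""
    log_scale = config.log_scale
    n_cols = work.shape[1]
    fit_matrix = np.column_stack(
        [_to_fit_scale(work[:, j], log_scale) for j in range(n_cols)]
    )
    for j in range(n_cols):
        missing = ~observed[:, j]
        if not missing.any():
            continue
        X = _design(fit_matrix, j, aux)
        y = fit_matrix[:, j]
        rows = observed[:, j]
        beta, *_ = np.linalg.lstsq(X[rows], y[rows], rcond=None)
        if config.method == "pmm":
            # Predictive-mean matching: donate an observed value whose
            # fitted mean is close to the missing cell's fitted mean.
            fitted_obs = X[rows] @ beta
            observed_values = y[rows]
            for i in np.where(missing)[0]:
                distance = np.abs(fitted_obs - X[i] @ beta)
                k = min(config.pmm_donors, len(distance))
                donors = np.argpartition(distance, k - 1)[:k]
                draws = observed_values[donors[rng.integers(k)]]
                work[i, j] = np.exp(draws) if log_scale else draws
        else:
            residuals = y[rows] - X[rows] @ beta
            dof = max(int(rows.sum()) - X.shape[1], 1)
            sigma = float(np.sqrt(np.sum(residuals**2) / dof))
            draws = X[missing] @ beta + rng.normal(
                0.0, sigma, size=int(missing.sum())
            )
            work[missing, j] = np.exp(draws) if log_scale else draws
        fit_matrix[:, j] = _to_fit_scale(work[:, j], log_scale)


def mice_impute(
    table: pd.DataFrame,
    config: ImputationConfig,
    columns: list[str] | None = None,
    auxiliary: pd.DataFrame | None = None,
) -> list[CompletedDataset]:
    """Run chained-equation multiple imputation on the given columns.

    Parameters
    ----------
    table:
        Input frame; only ``columns`` (default: all numeric columns) are
        imputed, everything else is passed through untouched.
    auxiliary:
        Optional fully-observed numeric predictors (e.g. calendar
        covariates) used in every column regression but never imputed.

    Returns ``config.n_imputations`` completed datasets.  Identical config
    and seed reproduce bit-identical output.
    """
    cols = columns if columns is not None else [
        c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])
    ]
    if len(cols) < 2 and auxiliary is None:
        raise ValueError("need >= 2 columns (or auxiliary predictors) to chain")
    matrix = table[cols].to_numpy(dtype=float)
    observed = ~np.isnan(matrix)
    for j, col in enumerate(cols):
        if not observed[:, j].any():
            raise ValueError(f"column {col!r} has no observed values")
    aux = None
    if auxiliary is not None:
        aux = auxiliary.to_numpy(dtype=float)
        if np.isnan(aux).any():
            raise ValueError("auxiliary predictors must be fully observed")
    root = np.random.SeedSequence(config.seed)
    completed: list[CompletedDataset] = []
    for m, child in enumerate(root.spawn(config.n_imputations), start=1):
        rng = np.random.default_rng(child)
        work = matrix.copy()
        # Initialize missing cells from the column's observed empirical
        # distribution, then iterate the chain.
        for j in range(work.shape[1]):
            missing = ~observed[:, j]
            if missing.any():
                pool = work[observed[:, j], j]
                work[missing, j] = rng.choice(pool, size=int(missing.sum()))
        for _ in range(config.n_iterations):
            _chained_pass(work, observed, aux, config, rng)
        values = table.copy()
        for j, col in enumerate(cols):
            values[col] = work[:, j]
        mask = pd.DataFrame(False, index=table.index, columns=table.columns)
        for j, col in enumerate(cols):
            mask[col] = ~observed[:, j]
        completed.append(
            CompletedDataset(values=values, imputation_index=m, imputed_mask=mask)
        )
    return completed


def combine_completed(completed: list[CompletedDataset], columns: list[str]) -> pd.DataFrame:
    """Average the imputed columns across completed datasets.

    Observed cells are identical in every dataset, so the average leaves
    them untouched; imputed cells get the across-imputation mean.
    """
    if not completed:
        raise ValueError("no completed datasets to combine")
    out = completed[0].values.copy()
    stacked = np.stack([c.values[columns].to_numpy(dtype=float) for c in completed])
    out[columns] = stacked.mean(axis=0)
    return out


def calendar_covariates(dates: pd.Series) -> pd.DataFrame:
    """Seasonal and weekly auxiliary predictors for exposure imputation.

    Two annual harmonics plus a weekend indicator; fully observed by
    construction.
    """
    ts = pd.to_datetime(dates)
    doy = ts.dt.dayofyear.to_numpy(dtype=float)
    angle = 2.0 * np.pi * doy / 365.25
    return pd.DataFrame(
        {
            "sin_annual": np.sin(angle),
            "cos_annual": np.cos(angle),
            "sin_semiannual": np.sin(2 * angle),
            "cos_semiannual": np.cos(2 * angle),
            "weekend": (ts.dt.dayofweek >= 5).astype(float),
        },
        index=ts.index,
    )


def impute_exposure(
    exposure: pd.DataFrame,
    config: ImputationConfig,
    pollutants: list[str] | None = None,
) -> tuple[pd.DataFrame, list[CompletedDataset]]:
    """Impute missing daily AQI values per governorate series.

    Chains run separately within each governorate (one monitor per
    governorate, so series are spatially distinct), using calendar
    covariates as auxiliary predictors.  Returns the combined table under
    ``config.combine_rule == "mean_of_completed"`` plus the raw completed
    datasets for Rubin pooling.
    """
    aqi_cols = (
        [f"aqi_{p}" for p in pollutants]
        if pollutants is not None
        else [c for c in exposure.columns if c.startswith("aqi_")]
    )
    pieces, all_completed = [], []
    root = np.random.SeedSequence(config.seed)
    for (governorate, block), child in zip(
        exposure.groupby("governorate", sort=True),
        root.spawn(exposure["governorate"].nunique()),
    ):
        local = replace(config, seed=int(child.generate_state(1)[0] % (2**31)))
        completed = mice_impute(
            block,
            local,
            columns=aqi_cols,
            auxiliary=calendar_covariates(block["date"]),
        )
        all_completed.extend(completed)
        pieces.append(combine_completed(completed, aqi_cols))
    combined = pd.concat(pieces).sort_index()
    return combined, all_completed
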