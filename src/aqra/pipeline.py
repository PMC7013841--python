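"""End-to-end orchestration: simulate -> aggregate -> impute -> indices ->
link -> fit -> report.

Every stage is a pure function of (inputs, config, seed); stage seeds are
derived deterministically from the master seed, so a rerun with the same
config reproduces byte-identical tables.  Stage failures abort with the
failing stage named.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import models as models_mod
from .aggregation import build_daily_exposure
from .breakpoints import load_breakpoint_table
from .imputation import ImputationConfig, impute_exposure, missingness_summary
from .indices import add_indices
from .linkage import match_visits
from .simulate import (
    POLLUTANT_ORDER,
    PollutantGenParams,
    RegistryGenParams,
    simulate_hourly_pollutants,
    simulate_registry,
)

logger = logging.getLogger("aqra")


@dataclass
class PipelineConfig:
    """Flat configuration of the demo pipeline (YAML key: value file)."""

    output_dir: str = "pipeline_out"
    seed: int = 0
    n_days: int = 120
    n_patients: int = 300
    breakpoint_source: str | None = None
    n_imputations: int = 5
    n_iterations: int = 10
    log_scale_imputation: bool = True
    marker_kind: str = "ESR"
    das28_sqrt_counts: bool = False
    usepa_truncation: bool = False
    eight_hour_reduce: str = "max"
    mixed_model: bool = False
    planted_response: str = "das28"
    responses: str = "das28,cdai"
    model_labels: str = "M1,M2,M3,M4"
    make_plot: bool = False

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, float_format="%.10g")


def _stage(name: str):
    def decorate(fn):
        def wrapped(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                logger.error("stage %s: FAILED (%s)", name, exc)
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done", name)
            return result

        return wrapped

    return decorate


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the artifact bundle.

    Returns a dict of the in-memory stage outputs (tables, reports, fit
    results) for programmatic use; files land under ``config.output_dir``.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log")
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    )
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run_stages(config, out)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run_stages(config: PipelineConfig, out: Path) -> dict:
    root = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(3)]
    table = load_breakpoint_table(config.breakpoint_source)
    logger.info("seed=%d stage-seeds=%s", config.seed, seeds)

    pollutant_params = PollutantGenParams(seed=seeds[0])
    hourly = _stage("simulate-hourly")(simulate_hourly_pollutants)(
        pollutant_params, config.n_days, breakpoint_table=table
    )
    _write_csv(hourly, out / "hourly.csv")

    exposure = _stage("aggregate")(build_daily_exposure)(
        hourly, table, eight_hour_reduce=config.eight_hour_reduce
    )
    _write_csv(exposure, out / "daily_exposure.csv")
    missing = missingness_summary(
        exposure, [f"aqi_{p}" for p in POLLUTANT_ORDER]
    )

    imp_config = ImputationConfig(
        n_imputations=config.n_imputations,
        n_iterations=config.n_iterations,
        log_scale=config.log_scale_imputation,
        seed=seeds[1],
    )
    imputed, _completed = _stage("impute")(impute_exposure)(exposure, imp_config)
    _write_csv(imputed, out / "daily_exposure_imputed.csv")

    registry_params = RegistryGenParams(
        n_patients=config.n_patients,
        planted_response=config.planted_response,
        seed=seeds[2],
    )
    registry = _stage("simulate-registry")(simulate_registry)(
        registry_params, imputed
    )
    _write_csv(registry, out / "registry.csv")

    visits = _stage("indices")(add_indices)(
        registry,
        marker_kind=config.marker_kind,
        sqrt_counts=config.das28_sqrt_counts,
    )
    _write_csv(visits, out / "registry_with_indices.csv")

    linked, link_report = _stage("link")(match_visits)(visits, imputed)
    _write_csv(linked, out / "linked.csv")
    (out / "linkage_report.json").write_text(
        json.dumps(link_report.to_dict(), indent=2, sort_keys=True) + "\n"
    )

    corr_vars = ["das28", "cdai"] + [f"aqi_{p}" for p in POLLUTANT_ORDER]
    corr_matrix, corr_results = _stage("correlation")(models_mod.pearson_matrix)(
        linked, corr_vars
    )
    corr_matrix.round(4).to_csv(out / "correlations.csv")

    labels = [s.strip() for s in config.model_labels.split(",") if s.strip()]
    responses = [s.strip() for s in config.responses.split(",") if s.strip()]
    fits: dict[str, dict[str, models_mod.FitResult]] = {}
    for response in responses:
        fits[response] = _stage(f"fit-{response}")(models_mod.fit_ladder)(
            linked,
            response,
            labels,
            random_governorate_intercept=config.mixed_model,
        )
        for label, fit in fits[response].items():
            fit.coefficients.round(6).to_csv(
                out / f"coefficients_{response}_{label}.csv"
            )

    report = _render_report(missing, link_report, corr_results, fits)
    (out / "report.txt").write_text(report)
    if config.make_plot:
        _stage("plot")(_monthly_plot)(imputed, out / "monthly_aqi.png")
    return {
        "hourly": hourly,
        "exposure": exposure,
        "imputed": imputed,
        "registry": visits,
        "linked": linked,
        "missingness": missing,
        "linkage_report": link_report,
        "correlations": corr_matrix,
        "fits": fits,
        "report": report,
    }


def _render_report(missing, link_report, corr_results, fits) -> str:
    lines = ["Exposure / disease-activity pipeline report", ""]
    lines.append("Missingness per daily AQI column:")
    for row in missing.itertuples():
        lines.append(
            f"  {row.column}: {row.n_missing}/{row.n} ({row.fraction:.1%})"
        )
    lines.append("")
    lines.append(
        f"Linkage: {link_report.n_linked}/{link_report.n_visits_in} visits "
        f"linked, {link_report.n_dropped_no_exposure} dropped"
    )
    for gov, count in sorted(link_report.per_governorate.items()):
        lines.append(f"  {gov}: {count}")
    lines.append("")
    lines.append("Pearson correlations (pairwise complete):")
    for res in corr_results:
        lines.append(
            f"  {res.var_a} ~ {res.var_b}: r={res.rp:+.3f} "
            f"(p={res.p_value:.2g}) {res.star_code}"
        )
    for response, ladder in fits.items():
        lines.append("")
        lines.append(f"Model ladder for {response}:")
        for label, fit in ladder.items():
            lines.append(
                f"  {label}: n={fit.n_obs} R2={fit.r_squared:.4f} "
                f"adjR2={fit.adj_r_squared:.4f} deviance={fit.deviance:.1f}"
            )
            for term, row in fit.coefficients.iterrows():
                lines.append(
                    f"    {term}: {row.beta:+.5f} "
                    f"[{row.ci_low:+.5f}, {row.ci_high:+.5f}]"
                )
    return "\n".join(lines) + "\n"


def _monthly_plot(exposure: pd.DataFrame, path: Path) -> None:
    """Basic monthly-mean AQI time-series plot (plumbing, not analysis)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = exposure.copy()
    frame["month"] = pd.to_datetime(frame["date"]).dt.to_period("M").dt.to_timestamp()
    monthly = frame.groupby("month")[[f"aqi_{p}" for p in POLLUTANT_ORDER]].mean()
    fig, ax = plt.subplots(figsize=(9, 4.5))
    for pollutant in POLLUTANT_ORDER:
        ax.plot(monthly.index, monthly[f"aqi_{pollutant}"], label=pollutant)
    ax.set_xlabel("month")
    ax.set_ylabel("monthly mean AQI")
    ax.legend(ncol=5, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
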