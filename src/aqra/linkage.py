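"""Visit-to-exposure record linkage.

Each registry visit is joined to the daily exposure record sharing its
calendar date and governorate (the patient's home governorate; one
monitoring station per governorate).  Matching is exact-date only — the
study design offers no nearest-day window — and visits without a usable
exposure row are dropped and counted, never silently lost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass
class LinkageReport:
    """Bookkeeping of one linkage run; drops are broken out by reason."""

    n_visits_in: int
    n_linked: int
    n_dropped_no_exposure: int
    per_governorate: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.n_linked + self.n_dropped_no_exposure == self.n_visits_in

    def to_dict(self) -> dict:
        return {
            "n_visits_in": self.n_visits_in,
            "n_linked": self.n_linked,
            "n_dropped_no_exposure": self.n_dropped_no_exposure,
            "per_governorate": dict(self.per_governorate),
        }


def match_visits(
    visits: pd.DataFrame,
    exposure: pd.DataFrame,
    *,
    governorate_column: str = "governorate",
) -> tuple[pd.DataFrame, LinkageReport]:
    """Inner-join visits to same-date, same-governorate daily exposure.

    The exposure table must have at most one row per (date, governorate);
    duplicates make the match ambiguous and raise.  Visits whose key is
    absent from the exposure table, or whose exposure row carries no AQI
    value for any pollutant, are dropped and counted.  Multiple visits on
    one day all receive the same exposure row.
    """
    aqi_cols = [c for c in exposure.columns if c.startswith("aqi_")]
    if not aqi_cols:
        raise ValueError("exposure table has no aqi_* columns")
    exp = exposure.copy()
    exp["date"] = pd.to_datetime(exp["date"]).dt.date
    dup = exp.duplicated(subset=["date", "governorate"])
    if dup.any():
        first = exp.loc[dup.idxmax()]
        raise ValueError(
            f"duplicate exposure rows for ({first['date']}, {first['governorate']}); "
            "ambiguous match"
        )
    vis = visits.copy()
    vis["visit_date"] = pd.to_datetime(vis["visit_date"]).dt.date
    # An exposure row that is entirely missing after imputation matches
    # nothing usefully; treat it as absent.
    usable = exp[exp[aqi_cols].notna().any(axis=1)]
    # Re-linking an already linked table replaces its exposure columns,
    # which makes the join idempotent.
    stale = [
        c for c in usable.columns
        if c in vis.columns and c not in ("governorate", governorate_column)
    ]
    vis = vis.drop(columns=stale)
    merged = vis.merge(
        usable,
        left_on=["visit_date", governorate_column],
        right_on=["date", "governorate"],
        how="left",
        suffixes=("", "_exposure"),
        indicator=True,
    )
    linked = merged[merged["_merge"] == "both"].drop(columns=["_merge"])
    n_in = len(vis)
    n_linked = len(linked)
    report = LinkageReport(
        n_visits_in=n_in,
        n_linked=n_linked,
        n_dropped_no_exposure=n_in - n_linked,
        per_governorate=linked.groupby(governorate_column).size().to_dict(),
    )
    return linked.reset_index(drop=True), report
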