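"""Air Quality Index conversion over a declarative breakpoint table.

The AQI maps a pollutant concentration onto a dimensionless 0--500 health
scale by piecewise-linear interpolation between tabulated breakpoints:

    I_p = (I_high - I_low) / (C_high - C_low) * (C_p - C_low) + I_low

where ``(C_low, C_high)`` is the concentration range of the breakpoint row
containing ``C_p`` and ``(I_low, I_high)`` the corresponding index range.
The bundled default table is the Kuwait AQI (six categories per pollutant,
PM10 in µg/m³, gaseous pollutants in ppm).

Published breakpoint tables are discretized, so consecutive rows abut with
small gaps (e.g. PM10 90 / 90.1).  Concentrations strictly inside such a
gap are resolved to the row with the nearest ``conc_low`` above, which
preserves monotonicity of the conversion.  Concentrations above the top
breakpoint clip to the top index with a flag rather than extrapolate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

POLLUTANTS = ("PM10", "NO2", "SO2", "O3", "CO")

#: Pollutants averaged over a full day vs. an 8-hour rolling window.
WINDOW_24H = ("PM10", "NO2", "SO2")
WINDOW_8H = ("O3", "CO")

#: Molar masses (g/mol) for the optional ppm <-> µg/m³ conversion layer.
_MOLAR_MASS = {"NO2": 46.0055, "SO2": 64.066, "O3": 47.9982, "CO": 28.010}

_GAS_CONSTANT = 8.31446  # J/(mol·K)


class BreakpointValidationError(ValueError):
    """Raised when a breakpoint table violates its structural invariants."""


@dataclass(frozen=True)
class BreakpointRow:
    """One (category, index range, concentration range) cell of the table."""

    pollutant: str
    category_label: str
    index_low: float
    index_high: float
    conc_low: float
    conc_high: float
    averaging_window: int

    def contains(self, concentration: float) -> bool:
        return self.conc_low <= concentration <= self.conc_high


@dataclass
class BreakpointTable:
    """Validated collection of breakpoint rows, grouped per pollutant."""

    rows: list[BreakpointRow]
    source_label: str = "unnamed"
    _by_pollutant: dict[str, list[BreakpointRow]] = field(
        default_factory=dict, repr=False
    )

    def __post_init__(self) -> None:
        for row in self.rows:
            self._by_pollutant.setdefault(row.pollutant, []).append(row)
        for pollutant, rows in self._by_pollutant.items():
            rows.sort(key=lambda r: r.conc_low)
            _validate_pollutant_rows(pollutant, rows)
        if not self._by_pollutant:
            raise BreakpointValidationError("breakpoint table is empty")

    @property
    def pollutants(self) -> tuple[str, ...]:
        return tuple(self._by_pollutant)

    def rows_for(self, pollutant: str) -> list[BreakpointRow]:
        try:
            return self._by_pollutant[pollutant]
        except KeyError:
            raise KeyError(
                f"unknown pollutant {pollutant!r}; table covers {self.pollutants}"
            ) from None

    def top_index(self, pollutant: str) -> float:
        return self.rows_for(pollutant)[-1].index_high


@dataclass(frozen=True)
class AQIValue:
    """Result of one concentration -> index conversion."""

    pollutant: str
    concentration: float
    index: float
    category_label: str
    clipped: bool = False


def _validate_pollutant_rows(pollutant: str, rows: list[BreakpointRow]) -> None:
    for row in rows:
        if not (row.index_low < row.index_high):
            raise BreakpointValidationError(
                f"{pollutant} {row.category_label!r}: index_low must be < index_high"
            )
        if not (row.conc_low < row.conc_high):
            raise BreakpointValidationError(
                f"{pollutant} {row.category_label!r}: conc_low must be < conc_high"
            )
    for prev, cur in zip(rows, rows[1:]):
        if cur.conc_low <= prev.conc_high:
            raise BreakpointValidationError(
                f"{pollutant}: rows {prev.category_label!r} and "
                f"{cur.category_label!r} overlap in concentration "
                f"({prev.conc_high} >= {cur.conc_low})"
            )
        if cur.index_low <= prev.index_high:
            raise BreakpointValidationError(
                f"{pollutant}: rows {prev.category_label!r} and "
                f"{cur.category_label!r} are not jointly monotone in index"
            )


def _bundled_source() -> Path:
    return Path(str(resources.files("aqra").joinpath("data/kuwait_aqi_breakpoints.csv")))


def load_breakpoint_table(source: str | Path | None = None) -> BreakpointTable:
    """Load and validate a breakpoint table from delimited text.

    Parameters
    ----------
    source:
        Path to a CSV with columns ``pollutant, category, index_low,
        index_high, conc_low, conc_high, window_hours``.  ``None`` loads the
        bundled Kuwait table.
    """
    label = "Kuwait AQI (bundled)" if source is None else str(source)
    path = _bundled_source() if source is None else Path(source)
    frame = pd.read_csv(path)
    required = {
        "pollutant", "category", "index_low", "index_high",
        "conc_low", "conc_high", "window_hours",
    }
    missing = required - set(frame.columns)
    if missing:
        raise BreakpointValidationError(
            f"breakpoint source {label!r} lacks columns {sorted(missing)}"
        )
    if frame.empty:
        raise BreakpointValidationError(f"breakpoint source {label!r} has no rows")
    rows = [
        BreakpointRow(
            pollutant=str(r.pollutant),
            category_label=str(r.category),
            index_low=float(r.index_low),
            index_high=float(r.index_high),
            conc_low=float(r.conc_low),
            conc_high=float(r.conc_high),
            averaging_window=int(r.window_hours),
        )
        for r in frame.itertuples()
    ]
    return BreakpointTable(rows=rows, source_label=label)


def _match_row(
    rows: list[BreakpointRow], concentration: float
) -> tuple[BreakpointRow, bool]:
    """Return (row, clipped) for a concentration, applying the gap rule."""
    for row in rows:
        if row.contains(concentration):
            return row, False
    top = rows[-1]
    if concentration > top.conc_high:
        return top, True
    # Inside an inter-row discretization gap: take the nearest row above.
    for row in rows:
        if concentration < row.conc_low:
            return row, False
    raise AssertionError("unreachable: concentration not matched")  # pragma: no cover


def truncate_concentration(pollutant: str, concentration: float) -> float:
    """USEPA-style truncation of the raw concentration before lookup.

    PM10 truncates to integer µg/m³; gases to three decimals (ppm).  Off by
    default in :func:`compute_aqi`; the published conversion used the raw
    value.
    """
    if pollutant == "PM10":
        return math.floor(concentration)
    return math.floor(concentration * 1000.0) / 1000.0


def compute_aqi(
    pollutant: str,
    concentration: float,
    table: BreakpointTable,
    *,
    usepa_truncation: bool = False,
) -> AQIValue:
    """Convert a pollutant concentration to its Air Quality Index value.

    Concentrations inside a discretization gap use the next row up;
    concentrations above the top breakpoint return the top index with
    ``clipped=True``.
    """
    if not math.isfinite(concentration) or concentration < 0:
        raise ValueError(
            f"concentration must be finite and >= 0, got {concentration!r}"
        )
    rows = table.rows_for(pollutant)
    value = (
        truncate_concentration(pollutant, concentration)
        if usepa_truncation
        else concentration
    )
    row, clipped = _match_row(rows, value)
    if clipped:
        index = row.index_high
    else:
        c = min(max(value, row.conc_low), row.conc_high)
        slope = (row.index_high - row.index_low) / (row.conc_high - row.conc_low)
        index = slope * (c - row.conc_low) + row.index_low
    return AQIValue(
        pollutant=pollutant,
        concentration=concentration,
        index=index,
        category_label=row.category_label,
        clipped=clipped,
    )


def classify_category(index: float, table: BreakpointTable) -> str:
    """Category label for an index value (values above 500 are Hazardous)."""
    if index < 0 or not math.isfinite(index):
        raise ValueError(f"index must be finite and >= 0, got {index!r}")
    rows = table.rows_for(table.pollutants[0])
    for row in rows:
        if row.index_low <= index <= row.index_high:
            return row.category_label
    if index > rows[-1].index_high:
        return rows[-1].category_label
    for row in rows:  # index inside a discretization gap such as (50, 51)
        if index < row.index_low:
            return row.category_label
    raise AssertionError("unreachable")  # pragma: no cover


def concentration_for_index(
    pollutant: str, index: float, table: BreakpointTable
) -> float:
    """Inverse conversion: the concentration whose AQI equals ``index``.

    Used by the synthetic generator to realize drawn index values as
    physical concentrations.  Indices above the top of the scale map to the
    top breakpoint concentration; indices inside an index discretization
    gap map to the next row's lower concentration bound.
    """
    if index < 0 or not math.isfinite(index):
        raise ValueError(f"index must be finite and >= 0, got {index!r}")
    rows = table.rows_for(pollutant)
    for row in rows:
        if row.index_low <= index <= row.index_high:
            frac = (index - row.index_low) / (row.index_high - row.index_low)
            return row.conc_low + frac * (row.conc_high - row.conc_low)
    if index > rows[-1].index_high:
        return rows[-1].conc_high
    for row in rows:
        if index < row.index_low:
            return row.conc_low
    raise AssertionError("unreachable")  # pragma: no cover


def convert_gas_units(
    value: float,
    pollutant: str,
    *,
    to: str,
    temperature_c: float = 25.0,
    pressure_kpa: float = 101.325,
) -> float:
    """Convert a gaseous concentration between ppm and µg/m³.

    Ideal-gas conversion at the given temperature and pressure; PM10 is a
    gravimetric measure and is rejected.
    """
    if pollutant not in _MOLAR_MASS:
        raise ValueError(f"no molar mass for {pollutant!r}; gases only")
    molar_volume = _GAS_CONSTANT * (temperature_c + 273.15) / pressure_kpa  # L/mol
    factor = 1000.0 * _MOLAR_MASS[pollutant] / molar_volume  # µg/m³ per ppm
    if to == "ug_m3":
        return value * factor
    if to == "ppm":
        return value / factor
    raise ValueError(f"unknown target unit {to!r}; use 'ppm' or 'ug_m3'")


def aqi_table(
    concentrations: pd.DataFrame,
    table: BreakpointTable,
    *,
    usepa_truncation: bool = False,
) -> pd.DataFrame:
    """Vectorized conversion of a (pollutant, concentration) frame.

    Returns the input with ``aqi``, ``category`` and ``clipped`` columns
    appended; missing concentrations yield missing AQI.
    """
    out = concentrations.copy()
    idx, cat, clip = [], [], []
    for r in out.itertuples():
        c = getattr(r, "concentration")
        if pd.isna(c):
            idx.append(float("nan"))
            cat.append(None)
            clip.append(False)
            continue
        v = compute_aqi(
            getattr(r, "pollutant"), float(c), table, usepa_truncation=usepa_truncation
        )
        idx.append(v.index)
        cat.append(v.category_label)
        clip.append(v.clipped)
    out["aqi"] = idx
    out["category"] = cat
    out["clipped"] = clip
    return out


def validate_rows(rows: Iterable[BreakpointRow]) -> BreakpointTable:
    """Build a validated table from in-memory rows (testing/config hook)."""
    return BreakpointTable(rows=list(rows), source_label="in-memory")
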