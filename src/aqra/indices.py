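"""Composite rheumatoid-arthritis disease-activity indices.

DAS-28 combines the 28-joint tender and swollen counts, an inflammation
marker (ESR in mm/h, or CRP in mg/L as an alternative) and the patient
global-health assessment (0--100).  The default evaluates the linear form

    DAS-28 = 0.56*TJC28 + 0.28*SJC28 + 0.70*ln(marker) + 0.014*GH

with the same coefficients for either marker.  The canonical published
DAS-28 uses square roots of the joint counts; that variant is available
behind ``sqrt_counts=True`` but is not the default here.

CDAI is the plain sum TJC28 + SJC28 + PaGH + PrGH with the global
assessments on 0--10 scales (range 0--76).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

#: Literature cutoffs for activity bands.  These are conventional clinical
#: thresholds shipped as configurable defaults, not derived quantities.
DEFAULT_THRESHOLDS = {
    "das28": (2.6, 3.2, 5.1),
    "cdai": (2.8, 10.0, 22.0),
}

_CATEGORIES = ("remission", "low", "moderate", "high")


def _check_range(name: str, value: float, low: float, high: float) -> None:
    if not (low <= value <= high):
        raise ValueError(f"{name}={value!r} outside [{low}, {high}]")


def das28(
    tjc28: float,
    sjc28: float,
    marker: float,
    gh: float,
    *,
    sqrt_counts: bool = False,
) -> float:
    """Disease Activity Score over 28 joints.

    Parameters
    ----------
    marker:
        ESR (mm/h) or CRP (mg/L); must be strictly positive since it
        enters through a logarithm.
    sqrt_counts:
        Use the canonical square-root joint-count form instead of the
        linear default.
    """
    _check_range("tjc28", tjc28, 0, 28)
    _check_range("sjc28", sjc28, 0, 28)
    _check_range("gh", gh, 0, 100)
    if marker <= 0:
        raise ValueError(f"inflammation marker must be > 0, got {marker!r}")
    tj, sj = (math.sqrt(tjc28), math.sqrt(sjc28)) if sqrt_counts else (tjc28, sjc28)
    return 0.56 * tj + 0.28 * sj + 0.70 * math.log(marker) + 0.014 * gh


def cdai(tjc28: float, sjc28: float, pagh: float, prgh: float) -> float:
    """Clinical Disease Activity Index: TJC28 + SJC28 + PaGH + PrGH."""
    _check_range("tjc28", tjc28, 0, 28)
    _check_range("sjc28", sjc28, 0, 28)
    _check_range("pagh", pagh, 0, 10)
    _check_range("prgh", prgh, 0, 10)
    return tjc28 + sjc28 + pagh + prgh


def classify_activity(
    score: float,
    index_kind: str = "das28",
    thresholds: tuple[float, float, float] | None = None,
) -> str:
    """Band a score into remission / low / moderate / high activity.

    Thresholds are upper bounds of the first three bands and must be
    strictly increasing; defaults are the conventional clinical cutoffs.
    """
    cuts = thresholds if thresholds is not None else DEFAULT_THRESHOLDS[index_kind]
    if not (cuts[0] < cuts[1] < cuts[2]):
        raise ValueError(f"thresholds must be strictly increasing, got {cuts}")
    for cut, label in zip(cuts, _CATEGORIES):
        if score <= cut:
            return label
    return _CATEGORIES[-1]


def add_indices(
    visits: pd.DataFrame,
    *,
    marker_kind: str = "ESR",
    sqrt_counts: bool = False,
) -> pd.DataFrame:
    """Append ``das28`` and ``cdai`` columns to a visit registry frame.

    ``marker_kind`` selects which inflammation marker feeds DAS-28.
    """
    if marker_kind not in ("ESR", "CRP"):
        raise ValueError(f"marker_kind must be 'ESR' or 'CRP', got {marker_kind!r}")
    out = visits.copy()
    marker = out["esr" if marker_kind == "ESR" else "crp"].to_numpy(dtype=float)
    tj = out["tjc28"].to_numpy(dtype=float)
    sj = out["sjc28"].to_numpy(dtype=float)
    gh = out["gh"].to_numpy(dtype=float)
    if np.any(marker <= 0):
        raise ValueError("inflammation marker must be > 0 for every visit")
    if sqrt_counts:
        tj_term, sj_term = np.sqrt(tj), np.sqrt(sj)
    else:
        tj_term, sj_term = tj, sj
    out["das28"] = 0.56 * tj_term + 0.28 * sj_term + 0.70 * np.log(marker) + 0.014 * gh
    out["cdai"] = tj + sj + out["pagh"].to_numpy(dtype=float) + out["prgh"].to_numpy(
        dtype=float
    )
    out["marker_used"] = marker_kind
    return out
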