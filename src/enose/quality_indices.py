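"""Freshness grading rules and internal-standard volatile quantification.

Oyster freshness is graded on a 3-level scale (1 = fresh, 2 = sub-fresh,
3 = decayed) from any of three laboratory quality indices:

* total volatile basic nitrogen (TVB-N, mg/100 g) — amine/ammonia products
  of protein degradation, the label-defining index for the classifier;
* total plate count (TPC, log CFU/g) — aerobic microbial load;
* sensory score — the mean of three trained-panel sub-scores
  (color, odor, tissue status), each on a 0–10 scale.

Dimethyl sulfide, a late-spoilage sulfur volatile, is quantified from GC-MS
peak areas by the internal-standard ratio method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FRESH",
    "SUB_FRESH",
    "DECAYED",
    "TVBN_FRESH_MAX",
    "TVBN_SUBFRESH_MAX",
    "TPC_FRESH_MAX",
    "TPC_SUBFRESH_MAX",
    "SENSORY_FRESH_MIN",
    "SENSORY_SUBFRESH_MIN",
    "DmsQuantInput",
    "classify_tvbn",
    "classify_tpc",
    "classify_sensory",
    "quantify_dms",
    "grade_series",
]

FRESH = 1
SUB_FRESH = 2
DECAYED = 3

# Grade boundaries. Boundary values fall in the sub-fresh class: the fresh
# and decayed ranges are open ("< 15", "> 25"), the middle range closed.
TVBN_FRESH_MAX = 15.0  # mg / 100 g
TVBN_SUBFRESH_MAX = 25.0  # mg / 100 g
TPC_FRESH_MAX = 6.70  # log CFU / g
TPC_SUBFRESH_MAX = 7.70  # log CFU / g
SENSORY_FRESH_MIN = 8.0  # mean panel score out of 10
SENSORY_SUBFRESH_MIN = 5.0

GRADE_NAMES = {FRESH: "fresh", SUB_FRESH: "sub-fresh", DECAYED: "decayed"}


def _check_finite_nonnegative(value: float, name: str) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    if value < 0:
        raise ValueError(f"{name} must be nonnegative, got {value!r}")
    return value


def classify_tvbn(tvbn_mg_per_100g: float) -> int:
    """Grade a TVB-N measurement (mg per 100 g) on the 1/2/3 freshness scale.

    Below 15 mg/100 g is fresh (1); 15–25 mg/100 g inclusive is sub-fresh
    (2); above 25 mg/100 g is decayed (3).
    """
    v = _check_finite_nonnegative(tvbn_mg_per_100g, "tvbn_mg_per_100g")
    if v < TVBN_FRESH_MAX:
        return FRESH
    if v <= TVBN_SUBFRESH_MAX:
        return SUB_FRESH
    return DECAYED


def classify_tpc(tpc_log_cfu_per_g: float) -> int:
    """Grade a total plate count (log CFU/g): <6.70 fresh, 6.70–7.70
    sub-fresh, >7.70 decayed."""
    v = _check_finite_nonnegative(tpc_log_cfu_per_g, "tpc_log_cfu_per_g")
    if v < TPC_FRESH_MAX:
        return FRESH
    if v <= TPC_SUBFRESH_MAX:
        return SUB_FRESH
    return DECAYED


def classify_sensory(color: float, odor: float, tissue: float) -> int:
    """Grade the unweighted mean of three 0–10 panel sub-scores.

    A mean of 8 or above is fresh; 5 (inclusive) up to 8 is sub-fresh;
    below 5 is decayed. Note the orientation: higher scores are fresher,
    the opposite of the chemical indices.
    """
    scores = []
    for name, s in (("color", color), ("odor", odor), ("tissue", tissue)):
        s = float(s)
        if not math.isfinite(s) or not 0.0 <= s <= 10.0:
            raise ValueError(f"sensory sub-score {name} must be in [0, 10], got {s!r}")
        scores.append(s)
    mean = sum(scores) / 3.0
    if mean >= SENSORY_FRESH_MIN:
        return FRESH
    if mean >= SENSORY_SUBFRESH_MIN:
        return SUB_FRESH
    return DECAYED


@dataclass(frozen=True)
class DmsQuantInput:
    """Inputs for internal-standard quantification of dimethyl sulfide.

    Attributes
    ----------
    standard_ppm:
        Concentration of the dimethyl sulfide standard (ppm).
    sample_peak_area:
        GC-MS peak area of the sample, arbitrary area units.
    standard_peak_area:
        GC-MS peak area of the standard, same units as the sample's.
    """

    standard_ppm: float
    sample_peak_area: float
    standard_peak_area: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.standard_ppm) and self.standard_ppm > 0):
            raise ValueError("standard_ppm must be positive and finite")
        if not (math.isfinite(self.sample_peak_area) and self.sample_peak_area >= 0):
            raise ValueError("sample_peak_area must be nonnegative and finite")
        if not (math.isfinite(self.standard_peak_area) and self.standard_peak_area > 0):
            raise ValueError("standard_peak_area must be positive and finite")


def quantify_dms(
    standard_ppm: float | DmsQuantInput,
    sample_peak_area: float | None = None,
    standard_peak_area: float | None = None,
) -> float:
    """Concentration of dimethyl sulfide by the internal-standard ratio.

    The sample concentration is the standard concentration scaled by the
    ratio of the two peak areas: ``standard_ppm * sample_area / standard_area``.
    Accepts either a :class:`DmsQuantInput` or the three scalars. Returns
    full precision; round for display (reports use 3 significant figures).
    """
    if isinstance(standard_ppm, DmsQuantInput):
        q = standard_ppm
    else:
        q = DmsQuantInput(standard_ppm, sample_peak_area, standard_peak_area)
    return q.standard_ppm * q.sample_peak_area / q.standard_peak_area


_RULES = {
    "tvbn": ("tvbn", classify_tvbn),
    "tpc": ("tpc", classify_tpc),
    "sensory": (("color", "odor", "tissue"), classify_sensory),
}


def grade_series(records: pd.DataFrame | Iterable, rule: str = "tvbn") -> np.ndarray:
    """Apply one grading rule element-wise to a quality table.

    Parameters
    ----------
    records:
        Quality table: a DataFrame with columns ``tvbn``, ``tpc``, ``color``,
        ``odor``, ``tissue`` (only those the rule needs are required), or any
        sequence of objects exposing same-named attributes.
    rule:
        ``"tvbn"``, ``"tpc"`` or ``"sensory"``.

    Returns an integer array of grades, one per record.
    """
    if rule not in _RULES:
        raise ValueError(f"unknown grading rule {rule!r}; expected one of {sorted(_RULES)}")
    cols, func = _RULES[rule]
    if not isinstance(records, pd.DataFrame):
        records = _records_to_frame(records)
    if len(records) == 0:
        raise ValueError("cannot grade an empty quality table")
    if isinstance(cols, str):
        missing = [cols] if cols not in records.columns else []
        args = (records[cols].to_numpy(),) if not missing else ()
    else:
        missing = [c for c in cols if c not in records.columns]
        args = tuple(records[c].to_numpy() for c in cols) if not missing else ()
    if missing:
        raise ValueError(f"quality table lacks column(s) {missing} required by rule {rule!r}")
    return np.array([func(*row) for row in zip(*args)], dtype=np.int64)


def _records_to_frame(records: Iterable) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "tvbn": getattr(r, "tvbn_mg_per_100g", getattr(r, "tvbn", np.nan)),
                "tpc": getattr(r, "tpc_log_cfu_per_g", getattr(r, "tpc", np.nan)),
                "color": getattr(r, "sensory_color", getattr(r, "color", np.nan)),
                "odor": getattr(r, "sensory_odor", getattr(r, "odor", np.nan)),
                "tissue": getattr(r, "sensory_tissue", getattr(r, "tissue", np.nan)),
            }
        )
    return pd.DataFrame(rows)
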