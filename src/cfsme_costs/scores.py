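"""Scoring of the four patient-reported inventories.

Instruments and ranges: the 11-item Chalder Fatigue Scale under 0-3 item
scoring (total 0-33); the 10-item SF-36 physical-function subscale with items
in {0, 5, 10} (total 0-100, 0 = most disabled); the two 7-item HADS subscales
(anxiety and depression, each 0-21); and a 0-100 visual-analogue pain rating.

Missing-item rule: a total is missing if more than one item is unanswered;
with exactly one unanswered item an adjusted total is pro-rated from the
answered items by n/(n-1) — equivalent to imputing the mean of the answered
items — and rounded half-up to the instrument's attainable score grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import cohort

#: name -> (item columns, per-item maximum, grid step, scale maximum)
INVENTORIES: dict[str, tuple[tuple[str, ...], int, int, int]] = {
    "chalder": (cohort.CHALDER_ITEMS, 3, 1, 33),
    "sf36_pf": (cohort.SF36PF_ITEMS, 10, 5, 100),
    "hads_anxiety": (cohort.HADS_A_ITEMS, 3, 1, 21),
    "hads_depression": (cohort.HADS_D_ITEMS, 3, 1, 21),
}

SCALE_MAXIMA = {
    "chalder": 33,
    "sf36_pf": 100,
    "hads_anxiety": 21,
    "hads_depression": 21,
    "vas_pain": 100,
}

SCORE_COLUMNS = (
    "chalder_total",
    "sf36pf_total",
    "hads_anxiety",
    "hads_depression",
    "vas_pain",
)


@dataclass(frozen=True)
class ItemResponses:
    """Item-level responses for one patient; ``None`` marks unanswered items."""

    chalder: Sequence[float | None]
    sf36_pf: Sequence[float | None]
    hads_anxiety: Sequence[float | None]
    hads_depression: Sequence[float | None]
    vas_pain: float | None = None


@dataclass(frozen=True)
class ScoreSet:
    """The five inventory totals; ``None`` where the missing rule fired."""

    chalder_total: float | None
    sf36pf_total: float | None
    hads_anxiety: float | None
    hads_depression: float | None
    vas_pain: float | None


def _round_half_up(x: float, step: int) -> float:
    return math.floor(x / step + 0.5) * step


def score_inventory(
    items: Sequence[float | None],
    n_items: int,
    item_max: int,
    step: int = 1,
) -> float | None:
    """Total an item vector under the missing-item rule.

    0 missing -> plain sum; exactly 1 missing -> sum of answered x
    n/(n-1), rounded half-up to the nearest multiple of ``step``; >1
    missing -> ``None``. Out-of-range answered items raise ``ValueError``
    naming the offending index.
    """
    if len(items) != n_items:
        raise ValueError(f"expected {n_items} items, got {len(items)}")
    answered = []
    n_missing = 0
    for i, v in enumerate(items):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            n_missing += 1
            continue
        if not (0 <= v <= item_max):
            raise ValueError(f"item {i} value {v!r} outside [0, {item_max}]")
        if step > 1 and float(v) % step:
            raise ValueError(f"item {i} value {v!r} not on the {step}-point grid")
        answered.append(float(v))
    if n_missing > 1:
        return None
    total = sum(answered)
    if n_missing == 1:
        total = _round_half_up(total * n_items / (n_items - 1), step)
    return float(total)


def score_all(responses: ItemResponses) -> ScoreSet:
    """Score every inventory for one patient; VAS passes through unchanged."""
    c, _, cstep, _ = INVENTORIES["chalder"]
    vas = responses.vas_pain
    if vas is not None and not (0 <= vas <= 100):
        raise ValueError(f"vas_pain {vas!r} outside [0, 100]")
    return ScoreSet(
        chalder_total=score_inventory(responses.chalder, 11, 3, 1),
        sf36pf_total=score_inventory(responses.sf36_pf, 10, 10, 5),
        hads_anxiety=score_inventory(responses.hads_anxiety, 7, 3, 1),
        hads_depression=score_inventory(responses.hads_depression, 7, 3, 1),
        vas_pain=None if vas is None or (isinstance(vas, float) and math.isnan(vas)) else float(vas),
    )


def score_matrix(items: np.ndarray, n_items: int, step: int = 1) -> np.ndarray:
    """Vectorised :func:`score_inventory` over a (patients x items) array.

    NaN marks unanswered items; rows with >1 NaN score NaN.
    """
    items = np.asarray(items, dtype=float)
    n_missing = np.isnan(items).sum(axis=1)
    answered_sum = np.nansum(items, axis=1)
    total = answered_sum.copy()
    one = n_missing == 1
    total[one] = np.floor(answered_sum[one] * n_items / (n_items - 1) / step + 0.5) * step
    total[n_missing > 1] = np.nan
    return total


def score_table(frame: pd.DataFrame) -> pd.DataFrame:
    """Append the five total-score columns to a patient table.

    Returns a copy with :data:`SCORE_COLUMNS` added; the vectorised path is
    used so cohort-scale tables score in milliseconds.
    """
    out = frame.copy()
    out["chalder_total"] = score_matrix(frame[list(cohort.CHALDER_ITEMS)].to_numpy(), 11, 1)
    out["sf36pf_total"] = score_matrix(frame[list(cohort.SF36PF_ITEMS)].to_numpy(), 10, 5)
    out["hads_anxiety"] = score_matrix(frame[list(cohort.HADS_A_ITEMS)].to_numpy(), 7, 1)
    out["hads_depression"] = score_matrix(frame[list(cohort.HADS_D_ITEMS)].to_numpy(), 7, 1)
    out["vas_pain"] = pd.to_numeric(frame["vas"], errors="coerce")
    return out


def rescale_for_regression(score, scale_max: float):
    """Map a total onto the common 0-10 regression scale (score x 10 / max).

    Accepts scalars or arrays; missing values pass through as NaN.
    """
    if scale_max <= 0:
        raise ValueError("scale_max must be positive")
    return np.multiply(score, 10.0 / scale_max)
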