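"""Classification of N-fractions into relative-expression categories.

A measurement's N-fraction (percent contribution of the japonica homeolog)
maps onto seven bias categories that partition [0, 100], with left-closed
half-open intervals and the top interval closed at 100:

====================  ==============
category              N-fraction
====================  ==============
COMPLETE_9            [0, 5)
STRONG_9              [5, 20)
BIASED_9              [20, 40)
EQUIVALENT            [40, 60)
BIASED_N              [60, 80)
STRONG_N              [80, 95)
COMPLETE_N            [95, 100]
====================  ==============

An undefined fraction (both allele signals below detection) is
NO_EXPRESSION: silencing of both copies, a distinct state that sets
neither allele-specific silencing flag.

The half-open boundary convention is a documented tie-break: the category
bands are printed as touching ranges, so boundary membership must be fixed
by convention; under continuous measurement noise it affects only
measure-zero inputs.
"""
from __future__ import annotations

import math
from typing import Iterable

import numpy as np
import pandas as pd

from .model import BiasCategory

#: Interior breakpoints of the seven-way partition of [0, 100].
_BREAKS = np.array([5.0, 20.0, 40.0, 60.0, 80.0, 95.0])

#: Categories in ascending N-fraction order.
_ORDERED = (
    BiasCategory.COMPLETE_9,
    BiasCategory.STRONG_9,
    BiasCategory.BIASED_9,
    BiasCategory.EQUIVALENT,
    BiasCategory.BIASED_N,
    BiasCategory.STRONG_N,
    BiasCategory.COMPLETE_N,
)


def classify_bias(n_fraction: float | None) -> BiasCategory:
    """Map one N-fraction to its bias category.

    ``None`` or NaN (the undefined flag) maps to NO_EXPRESSION; any other
    value must lie in [0, 100].
    """
    if n_fraction is None or (isinstance(n_fraction, float) and math.isnan(n_fraction)):
        return BiasCategory.NO_EXPRESSION
    f = float(n_fraction)
    if not 0.0 <= f <= 100.0:
        raise ValueError(f"n_fraction must be in [0, 100], got {f}")
    return _ORDERED[int(np.searchsorted(_BREAKS, f, side="right"))]


def classify_bias_array(n_fraction: np.ndarray) -> np.ndarray:
    """Vectorised :func:`classify_bias`; NaN means undefined."""
    f = np.asarray(n_fraction, dtype=float)
    defined = ~np.isnan(f)
    if np.any((f[defined] < 0) | (f[defined] > 100)):
        raise ValueError("n_fraction values must be in [0, 100]")
    idx = np.searchsorted(_BREAKS, np.where(defined, f, 0.0), side="right")
    cats = np.array([c.value for c in _ORDERED], dtype=object)[idx]
    cats[~defined] = BiasCategory.NO_EXPRESSION.value
    return cats


def call_silencing(category: BiasCategory | str) -> tuple[bool, bool]:
    """Per-homeolog silencing flags ``(silenced_n, silenced_9)``.

    Only the two complete-bias categories silence an allele: COMPLETE_9
    means the japonica (N) copy is off, COMPLETE_N means the indica (9)
    copy is off. NO_EXPRESSION silences *both* copies but is its own
    state, so it sets neither allele-specific flag.
    """
    category = BiasCategory(category)
    return (
        category is BiasCategory.COMPLETE_9,
        category is BiasCategory.COMPLETE_N,
    )


def classify_table(records: pd.DataFrame) -> pd.DataFrame:
    """Annotate a validated assay frame with category and silencing calls.

    Adds ``category``, ``silenced_n``, ``silenced_9``, ``expressed_n``,
    ``expressed_9``. A homeolog is *expressed* when it is not silenced and
    the measurement is not NO_EXPRESSION.
    """
    frac = records["n_fraction"].to_numpy(dtype=float)
    if "below_detection" in records.columns:
        frac = np.where(records["below_detection"].to_numpy(bool), np.nan, frac)
    cats = classify_bias_array(frac)
    calls = records.copy()
    calls["category"] = cats
    silenced_n = cats == BiasCategory.COMPLETE_9.value
    silenced_9 = cats == BiasCategory.COMPLETE_N.value
    no_expr = cats == BiasCategory.NO_EXPRESSION.value
    calls["silenced_n"] = silenced_n
    calls["silenced_9"] = silenced_9
    calls["expressed_n"] = ~silenced_n & ~no_expr
    calls["expressed_9"] = ~silenced_9 & ~no_expr
    return calls


def tabulate_states(
    calls: pd.DataFrame, by: Iterable[str] = ("group", "tissue")
) -> pd.DataFrame:
    """Category counts and within-cell proportions.

    Returns one row per (*by* keys, category) with ``count`` and
    ``proportion``; proportions sum to 1 within each *by* cell. An empty
    input yields an empty table with the same header.
    """
    by = list(by)
    cols = by + ["category", "count", "proportion"]
    if calls.empty:
        return pd.DataFrame(columns=cols)
    counts = (
        calls.groupby(by + ["category"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    totals = counts.groupby(by, observed=True)["count"].transform("sum")
    counts["proportion"] = counts["count"] / totals
    return counts[cols].sort_values(cols[:-2]).reset_index(drop=True)
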