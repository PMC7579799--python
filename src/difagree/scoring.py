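"""PedsQL-style scale scoring on the 0-100 metric.

Raw responses count problems (0 = never a problem ... 4 = almost always a
problem); scores are reverse-transformed so that higher means better
health-related quality of life: ``score = (4 - raw) * 25``, i.e.
0 -> 100, 1 -> 75, 2 -> 50, 3 -> 25, 4 -> 0.  A subscale score is the mean
of its transformed answered items; the total score is the mean over all
answered items of the instrument (not the mean of subscale means, so an
8-item subscale weighs proportionally).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._exceptions import DifagreeError
from .data import ResponseMatrix

__all__ = ["transform_item", "subscale_score", "total_score", "score_table"]

#: minimum fraction of a subscale's items that must be answered for the
#: subscale score to be defined
MIN_ANSWERED_FRAC = 0.5


def transform_item(raw, n_categories: int = 5):
    """Reverse-transform a raw response onto the 0-100 metric.

    For the five-category scale this maps 0,1,2,3,4 to 100,75,50,25,0.
    Accepts scalars or arrays; NaN (missing) propagates.
    """
    arr = np.asarray(raw, dtype=float)
    top = n_categories - 1
    valid = np.isnan(arr) | ((arr >= 0) & (arr <= top) & (arr % 1 == 0))
    if not np.all(valid):
        raise DifagreeError(f"raw response out of range 0..{top}: {arr[~valid][:5]}")
    out = (top - arr) * (100.0 / top)
    return out if out.ndim else float(out)


def _mean_available(transformed, min_frac):
    """Mean of non-missing values; NaN when too few are available."""
    t = np.asarray(transformed, dtype=float)
    n_avail = np.sum(~np.isnan(t))
    if t.size == 0 or n_avail == 0 or n_avail < min_frac * t.size:
        return float("nan")
    return float(np.nanmean(t))


def subscale_score(m: ResponseMatrix, subscale, item_subset=None,
                   min_answered_frac: float = MIN_ANSWERED_FRAC):
    """Per-respondent subscale scores on the 0-100 metric.

    ``item_subset`` restricts the subscale to the listed items (used for
    DIF-corrected scores after removing uncancelled uniform-DIF items).
    When the subset is empty, or too few items are answered, the score is
    undefined (NaN) — a value, not an error.
    """
    items = m.spec.subscale_items(subscale)
    if item_subset is not None:
        unknown = set(item_subset) - set(items)
        if unknown:
            raise DifagreeError(f"items {sorted(unknown)} not in subscale {subscale!r}")
        items = [i for i in items if i in set(item_subset)]
    if not items:
        return np.full(m.n_respondents, np.nan)
    t = transform_item(m.responses(items), m.spec.n_categories)
    return np.array([_mean_available(row, min_answered_frac) for row in t])


def total_score(m: ResponseMatrix, min_answered_frac: float = MIN_ANSWERED_FRAC):
    """Per-respondent total score: mean of all answered transformed items."""
    t = transform_item(m.responses(), m.spec.n_categories)
    return np.array([_mean_available(row, min_answered_frac) for row in t])


def score_table(m: ResponseMatrix, item_subsets=None) -> pd.DataFrame:
    """Scores for every subscale plus the total, one row per respondent.

    ``item_subsets`` optionally maps subscale id -> retained item list (the
    DIF-corrected restriction); the total is then computed over the union of
    retained items.
    """
    out = m.table[["respondent_id", "dyad_id", "group"]].copy()
    retained_all = []
    for sub in m.spec.subscales:
        subset = None if item_subsets is None else item_subsets.get(sub)
        out[sub] = subscale_score(m, sub, item_subset=subset)
        retained_all.extend(
            m.spec.subscale_items(sub) if subset is None else list(subset)
        )
    if item_subsets is None:
        out["total"] = total_score(m)
    elif retained_all:
        t = transform_item(m.responses(retained_all), m.spec.n_categories)
        out["total"] = [_mean_available(row, 0.0) for row in t]
    else:
        out["total"] = np.nan
    return out
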