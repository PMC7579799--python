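"""Response data container, CSV I/O and the eligibility filter.

Data live in a :class:`ResponseMatrix`: one row per respondent, identifier
columns (``respondent_id``, ``dyad_id``, ``group``) plus one integer column
per item.  Missing responses are ``NaN``.  Respondents with more than 5% of
items missing are excluded before analysis; because every item-level
comparison needs both members of a dyad, an exclusion drops the whole dyad.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._exceptions import ConfigError, FormatError, ParseError
from .instrument import InstrumentSpec

__all__ = [
    "ResponseMatrix",
    "read_responses",
    "write_responses",
    "apply_eligibility_filter",
    "impute_missing",
]

ID_COLUMNS = ["respondent_id", "dyad_id", "group"]


class ResponseMatrix:
    """Respondents x items integer responses with group labels and dyad links.

    Parameters
    ----------
    table : pandas.DataFrame
        Must contain ``respondent_id``, ``dyad_id``, ``group`` and one column
        per instrument item.  Item cells are integers in
        ``0 .. n_categories-1`` or ``NaN`` (missing).
    spec : InstrumentSpec
        The instrument the columns refer to.
    """

    def __init__(self, table: pd.DataFrame, spec: InstrumentSpec):
        missing_cols = [c for c in ID_COLUMNS + spec.item_ids if c not in table.columns]
        if missing_cols:
            raise FormatError(f"response table lacks columns: {missing_cols}")
        table = table.loc[:, ID_COLUMNS + spec.item_ids].reset_index(drop=True)
        vals = table[spec.item_ids].to_numpy(dtype=float)
        bad = np.where(
            ~np.isnan(vals) & ((vals < 0) | (vals > spec.n_categories - 1) | (vals % 1 != 0))
        )
        if bad[0].size:
            r, c = bad[0][0], bad[1][0]
            raise ParseError(
                f"out-of-range response {vals[r, c]!r} for respondent "
                f"{table['respondent_id'].iloc[r]!r}, item {spec.item_ids[c]!r} "
                f"(allowed 0..{spec.n_categories - 1})"
            )
        dup = table.groupby(["dyad_id", "group"]).size()
        if (dup > 1).any():
            pair = dup[dup > 1].index[0]
            raise FormatError(f"dyad {pair[0]!r} has multiple {pair[1]!r} respondents")
        self.table = table
        self.spec = spec

    # -- basic views ---------------------------------------------------------
    @property
    def n_respondents(self):
        return len(self.table)

    @property
    def groups(self):
        return sorted(self.table["group"].unique().tolist())

    def responses(self, item_ids=None):
        """Float array of responses (NaN = missing), columns in item order."""
        cols = item_ids if item_ids is not None else self.spec.item_ids
        return self.table[cols].to_numpy(dtype=float)

    def missing_fraction(self):
        """Per-respondent fraction of missing items."""
        return np.isnan(self.responses()).mean(axis=1)

    def select_groups(self, groups):
        """Restrict to respondents whose ``group`` is in ``groups``."""
        for g in groups:
            if g not in set(self.table["group"]):
                raise ConfigError(f"unknown group label {g!r}")
        sub = self.table[self.table["group"].isin(groups)].reset_index(drop=True)
        return ResponseMatrix(sub, self.spec)

    def group_indicator(self, groups):
        """0/1 coding of ``group`` for a two-group analysis.

        The first label of ``groups`` is the reference (coded 0); the second
        is the focal group (coded 1).  A positive group effect therefore
        means the focal group endorses higher categories at equal trait.
        """
        if len(groups) != 2:
            raise ConfigError("a DIF analysis compares exactly two groups")
        g = self.table["group"].to_numpy()
        extra = set(g) - set(groups)
        if extra:
            raise ConfigError(f"matrix contains groups beyond the pair: {sorted(extra)}")
        return (g == groups[1]).astype(int)

    def copy_with(self, responses):
        """New matrix with the same ids/groups but replaced response values."""
        tab = self.table.copy()
        tab[self.spec.item_ids] = responses
        return ResponseMatrix(tab, self.spec)

    def __repr__(self):
        return (
            f"<ResponseMatrix {self.n_respondents} respondents x "
            f"{self.spec.n_items} items, groups={self.groups}>"
        )


def read_responses(path, spec: InstrumentSpec) -> ResponseMatrix:
    """Read a wide-format response CSV.

    Comma-separated UTF-8 with a header row; item columns named by item id;
    missing responses encoded as an empty cell or ``NA``.  Out-of-range or
    non-integer cells raise :class:`ParseError` naming the offending cell —
    values are never silently clamped.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in ID_COLUMNS + spec.item_ids if c not in raw.columns]
    if missing_cols:
        raise FormatError(f"{path}: missing required columns {missing_cols}")
    parsed = raw[ID_COLUMNS].copy()
    for col in spec.item_ids:
        cells = raw[col].str.strip()
        blank = (cells == "") | (cells.str.upper() == "NA")
        numeric = pd.to_numeric(cells.where(~blank, other=np.nan), errors="coerce")
        bad = (~blank) & numeric.isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}: cannot parse value {cells.iloc[row]!r} at row {row + 2}, "
                f"column {col!r}"
            )
        parsed[col] = numeric
    return ResponseMatrix(parsed, spec)


def write_responses(m: ResponseMatrix, path):
    """Write the matrix back to wide CSV (missing cells left empty)."""
    out = m.table.copy()
    for col in m.spec.item_ids:
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else str(int(v)))
    out.to_csv(path, index=False)


def apply_eligibility_filter(m: ResponseMatrix, max_missing_frac: float = 0.05):
    """Drop respondents with too many missing items, and their dyad partners.

    A respondent is retained when the fraction of missing items is at most
    ``max_missing_frac`` (default 5%).  When a respondent fails the filter
    the remaining members of the same dyad are dropped too, so every
    analyzed dyad is complete.

    Returns
    -------
    (ResponseMatrix, list)
        The filtered matrix and the ids of the excluded respondents
        (including the partners removed for dyad completeness).
    """
    frac = m.missing_fraction()
    fail = frac > max_missing_frac
    bad_dyads = set(m.table.loc[fail, "dyad_id"])
    drop = m.table["dyad_id"].isin(bad_dyads)
    excluded = m.table.loc[drop, "respondent_id"].tolist()
    kept = m.table[~drop].reset_index(drop=True)
    return ResponseMatrix(kept, m.spec), excluded


def impute_missing(m: ResponseMatrix, method: str = "item_mean_within_group"):
    """Fill missing responses for model fitting.

    ``item_mean_within_group`` (default) replaces each missing cell with the
    rounded mean of the same item within the respondent's group — a
    minimal-assumption default; the eligibility filter guarantees at most 5%
    of a retained respondent's items are touched.  ``none`` returns the
    matrix unchanged (downstream EAP scoring tolerates NaN; model fitting
    does not).
    """
    if method == "none":
        return m
    if method != "item_mean_within_group":
        raise ConfigError(f"unknown imputation method {method!r}")
    vals = m.responses()
    groups = m.table["group"].to_numpy()
    out = vals.copy()
    for g in np.unique(groups):
        rows = groups == g
        block = out[rows]
        col_mean = np.nanmean(np.where(np.isnan(block), np.nan, block), axis=0)
        col_mean = np.nan_to_num(col_mean, nan=(m.spec.n_categories - 1) / 2.0)
        fill = np.clip(np.round(col_mean), 0, m.spec.n_categories - 1)
        idx = np.isnan(block)
        block[idx] = np.broadcast_to(fill, block.shape)[idx]
        out[rows] = block
    return m.copy_with(out)
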