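"""The iterative hybrid OLR/IRT DIF engine.

Each subscale is analyzed on its own latent trait.  One iteration: (1)
calibrate the graded response model on the pooled two-group data, giving
items flagged in the previous round separate parameters per group
(purification) while unflagged items anchor the metric; (2) EAP-score every
respondent; (3) for each item fit the three nested cumulative-logit models
conditioning on the fresh trait, compute the two likelihood-ratio p-values,
the two McFadden delta-R^2 values and the CvBL delta-beta1, and classify
against the thresholds.  The loop stops when the flagged set repeats
(fixed point) or at ``max_iter``; an oscillating set is reported as the
union, marked unstable, never silently resolved.

User-facing surface follows the model/results idiom:
``HybridDIFModel(data, instrument, subscale, groups).fit()`` returns a
:class:`HybridDIFResults` carrying the flag set, the per-item statistics
table, the iteration trace and the final trait estimates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._exceptions import ConfigError
from .data import ResponseMatrix, impute_missing
from .grm import eap_score, fit_grm
from .montecarlo import ThresholdTable, empirical_thresholds
from .olr import dif_statistics

logger = logging.getLogger("difagree")

__all__ = ["IterationTrace", "HybridDIFModel", "HybridDIFResults",
           "run_hybrid_dif", "run_all_dyads"]


@dataclass
class IterationTrace:
    """State of one purification round."""

    iteration: int
    flagged: tuple                 # sorted item ids flagged THIS round
    rows: list                     # DIFResultRow per item
    theta: np.ndarray = field(repr=False, default=None)

    def to_record(self):
        return {
            "iteration": self.iteration,
            "flagged": list(self.flagged),
            "items": [
                {"item_id": r.item_id, "flag": r.flag,
                 "p_uniform": r.p_uniform, "p_nonuniform": r.p_nonuniform,
                 "delta_r2_uniform": r.delta_r2_uniform,
                 "delta_r2_nonuniform": r.delta_r2_nonuniform,
                 "delta_beta1": r.delta_beta1,
                 "practically_important": r.practically_important}
                for r in self.rows
            ],
        }


def _rows_to_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(
        [{
            "item_id": r.item_id,
            "p_nonuniform": r.p_nonuniform, "thr_p_nonuniform": r.thr_p_nonuniform,
            "delta_r2_nonuniform": r.delta_r2_nonuniform,
            "thr_dr2_nonuniform": r.thr_dr2_nonuniform,
            "p_uniform": r.p_uniform, "thr_p_uniform": r.thr_p_uniform,
            "delta_r2_uniform": r.delta_r2_uniform,
            "thr_dr2_uniform": r.thr_dr2_uniform,
            "delta_beta1": r.delta_beta1, "thr_dbeta1": r.thr_dbeta1,
            "flag": r.flag, "practically_important": r.practically_important,
            "beta2_sign": r.beta2_sign,
        } for r in rows]
    ).set_index("item_id")


@dataclass
class HybridDIFResults:
    """Outcome of one hybrid OLR/IRT run on a single subscale."""

    subscale: str
    groups: tuple
    flags: dict                    # item_id -> "uniform" | "nonuniform"
    rows: list                     # final-iteration DIFResultRow per item
    trace: list                    # IterationTrace per iteration
    converged: bool
    unstable: bool
    theta: np.ndarray = field(repr=False, default=None)
    respondent_ids: list = field(repr=False, default=None)
    thresholds: ThresholdTable = None
    category_maps: dict = field(default_factory=dict, repr=False)
    responses: np.ndarray = field(repr=False, default=None)   # collapsed coding
    group01: np.ndarray = field(repr=False, default=None)
    item_ids: list = field(repr=False, default=None)

    @property
    def n_iterations(self):
        return len(self.trace)

    @property
    def dif_table(self) -> pd.DataFrame:
        """Per-item statistics in the standard report layout."""
        return _rows_to_frame(self.rows)

    def flagged_items(self, kind=None):
        return sorted(i for i, f in self.flags.items()
                      if kind is None or f == kind)

    def trace_records(self):
        return [t.to_record() for t in self.trace]

    def summary(self) -> str:
        lines = [
            f"Hybrid OLR/IRT DIF analysis — subscale {self.subscale!r}, "
            f"groups {self.groups[0]!r} (ref) vs {self.groups[1]!r} (focal)",
            f"iterations: {self.n_iterations} "
            f"({'fixed point' if self.converged else 'NOT converged'}"
            f"{', unstable (union reported)' if self.unstable else ''})",
            f"flagged items: {self.flags or 'none'}",
            "",
            self.dif_table.round(4).to_string(),
        ]
        return "\n".join(lines)

    def plot_item(self, item_id, calibration=None, ax=None):
        from .plotting import plot_item_response
        return plot_item_response(self, item_id, ax=ax)


def _resolve_thresholds(thresholds, item_ids, alpha):
    if thresholds is None:
        return ThresholdTable.nominal(item_ids, alpha)
    if isinstance(thresholds, ThresholdTable):
        return thresholds
    if isinstance(thresholds, dict):
        tab = pd.DataFrame(thresholds).T
        tab.index.name = "item_id"
        return ThresholdTable(tab, nrep=0, alpha=alpha, seed=-1)
    raise ConfigError(f"unsupported threshold specification {type(thresholds)}")


def run_hybrid_dif(m: ResponseMatrix, subscale, groups, thresholds=None,
                   alpha: float = 0.01, max_iter: int = 10,
                   impute: str = "item_mean_within_group",
                   min_category_count: int = 5) -> HybridDIFResults:
    """Run the iterative purification loop for one subscale and group pair.

    ``thresholds`` — ``None`` for nominal-alpha classification, or a
    :class:`ThresholdTable` of Monte-Carlo empirical critical values.
    """
    item_ids = m.spec.subscale_items(subscale)
    if len(item_ids) < 2:
        raise ConfigError(f"subscale {subscale!r} needs >= 2 items")
    sub = m.select_groups(groups)
    sub = impute_missing(sub, impute)
    group01 = sub.group_indicator(groups)
    y = sub.responses(item_ids)
    thr = _resolve_thresholds(thresholds, item_ids, alpha)

    trace = []
    flag_history = [frozenset()]
    grm_cache = {}
    category_maps = {}
    converged = False
    unstable = False
    final_rows = None
    theta = None
    for it in range(1, max_iter + 1):
        dif_items = flag_history[-1]
        key = frozenset(dif_items)
        if key not in grm_cache:
            grm_cache[key] = fit_grm(y, item_ids, groups=group01,
                                     dif_items=dif_items,
                                     min_category_count=min_category_count)
        cal, y_c = grm_cache[key]
        category_maps = cal.category_maps
        y_last = y_c
        theta, _ = eap_score(y_c, cal, group01)
        rows = [dif_statistics(iid, y_c[:, j], theta, group01,
                               thresholds=thr.row(iid))
                for j, iid in enumerate(item_ids)]
        new_flags = frozenset(r.item_id for r in rows if r.flag != "none")
        trace.append(IterationTrace(it, tuple(sorted(new_flags)), rows, theta))
        logger.info("subscale %s iteration %d flagged=%s", subscale, it,
                    sorted(new_flags))
        final_rows = rows
        if it > 1 and new_flags == flag_history[-1]:
            converged = True
            break
        flag_history.append(new_flags)

    flags_final = set(trace[-1].flagged)
    if not converged:
        # oscillation: report the union of the last two states, marked unstable
        unstable = True
        flags_final |= set(trace[-2].flagged) if len(trace) > 1 else set()
        logger.warning("subscale %s: flag set did not stabilize in %d "
                       "iterations; reporting the union", subscale, max_iter)
    flags = {}
    for iid in sorted(flags_final):
        # flag type from the most recent iteration that flagged the item
        # (an unstable item may be unflagged in the final round)
        for t in reversed(trace):
            row = next(r for r in t.rows if r.item_id == iid)
            if row.flag != "none":
                flags[iid] = row.flag
                break
    return HybridDIFResults(
        subscale=subscale, groups=tuple(groups), flags=flags, rows=final_rows,
        trace=trace, converged=converged, unstable=unstable, theta=theta,
        respondent_ids=sub.table["respondent_id"].tolist(), thresholds=thr,
        category_maps=category_maps, responses=y_last, group01=group01,
        item_ids=item_ids,
    )


class HybridDIFModel:
    """Iterative hybrid OLR/IRT DIF model for one subscale and group pair.

    Parameters
    ----------
    data : ResponseMatrix
    subscale : str
        Subscale analyzed on its own latent trait.
    groups : (reference_label, focal_label)
        The two informant groups compared; the focal group is coded 1.

    Examples
    --------
    >>> model = HybridDIFModel(matrix, "emotional", ("child", "parent"))
    >>> res = model.fit(thresholds="montecarlo", nrep=1000, alpha=0.01, seed=7)
    >>> res.flagged_items()
    """

    def __init__(self, data: ResponseMatrix, subscale, groups,
                 impute: str = "item_mean_within_group",
                 min_category_count: int = 5):
        if subscale not in data.spec.subscales:
            raise ConfigError(f"unknown subscale {subscale!r}")
        self.data = data
        self.subscale = subscale
        self.groups = tuple(groups)
        self.impute = impute
        self.min_category_count = min_category_count

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, instrument, subscale, groups,
                       **kw):
        return cls(ResponseMatrix(df, instrument), subscale, groups, **kw)

    def empirical_thresholds(self, nrep: int = 1000, alpha: float = 0.01,
                             seed: int = 0, **kw) -> ThresholdTable:
        """Monte-Carlo thresholds matched to this model's calibration."""
        sub = impute_missing(self.data.select_groups(self.groups), self.impute)
        item_ids = self.data.spec.subscale_items(self.subscale)
        g = sub.group_indicator(self.groups)
        return empirical_thresholds(sub.responses(item_ids), item_ids, g,
                                    nrep=nrep, alpha=alpha, seed=seed,
                                    min_category_count=self.min_category_count,
                                    **kw)

    def fit(self, thresholds=None, alpha: float = 0.01, max_iter: int = 10,
            nrep: int = 1000, seed: int = 0) -> HybridDIFResults:
        """Run the purification loop.

        ``thresholds`` — ``None`` / ``"analytic"`` for nominal-alpha
        classification, ``"montecarlo"`` to derive empirical thresholds
        first (``nrep`` replicates at level ``alpha``), or a ready
        :class:`ThresholdTable`.
        """
        if thresholds == "analytic":
            thresholds = None
        if thresholds == "montecarlo":
            thresholds = self.empirical_thresholds(nrep=nrep, alpha=alpha,
                                                   seed=seed)
        return run_hybrid_dif(self.data, self.subscale, self.groups,
                              thresholds=thresholds, alpha=alpha,
                              max_iter=max_iter, impute=self.impute,
                              min_category_count=self.min_category_count)


def run_all_dyads(m: ResponseMatrix, pairs, subscales=None, thresholds=None,
                  alpha: float = 0.01, max_iter: int = 10, nrep: int = 1000,
                  seed: int = 0):
    """Independent hybrid runs for several informant pairs.

    Parameters
    ----------
    pairs : list of (reference_label, focal_label)
    subscales : subset of the instrument's subscales (default: all)
    thresholds : None (analytic alpha) or "montecarlo"

    Returns
    -------
    (results, summary) — ``results[pair][subscale]`` is a
    :class:`HybridDIFResults`; ``summary`` is a DataFrame of flag counts by
    pair and subscale (uniform / non-uniform split), mirroring a cross-dyad
    comparison table.
    """
    subscales = list(subscales or m.spec.subscales)
    results = {}
    records = []
    present = set(m.table["group"])
    for pair in pairs:
        pair = tuple(pair)
        counts = m.table["group"].value_counts()
        if any(g not in present or counts.get(g, 0) < 2 for g in pair):
            logger.warning("pair %s skipped: fewer than 2 respondents in a "
                           "group", pair)
            continue
        results[pair] = {}
        for sub in subscales:
            model = HybridDIFModel(m, sub, pair)
            res = model.fit(thresholds=thresholds, alpha=alpha,
                            max_iter=max_iter, nrep=nrep, seed=seed)
            results[pair][sub] = res
            records.append({
                "pair": f"{pair[0]}|{pair[1]}", "subscale": sub,
                "n_flagged": len(res.flags),
                "n_uniform": sum(v == "uniform" for v in res.flags.values()),
                "n_nonuniform": sum(v == "nonuniform" for v in res.flags.values()),
                "converged": res.converged,
            })
    summary = pd.DataFrame(records)
    return results, summary


def write_trace_jsonl(results: HybridDIFResults, path):
    """Serialize the iteration trace as JSON lines, one record per round."""
    with open(path, "w") as fh:
        for rec in results.trace_records():
            fh.write(json.dumps(rec) + "\n")
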