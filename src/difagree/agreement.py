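"""Scale-level cross-informant agreement statistics.

For each subscale (and the total score) of a paired design the module
reports each informant's mean and SD, the paired t-test of the score
difference, the pooled-SD standardized effect size with Cohen's labels, and
the absolute-agreement intraclass correlation with conventional cut-point
labels.  A second, DIF-corrected block recomputes everything on subscale
scores restricted to items that survive the uniform-DIF cancellation rule:
uniform-DIF items whose group effects point in opposite directions offset
each other at the domain level and are kept; an uncancelled uniform-DIF
item biases the scale score and is removed.  Non-uniform items are never
removed by this rule (their bias changes direction along the trait, so no
domain-level cancellation argument applies).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import ConfigError, DataError
from .data import ResponseMatrix
from .scoring import score_table

__all__ = [
    "cohen_effect_size", "effect_size_label", "paired_t", "icc_agreement",
    "icc_label", "cancellation_partition", "corrected_item_subsets",
    "corrected_agreement_table", "CrossInformantAgreement", "AgreementRow",
]


# --------------------------------------------------------------------------
# elementary statistics


def cohen_effect_size(mean1, sd1, mean2, sd2):
    """|mean difference| standardized by the pooled SD of the two scores.

    Pooled SD = sqrt((sd1^2 + sd2^2) / 2) — group sizes are equal by
    pairing.  Undefined (NaN) when both SDs are zero.
    """
    pooled = np.sqrt((sd1**2 + sd2**2) / 2.0)
    if pooled == 0:
        return float("nan")
    return abs(mean1 - mean2) / pooled


def effect_size_label(es) -> str:
    """Cohen's magnitude labels at |0.2| / |0.5| / |0.8|.

    Half-open intervals: [0, 0.2) negligible, [0.2, 0.5) small,
    [0.5, 0.8) medium, >= 0.8 large.
    """
    es = abs(es)
    if np.isnan(es):
        return "undefined"
    if es < 0.2:
        return "negligible"
    if es < 0.5:
        return "small"
    if es < 0.8:
        return "medium"
    return "large"


def paired_t(x, y):
    """Classical paired t-test on complete pairs.

    Returns ``(t, p, mean_diff)``; two-sided p.  When every difference is
    zero the statistic is undefined and p = 1 by convention; a constant
    non-zero difference gives p = 0 (the difference is certain).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 2:
        raise DataError("paired t-test needs at least 2 complete pairs")
    d = x - y
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0:
        if md == 0:
            return float("nan"), 1.0, 0.0
        return float(np.sign(md) * np.inf), 0.0, md
    t, p = stats.ttest_rel(x, y)
    return float(t), float(p), md


def icc_agreement(x, y, variant: str = "agreement"):
    """Intraclass correlation of two paired raters from the two-way ANOVA.

    Two-way model, single measurement.  ``variant="agreement"`` (default)
    is the absolute-agreement form ICC(A,1),

        (MS_R - MS_E) / (MS_R + (k-1) MS_E + k/n (MS_C - MS_E)),

    which penalizes a systematic rater offset; ``variant="consistency"``
    is ICC(C,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise DataError("ICC needs at least 3 complete pairs")
    data = np.column_stack([x, y])
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_total = np.sum((data - grand) ** 2)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    if ss_total == 0:
        return float("nan")
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if variant == "agreement":
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    elif variant == "consistency":
        denom = msr + (k - 1) * mse
    else:
        raise ConfigError(f"unknown ICC variant {variant!r}")
    if denom == 0:
        return float("nan")
    return float((msr - mse) / denom)


def icc_label(icc) -> str:
    """Conventional agreement labels: poor < 0.40, moderate 0.41-0.60,
    good 0.61-0.80, excellent > 0.81 (gaps closed at the lower edge)."""
    if np.isnan(icc):
        return "undefined"
    if icc <= 0.40:
        return "poor"
    if icc <= 0.60:
        return "moderate"
    if icc <= 0.80:
        return "good"
    return "excellent"


# --------------------------------------------------------------------------
# uniform-DIF cancellation


def cancellation_partition(flags_signs):
    """Pair opposite-direction uniform-DIF items; the rest are uncancelled.

    Greedy pairing, largest |beta2| first: the strongest positive-direction
    uniform item is paired with the strongest negative-direction one, and so
    on; the leftover (excess-sign, weakest-effect) items are uncancelled.

    Parameters
    ----------
    flags_signs : dict item_id -> (flag, beta2)
        Final flag and the signed Model-2 group effect per item.

    Returns
    -------
    (cancelled_pairs, uncancelled)
        ``cancelled_pairs`` — list of (positive_item, negative_item);
        ``uncancelled`` — uniform-DIF items left unpaired, to be removed
        from the corrected score.  Non-uniform items never appear in either.
    """
    uni = {i: b for i, (f, b) in flags_signs.items() if f == "uniform"}
    pos = sorted((i for i, b in uni.items() if b > 0),
                 key=lambda i: -abs(uni[i]))
    neg = sorted((i for i, b in uni.items() if b < 0),
                 key=lambda i: -abs(uni[i]))
    pairs = list(zip(pos, neg))
    m = len(pairs)
    uncancelled = sorted(pos[m:] + neg[m:])
    return pairs, uncancelled


def corrected_item_subsets(m: ResponseMatrix, flags_by_subscale,
                           remove: str = "uncancelled") -> dict:
    """Retained item lists per subscale after the DIF correction.

    ``remove="uncancelled"`` (default) drops only uniform-DIF items whose
    effect is not offset by an opposite-direction partner;
    ``remove="all_uniform"`` drops every uniform-DIF item.
    """
    if remove not in ("uncancelled", "all_uniform"):
        raise ConfigError(f"unknown removal policy {remove!r}")
    subsets = {}
    for sub in m.spec.subscales:
        items = m.spec.subscale_items(sub)
        fs = flags_by_subscale.get(sub, {})
        if remove == "all_uniform":
            removed = {i for i, (f, _) in fs.items() if f == "uniform"}
        else:
            _, uncancelled = cancellation_partition(fs)
            removed = set(uncancelled)
        subsets[sub] = [i for i in items if i not in removed]
    return subsets


# --------------------------------------------------------------------------
# table assembly


@dataclass
class AgreementRow:
    """One subscale-by-pair block of the agreement table."""

    scale: str
    group_pair: tuple
    mean1: float
    sd1: float
    mean2: float
    sd2: float
    effect_size: float
    es_label: str
    icc: float
    icc_label: str
    t: float
    t_p: float
    mean_diff: float
    n_pairs: int
    corrected: bool
    defined: bool = True

    def to_dict(self):
        return {
            "scale": self.scale,
            "pair": f"{self.group_pair[0]}|{self.group_pair[1]}",
            "corrected": self.corrected, "defined": self.defined,
            "mean_1": self.mean1, "sd_1": self.sd1,
            "mean_2": self.mean2, "sd_2": self.sd2,
            "effect_size": self.effect_size, "es_label": self.es_label,
            "icc": self.icc, "icc_label": self.icc_label,
            "t": self.t, "p": self.t_p, "mean_diff": self.mean_diff,
            "n_pairs": self.n_pairs,
        }


def _pair_scores(m: ResponseMatrix, pair, item_subsets=None):
    """Aligned per-dyad score frames for the two informants."""
    scores = score_table(m.select_groups(pair), item_subsets=item_subsets)
    s1 = scores[scores["group"] == pair[0]].set_index("dyad_id")
    s2 = scores[scores["group"] == pair[1]].set_index("dyad_id")
    common = s1.index.intersection(s2.index)
    return s1.loc[common], s2.loc[common]


def _build_row(scale, pair, x, y, corrected):
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        return AgreementRow(scale, pair, *(float("nan"),) * 4,
                            float("nan"), "undefined", float("nan"),
                            "undefined", float("nan"), float("nan"),
                            float("nan"), int(x.size), corrected, defined=False)
    m1, s1 = float(x.mean()), float(x.std(ddof=1))
    m2, s2 = float(y.mean()), float(y.std(ddof=1))
    es = cohen_effect_size(m1, s1, m2, s2)
    t, p, md = paired_t(x, y)
    icc = icc_agreement(x, y)
    return AgreementRow(scale, pair, m1, s1, m2, s2, es,
                        effect_size_label(es), icc, icc_label(icc), t, p, md,
                        int(x.size), corrected)


def corrected_agreement_table(m: ResponseMatrix, pair, flags_by_subscale=None,
                              remove: str = "uncancelled") -> pd.DataFrame:
    """Raw and DIF-corrected agreement blocks for one informant pair.

    ``flags_by_subscale`` maps subscale -> {item_id: (flag, beta2_sign)};
    when ``None`` only the raw block is produced.  A subscale whose items
    are all removed yields a row with ``defined=False`` — no corrected
    score exists.
    """
    rows = []
    scales = list(m.spec.subscales) + ["total"]
    s1, s2 = _pair_scores(m, pair)
    for sc in scales:
        rows.append(_build_row(sc, pair, s1[sc].to_numpy(),
                               s2[sc].to_numpy(), corrected=False))
    if flags_by_subscale is not None:
        subsets = corrected_item_subsets(m, flags_by_subscale, remove)
        c1, c2 = _pair_scores(m, pair, item_subsets=subsets)
        for sc in scales:
            rows.append(_build_row(sc, pair, c1[sc].to_numpy(),
                                   c2[sc].to_numpy(), corrected=True))
    return pd.DataFrame([r.to_dict() for r in rows])


class CrossInformantAgreement:
    """Scale-level agreement analysis for one informant pair.

    Parameters
    ----------
    data : ResponseMatrix
    pair : (reference_label, focal_label)
    dif_results : optional dict subscale -> HybridDIFResults
        When given, ``fit()`` also produces the DIF-corrected block using
        the uniform-DIF cancellation rule.
    """

    def __init__(self, data: ResponseMatrix, pair, dif_results=None,
                 remove: str = "uncancelled"):
        self.data = data
        self.pair = tuple(pair)
        self.dif_results = dif_results
        self.remove = remove

    @classmethod
    def from_dataframe(cls, df, instrument, pair, **kw):
        return cls(ResponseMatrix(df, instrument), pair, **kw)

    def fit(self) -> "AgreementResults":
        flags = None
        if self.dif_results is not None:
            flags = {
                sub: {r.item_id: (r.flag, r.beta2) for r in res.rows}
                for sub, res in self.dif_results.items()
            }
        table = corrected_agreement_table(self.data, self.pair, flags,
                                          remove=self.remove)
        return AgreementResults(self.pair, table, flags)


@dataclass
class AgreementResults:
    pair: tuple
    table: pd.DataFrame
    flags: dict | None = None

    def summary(self) -> str:
        show = self.table.copy()
        for c in ("mean_1", "sd_1", "mean_2", "sd_2"):
            show[c] = show[c].round(2)
        show["effect_size"] = show["effect_size"].round(2)
        show["icc"] = show["icc"].round(2)
        show["p"] = show["p"].round(4)
        head = (f"Cross-informant agreement — {self.pair[0]!r} vs "
                f"{self.pair[1]!r} (0-100 metric; higher = better HRQoL)")
        return head + "\n" + show.to_string(index=False)
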