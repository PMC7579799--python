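"""Diagnostic plots for DIF results."""

from __future__ import annotations

import numpy as np


def plot_item_response(results, item_id, ax=None, n_bins: int = 8):
    """Empirical item response by trait bin, one curve per group.

    A visual check of a flagged item: a vertical offset between the group
    curves indicates uniform DIF; curves that cross or diverge along the
    trait indicate non-uniform DIF.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    theta = results.theta
    j = results.item_ids.index(item_id)
    y = results.responses[:, j]
    edges = np.quantile(theta, np.linspace(0, 1, n_bins + 1))
    edges[-1] += 1e-9
    which = np.digitize(theta, edges[1:-1])
    mids = 0.5 * (edges[:-1] + edges[1:])
    for g, label in zip((0, 1), results.groups):
        mask = results.group01 == g
        means = [np.nanmean(y[mask & (which == b)]) if np.any(mask & (which == b))
                 else np.nan for b in range(n_bins)]
        ax.plot(mids, means, marker="o", label=label)
    ax.set_xlabel("trait (EAP)")
    ax.set_ylabel("mean response (collapsed coding)")
    ax.set_title(f"{results.subscale}: {item_id} "
                 f"[{results.flags.get(item_id, 'no flag')}]")
    ax.legend()
    return ax


def plot_flag_counts(summary, ax=None):
    """Bar chart of flag counts by pair and subscale from a run summary."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    pivot = summary.pivot_table(index="subscale", columns="pair",
                                values="n_flagged", aggfunc="sum")
    pivot.plot.bar(ax=ax)
    ax.set_ylabel("flagged items")
    return ax
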