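"""Synthetic dyadic Likert data with configurable DIF.

Generates paired informants (e.g. a child's self-report and a parent's
proxy report) whose latent traits are bivariate normal with correlation
``rho`` and a mean shift between members, and whose item responses follow
the graded response model.  DIF is injected per item against the second
(focal) group: uniform DIF as a common shift ``delta`` added to all of the
item's thresholds (location DIF, the analogue of a group main effect) and
non-uniform DIF as a multiplicative discrimination ratio ``gamma`` (the
analogue of a trait-by-group interaction).  ``delta = 0`` and ``gamma = 1``
leave an item DIF-free.

Defaults emulate a parent-adolescent PedsQL study: 23 five-category items
in four subscales, a few hundred complete dyads, trait correlation around
0.5 (the small-to-moderate agreement typical of self- vs proxy reports).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._exceptions import ConfigError
from .data import ResponseMatrix
from .grm import GRMItemParams, grm_category_probs
from .instrument import InstrumentSpec, pedsql_generic_core

__all__ = ["DyadSimSpec", "default_item_params", "generate_dyads",
           "preset_scenarios", "make_subscale_instrument"]


@dataclass(frozen=True)
class DifSpec:
    """Per-item DIF injection: threshold shift and discrimination ratio."""

    delta: float = 0.0   # added to all thresholds for the focal group
    gamma: float = 1.0   # multiplies discrimination for the focal group

    @property
    def is_null(self):
        return self.delta == 0.0 and self.gamma == 1.0


@dataclass
class DyadSimSpec:
    """Full description of one synthetic dyadic dataset.

    Parameters
    ----------
    n_dyads : int
        Number of complete pairs; the dataset has ``2 * n_dyads`` rows.
    instrument : InstrumentSpec
    item_params : dict item_id -> GRMItemParams
        Generating parameters of the reference group.
    trait_correlation : float
        Correlation of the two members' latent traits (|rho| <= 1).
    group_trait_shift : float
        Mean trait of the focal group minus the reference group.
    dif : dict item_id -> DifSpec
        Items omitted are DIF-free.
    group_labels : (str, str)
        Reference and focal labels (e.g. ``("child", "parent")``).
    missing_rate : float
        MCAR missingness rate applied to generated cells.
    """

    n_dyads: int
    instrument: InstrumentSpec
    item_params: dict
    trait_correlation: float = 0.5
    group_trait_shift: float = 0.0
    dif: dict = field(default_factory=dict)
    group_labels: tuple = ("child", "parent")
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if abs(self.trait_correlation) > 1:
            raise ConfigError("trait correlation must lie in [-1, 1]")
        missing = set(self.instrument.item_ids) - set(self.item_params)
        if missing:
            raise ConfigError(f"item parameters missing for {sorted(missing)}")


def default_item_params(instrument: InstrumentSpec, a_range=(1.2, 2.0),
                        b_span=2.5, location_spread=0.7):
    """Informative PRO-scale-like generating parameters.

    Discriminations evenly spaced over ``a_range``; each item's K-1
    thresholds evenly spread within [-b_span, b_span], item locations
    staggered over ``[-location_spread, location_spread]``.
    """
    J = instrument.n_items
    K = instrument.n_categories
    a_vals = np.linspace(a_range[0], a_range[1], J)
    offsets = (np.linspace(-location_spread, location_spread, J)
               if J > 1 else np.array([0.0]))
    base = np.linspace(-(b_span - location_spread), b_span - location_spread, K - 1)
    return {
        iid: GRMItemParams(iid, float(a_vals[j]), tuple(base + offsets[j]))
        for j, iid in enumerate(instrument.item_ids)
    }


def _draw_item(theta, a, b, rng):
    p = grm_category_probs(theta, a, b)
    u = rng.random(theta.size)
    return (u[:, None] > np.cumsum(p, axis=1)[:, :-1]).sum(axis=1).astype(float)


def generate_dyads(spec: DyadSimSpec) -> ResponseMatrix:
    """Draw a complete dyadic dataset from the generating model."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_dyads
    rho = spec.trait_correlation
    if abs(rho) > 1:
        raise ConfigError("trait covariance is not positive definite")
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    theta_ref = z1
    theta_focal = rho * z1 + np.sqrt(1 - rho**2) * z2 + spec.group_trait_shift

    ref_label, focal_label = spec.group_labels
    rows = []
    for label, theta, focal in ((ref_label, theta_ref, False),
                                (focal_label, theta_focal, True)):
        block = {}
        for iid in spec.instrument.item_ids:
            p = spec.item_params[iid]
            d = spec.dif.get(iid, DifSpec())
            a, b = p.a, np.asarray(p.b, dtype=float)
            if focal:
                a = a * d.gamma
                b = b + d.delta
            block[iid] = _draw_item(theta, a, b, rng)
        df = pd.DataFrame(block)
        df.insert(0, "group", label)
        df.insert(0, "dyad_id", [f"d{i:04d}" for i in range(n)])
        df.insert(0, "respondent_id", [f"{label}_{i:04d}" for i in range(n)])
        rows.append(df)
    table = pd.concat(rows, ignore_index=True)
    if spec.missing_rate > 0:
        vals = table[spec.instrument.item_ids].to_numpy(dtype=float)
        mask = rng.random(vals.shape) < spec.missing_rate
        vals[mask] = np.nan
        table[spec.instrument.item_ids] = vals
    return ResponseMatrix(table, spec.instrument)


def make_subscale_instrument(n_items: int = 5, name: str = "scale",
                             n_categories: int = 5) -> InstrumentSpec:
    """A single-subscale instrument for focused simulations."""
    items = tuple((f"item_{j + 1}", name, f"item {j + 1}") for j in range(n_items))
    return InstrumentSpec(name=name, items=items, subscales=(name,),
                          n_categories=n_categories)


def preset_scenarios(seed: int = 0) -> dict:
    """Named study conditions used throughout the test batteries.

    ``null``            5-item subscale, 500 dyads, no DIF.
    ``one_uniform``     as null, item_3 thresholds shifted by delta = 0.6.
    ``opposite_pair``   two uniform items in opposite directions (+/-0.6) —
                        the domain-level cancellation case.
    ``one_nonuniform``  item_3 discrimination ratio gamma = 1.8.
    ``saturated_uniform``  every item shifted the same way (delta = 0.8) —
                        no corrected score can exist.
    ``pedsql_like``     full 23-item four-subscale instrument, 573 dyads,
                        mild parent-proxy trait shift and a handful of
                        injected DIF items mirroring a real invariance study.
    """
    small = make_subscale_instrument(5)
    small_params = default_item_params(small)

    def base(**kw):
        d = dict(n_dyads=500, instrument=small, item_params=small_params,
                 trait_correlation=0.5, group_trait_shift=0.0, seed=seed)
        d.update(kw)
        return DyadSimSpec(**d)

    pedsql = pedsql_generic_core()
    scenarios = {
        "null": base(),
        "one_uniform": base(dif={"item_3": DifSpec(delta=0.6)}),
        "opposite_pair": base(dif={"item_2": DifSpec(delta=0.6),
                                   "item_4": DifSpec(delta=-0.6)}),
        "one_nonuniform": base(dif={"item_3": DifSpec(gamma=1.8)}),
        "saturated_uniform": base(dif={f"item_{j}": DifSpec(delta=0.8)
                                       for j in range(1, 6)}),
        "pedsql_like": DyadSimSpec(
            n_dyads=573,
            instrument=pedsql,
            item_params=default_item_params(pedsql),
            trait_correlation=0.5,
            group_trait_shift=0.15,
            dif={
                "physical_5": DifSpec(delta=0.6),
                "emotional_3": DifSpec(delta=0.5),
                "emotional_5": DifSpec(delta=-0.5),
                "social_1": DifSpec(delta=0.5),
                "social_3": DifSpec(delta=-0.5),
                "school_1": DifSpec(gamma=1.8),
            },
            group_labels=("child", "parent"),
            seed=seed,
        ),
    }
    return scenarios
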