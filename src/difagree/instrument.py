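"""Instrument layout: items, subscales and response categories.

An :class:`InstrumentSpec` describes a Likert questionnaire — which items
exist, which subscale each belongs to, and how many ordered response
categories the items share.  The shipped default is the 23-item PedsQL 4.0
Generic Core Scales layout (8 physical + 5 emotional + 5 social + 5 school
items, five response categories 0..4 where higher raw values mean more
frequent problems).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._exceptions import ConfigError

__all__ = ["InstrumentSpec", "pedsql_generic_core"]


@dataclass(frozen=True)
class InstrumentSpec:
    """Item/subscale layout of a polytomous Likert instrument.

    Parameters
    ----------
    name : str
        Human-readable instrument name.
    items : tuple of (item_id, subscale_id, prompt)
        Ordered item definitions. Every item belongs to exactly one subscale.
    subscales : tuple of str
        Ordered subscale identifiers.
    n_categories : int
        Number of ordered response categories (>= 2); raw responses take
        integer values ``0 .. n_categories - 1``.
    """

    name: str
    items: tuple = field(default_factory=tuple)
    subscales: tuple = field(default_factory=tuple)
    n_categories: int = 5

    def __post_init__(self):
        if self.n_categories < 2:
            raise ConfigError("an instrument needs at least 2 response categories")
        ids = [it[0] for it in self.items]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate item ids in instrument spec")
        known = set(self.subscales)
        for item_id, subscale_id, _prompt in self.items:
            if subscale_id not in known:
                raise ConfigError(
                    f"item {item_id!r} references unknown subscale {subscale_id!r}"
                )

    @property
    def item_ids(self):
        return [it[0] for it in self.items]

    @property
    def n_items(self):
        return len(self.items)

    def subscale_items(self, subscale_id):
        """Ordered item ids belonging to ``subscale_id``."""
        if subscale_id not in self.subscales:
            raise ConfigError(f"unknown subscale {subscale_id!r}")
        return [it[0] for it in self.items if it[1] == subscale_id]

    def subscale_of(self, item_id):
        for iid, sid, _ in self.items:
            if iid == item_id:
                return sid
        raise ConfigError(f"unknown item {item_id!r}")

    def to_dict(self):
        return {
            "name": self.name,
            "items": [list(it) for it in self.items],
            "subscales": list(self.subscales),
            "n_categories": self.n_categories,
        }

    @classmethod
    def from_dict(cls, d):
        return cls(
            name=d["name"],
            items=tuple(tuple(it) for it in d["items"]),
            subscales=tuple(d["subscales"]),
            n_categories=int(d.get("n_categories", 5)),
        )


_PEDSQL_PROMPTS = {
    "physical": [
        "Hard to walk more than one block",
        "Hard to run",
        "Hard to do sports or exercise",
        "Hard to lift something heavy",
        "Hard to take a bath or shower",
        "Hard to do chores around the house",
        "Having hurts or aches",
        "Low energy level",
    ],
    "emotional": [
        "Feel afraid or scared",
        "Feel sad or blue",
        "Feel angry",
        "Trouble sleeping",
        "Worry about what will happen",
    ],
    "social": [
        "Trouble getting along with peers",
        "Other kids do not want to be friends",
        "Teased by other children",
        "Cannot do things other peers do",
        "Hard to keep up when playing with others",
    ],
    "school": [
        "Hard to concentrate in class",
        "Forget things",
        "Trouble keeping up with schoolwork",
        "Miss school because of not feeling well",
        "Miss school for doctor appointment",
    ],
}


def pedsql_generic_core():
    """The 23-item PedsQL 4.0 Generic Core Scales layout (adolescent form).

    Four subscales — physical (8 items), emotional, social and school
    functioning (5 items each) — each item on a five-point 0..4 scale
    (0 = never a problem ... 4 = almost always a problem).
    """
    items = []
    for sub, prompts in _PEDSQL_PROMPTS.items():
        for j, prompt in enumerate(prompts, start=1):
            items.append((f"{sub}_{j}", sub, prompt))
    return InstrumentSpec(
        name="PedsQL 4.0 Generic Core Scales",
        items=tuple(items),
        subscales=("physical", "emotional", "social", "school"),
        n_categories=5,
    )
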