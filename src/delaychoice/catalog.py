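"""Item catalogs for the episodic intertemporal-choice task.

Options in the episodic task are concrete consumable items from three
domains (food, culture, sport), each with a nominal price tier. The default
catalog ships ten example items per domain, ordered by increasing price;
price tiers 1..10 follow that ordering (stated prices range 1-100 EUR, so a
tier is an ordinal stand-in, not an amount).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

DOMAINS = ("food", "culture", "sport")

_DEFAULT_ITEMS = {
    "sport": [
        "A free bowling session in a bar",
        "A hiking session in Fontainebleau",
        "One hour of body massage",
        "An initiation to Aikido practice",
        "An indoor climbing session in Bercy",
        "A rowing session on Cergy lake",
        "A seat for a premier league rugby game",
        "A seat for a first league football game",
        "A horse riding tour in the Bois de Vincennes",
        "A seat for the Roland Garros tennis tournament final",
    ],
    "culture": [
        "A visit of the Menagerie du Jardin des Plantes",
        "A visit of the Palais de la Decouverte",
        "A 1-hour chess lesson",
        "A guided tour of Centre Pompidou",
        "A guided tour of the Musee du Louvre",
        "A day at the Chateau de Versailles",
        "A salsa dancing lesson",
        "A 2-h oenology lesson",
        "A theater play at the Comedie Francaise",
        "A concert in a Paris Jazz Club",
    ],
    "food": [
        "A packet of crisps",
        "A piece of cheesecake",
        "A glass of red wine",
        "A cup of Champagne",
        "A lunch in an Italian pizzeria",
        "A Japanese meal in front of Notre-Dame cathedral",
        "A dinner on a Paris river boat",
        "A plate of seafood on the Champs-Elysees",
        "A breakfast at the Tour Eiffel restaurant",
        "A lobster in the Tour Montparnasse restaurant",
    ],
}


@dataclass(frozen=True)
class ItemCatalog:
    """Items available per domain, with ordinal price tiers.

    ``items`` maps a domain label to an ordered list of unique item labels;
    the price tier of an item is its 1-based position in that list.
    """

    items: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for domain, labels in self.items.items():
            if len(set(labels)) != len(labels):
                raise ValueError(f"duplicate item labels in domain {domain!r}")

    @property
    def domains(self) -> tuple:
        return tuple(self.items)

    def n_items(self, domain: str) -> int:
        return len(self.items.get(domain, ()))

    def restrict(self, domains) -> "ItemCatalog":
        """Sub-catalog containing only the given domains."""
        return ItemCatalog({d: list(self.items[d]) for d in domains if d in self.items})

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"domain": d, "item": label, "price_tier": i + 1}
            for d, labels in self.items.items()
            for i, label in enumerate(labels)
        ]
        return pd.DataFrame(rows, columns=["domain", "item", "price_tier"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ItemCatalog":
        items = {
            str(d): list(sub.sort_values("price_tier")["item"])
            for d, sub in frame.groupby("domain", sort=False)
        }
        return cls(items)


def default_catalog() -> ItemCatalog:
    """The 30-item default catalog (10 items per domain, tiers by price order)."""
    return ItemCatalog({d: list(_DEFAULT_ITEMS[d]) for d in DOMAINS})
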