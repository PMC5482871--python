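"""Two-level label taxonomy and pairwise label relations.

The taxonomy is the prior knowledge consumed by the distance-constraint
loss: every subclass belongs to exactly one superclass, and any pair of
labels falls into one of three relations (same subclass, same superclass,
different superclass).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence


class PairRelation(enum.Enum):
    """Relation between two subclass labels under a two-level taxonomy."""

    SAME_SUBCLASS = "same_subclass"
    SAME_SUPERCLASS = "same_superclass"
    DIFFERENT_SUPERCLASS = "different_superclass"


#: Long-name aliases for the default tumor-type short codes (dataset folder
#: conventions use full names).
LONG_NAME_ALIASES: dict[str, str] = {
    "adenosis": "A",
    "fibroadenoma": "F",
    "phyllodes_tumor": "PT",
    "tubular_adenoma": "TA",
    "ductal_carcinoma": "DC",
    "lobular_carcinoma": "LC",
    "mucinous_carcinoma": "MC",
    "papillary_carcinoma": "PC",
}


@dataclass(frozen=True)
class Taxonomy:
    """A two-level class structure: ordered superclasses and a subclass map.

    Parameters
    ----------
    superclasses:
        Ordered superclass names.
    subclass_map:
        Mapping from subclass name to its (single) superclass name.
    """

    superclasses: tuple[str, ...]
    subclass_map: Mapping[str, str]
    aliases: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.superclasses) < 1:
            raise ValueError("taxonomy needs at least one superclass")
        object.__setattr__(self, "superclasses", tuple(self.superclasses))
        object.__setattr__(self, "subclass_map", dict(self.subclass_map))
        object.__setattr__(self, "aliases", dict(self.aliases))
        if len(set(self.superclasses)) != len(self.superclasses):
            raise ValueError("duplicate superclass names")
        seen = set()
        for sub, sup in self.subclass_map.items():
            if sup not in self.superclasses:
                raise ValueError(f"subclass {sub!r} maps to unknown superclass {sup!r}")
            seen.add(sup)
        missing = set(self.superclasses) - seen
        if missing:
            raise ValueError(f"superclasses with no subclass: {sorted(missing)}")
        if self.k < 2:
            raise ValueError("taxonomy needs at least two subclasses")

    @property
    def k(self) -> int:
        """Total number of subclasses."""
        return len(self.subclass_map)

    @property
    def subclasses(self) -> tuple[str, ...]:
        """Subclass names, ordered by superclass then insertion order."""
        return tuple(
            sub
            for sup in self.superclasses
            for sub, s in self.subclass_map.items()
            if s == sup
        )

    def canonical(self, label: str) -> str:
        """Resolve a label (short code or long-name alias) to its short code."""
        if label in self.subclass_map:
            return label
        alias = self.aliases.get(label)
        if alias is not None and alias in self.subclass_map:
            return alias
        raise KeyError(f"unknown subclass label: {label!r}")

    def superclass(self, subclass: str) -> str:
        """Superclass that owns *subclass*."""
        return self.subclass_map[self.canonical(subclass)]

    def index(self, subclass: str) -> int:
        """0-based integer index of a subclass in :attr:`subclasses` order."""
        return self.subclasses.index(self.canonical(subclass))

    def siblings(self, subclass: str) -> tuple[str, ...]:
        """Other subclasses sharing this subclass's superclass."""
        sub = self.canonical(subclass)
        sup = self.subclass_map[sub]
        return tuple(s for s, p in self.subclass_map.items() if p == sup and s != sub)

    def to_config(self) -> dict:
        """Serialize to a plain config block (YAML/JSON friendly)."""
        return {
            "superclasses": list(self.superclasses),
            "subclasses": dict(self.subclass_map),
        }

    @classmethod
    def from_config(cls, block: Mapping) -> "Taxonomy":
        """Build a taxonomy from a config block with ``superclasses`` and
        ``subclasses`` keys."""
        try:
            supers = block["superclasses"]
            subs = block["subclasses"]
        except KeyError as exc:  # pragma: no cover - defensive
            raise ValueError(f"taxonomy config missing key: {exc}") from exc
        return cls(tuple(supers), dict(subs), aliases=dict(block.get("aliases", {})))


def default_breakhis_taxonomy() -> Taxonomy:
    """The default 8-subclass benign/malignant tumor taxonomy.

    Benign: adenosis (A), fibroadenoma (F), phyllodes tumor (PT),
    tubular adenoma (TA).  Malignant: ductal (DC), lobular (LC),
    mucinous (MC), papillary (PC) carcinoma.
    """
    return Taxonomy(
        superclasses=("benign", "malignant"),
        subclass_map={
            "A": "benign",
            "F": "benign",
            "PT": "benign",
            "TA": "benign",
            "DC": "malignant",
            "LC": "malignant",
            "MC": "malignant",
            "PC": "malignant",
        },
        aliases=dict(LONG_NAME_ALIASES),
    )


def relation(t: Taxonomy, a: str, b: str) -> PairRelation:
    """Classify the relation between two subclass labels.

    Returns ``SAME_SUBCLASS`` iff the labels are equal, ``SAME_SUPERCLASS``
    iff they differ but share a superclass, else ``DIFFERENT_SUPERCLASS``.
    Unknown labels raise :class:`KeyError` naming the offending value.
    """
    ca, cb = t.canonical(a), t.canonical(b)
    if ca == cb:
        return PairRelation.SAME_SUBCLASS
    if t.subclass_map[ca] == t.subclass_map[cb]:
        return PairRelation.SAME_SUPERCLASS
    return PairRelation.DIFFERENT_SUPERCLASS
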