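"""Scoring key for the LEAM-Q screening questionnaire.

The scoring engine is fully key-driven: every scored item carries its
section, optional wellbeing sub-scale, the ordered set of allowed ordinal
codes, a reverse-coding flag and the instrument version(s) in which it
appears.  Higher adjusted codes always indicate a presentation more
consistent with low energy availability, which is why positively worded
wellbeing items ("I feel very energetic in general") are reverse-coded
before summation.

The default key ships the section structure of the instrument (dizziness,
gastrointestinal, thermoregulation, injury/illness 4A-4F, wellbeing with
fatigue / poor-fitness / sleep / poor-recovery / mood / low-energy
sub-scales, and the version-2 sex-drive items 6A-6D) with codes 0-3 per
item.  The exact item wording is a configuration concern; keys can be
loaded from YAML/JSON to rescore with a different instrument revision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from .errors import ConfigError

SECTIONS = (
    "dizziness",
    "gastrointestinal",
    "thermoregulation",
    "injury_illness",
    "wellbeing",
    "sex_drive",
)

VERSIONS = ("v1", "v2")


@dataclass(frozen=True)
class ItemKey:
    """Scoring metadata for one questionnaire item."""

    item_id: str
    section: str
    allowed_codes: tuple[int, ...] = (0, 1, 2, 3)
    reverse_coded: bool = False
    version: str = "both"  # "v1", "v2" or "both"
    subscale: Optional[str] = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.section not in SECTIONS:
            raise ConfigError(f"unknown section {self.section!r} for item {self.item_id}")
        if not self.allowed_codes:
            raise ConfigError(f"item {self.item_id}: allowed_codes must be non-empty")
        if any(c < 0 for c in self.allowed_codes):
            raise ConfigError(f"item {self.item_id}: codes must be >= 0")
        if self.version not in ("v1", "v2", "both"):
            raise ConfigError(f"item {self.item_id}: bad version {self.version!r}")

    @property
    def max_code(self) -> int:
        return max(self.allowed_codes)

    def adjust(self, code: int) -> int:
        """Reverse-adjust an answered code so that higher = more adverse."""
        return self.max_code - code if self.reverse_coded else code

    def available_in(self, version: str) -> bool:
        return self.version in ("both", version)


class ScoringKey:
    """An ordered collection of :class:`ItemKey` plus named composites."""

    def __init__(self, items: Iterable[ItemKey], ehmc_items: Sequence[str] = ()):
        self._items: dict[str, ItemKey] = {}
        for it in items:
            if it.item_id in self._items:
                raise ConfigError(f"duplicate item id {it.item_id!r} in key")
            self._items[it.item_id] = it
        self.ehmc_items = tuple(ehmc_items)
        missing = [i for i in self.ehmc_items if i not in self._items]
        if missing:
            raise ConfigError(f"EHMC composite references unknown items: {missing}")

    def __contains__(self, item_id: str) -> bool:
        return item_id in self._items

    def __getitem__(self, item_id: str) -> ItemKey:
        return self._items[item_id]

    def __iter__(self):
        return iter(self._items.values())

    def __len__(self) -> int:
        return len(self._items)

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(self._items)

    def items_for(self, version: str, section: Optional[str] = None) -> list[ItemKey]:
        out = [it for it in self._items.values() if it.available_in(version)]
        if section is not None:
            out = [it for it in out if it.section == section]
        return out

    def drop(self, item_ids: Iterable[str]) -> "ScoringKey":
        """Return a new key without the given items (test-retest removals)."""
        dropped = set(item_ids)
        keep = [it for it in self._items.values() if it.item_id not in dropped]
        ehmc = [i for i in self.ehmc_items if i not in dropped]
        return ScoringKey(keep, ehmc)

    # ---- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "items": [
                {
                    "item_id": it.item_id,
                    "section": it.section,
                    "allowed_codes": list(it.allowed_codes),
                    "reverse_coded": it.reverse_coded,
                    "version": it.version,
                    "subscale": it.subscale,
                    "label": it.label,
                }
                for it in self._items.values()
            ],
            "ehmc_items": list(self.ehmc_items),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScoringKey":
        try:
            items = [
                ItemKey(
                    item_id=str(e["item_id"]),
                    section=e["section"],
                    allowed_codes=tuple(int(c) for c in e.get("allowed_codes", (0, 1, 2, 3))),
                    reverse_coded=bool(e.get("reverse_coded", False)),
                    version=e.get("version", "both"),
                    subscale=e.get("subscale"),
                    label=e.get("label", ""),
                )
                for e in d["items"]
            ]
        except KeyError as exc:  # pragma: no cover - defensive
            raise ConfigError(f"scoring key entry missing field {exc}") from exc
        return cls(items, tuple(d.get("ehmc_items", ())))

    @classmethod
    def from_yaml(cls, path) -> "ScoringKey":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _default_items() -> list[ItemKey]:
    spec = [
        # id, section, subscale, reverse, version, label
        ("1A", "dizziness", None, False, "both", "Dizziness during or after training"),
        ("1B", "dizziness", None, False, "v2", "Dizziness outside of training"),
        ("2A", "gastrointestinal", None, False, "both", "Bloating or abdominal cramps"),
        ("2B", "gastrointestinal", None, False, "both", "Fullness or early satiety"),
        ("2C", "gastrointestinal", None, False, "both", "How would you describe your normal stool"),
        ("3A", "thermoregulation", None, False, "both", "Feeling cold compared to others"),
        ("3B", "thermoregulation", None, False, "both", "Cold hands and feet"),
        ("4A", "injury_illness", None, False, "both", "How many acute injuries?"),
        ("4B", "injury_illness", None, False, "both", "How many overload injuries?"),
        ("4C", "injury_illness", None, False, "both", "Currently injured"),
        ("4D", "injury_illness", None, False, "both", "Breaks in training for acute injury"),
        ("4E", "injury_illness", None, False, "both", "Breaks in training for overload injury"),
        ("4F", "injury_illness", None, False, "both", "Days unable to train due to illness"),
        ("5A1", "wellbeing", "fatigue", False, "both", "I feel tired from work or school"),
        ("5A2", "wellbeing", "fatigue", False, "both", "I feel lethargic"),
        ("5A3", "wellbeing", "fatigue", False, "both", "I feel tired during the day"),
        ("5B1", "wellbeing", "poor_fitness", True, "both",
         "I feel strong and making good progress with my strength training"),
        ("5B2", "wellbeing", "poor_fitness", True, "both",
         "I feel invigorated for training sessions and ready to perform well"),
        ("5C1", "wellbeing", "sleep", False, "v2", "I sleep poorly"),
        ("5C2", "wellbeing", "sleep", False, "v2", "I have trouble falling asleep"),
        ("5D1", "wellbeing", "poor_recovery", True, "both", "I recover well between training sessions"),
        ("5D2", "wellbeing", "mood", False, "both",
         "I feel down and less happy than I used to feel or would like to feel"),
        ("5D3", "wellbeing", "mood", True, "both", "I feel happy and on top of my life outside of sport"),
        ("5E1", "wellbeing", "low_energy", True, "both", "I feel very energetic in general"),
        ("5E2", "wellbeing", "low_energy", False, "both", "My energy levels are low"),
        ("6A", "sex_drive", None, False, "v2", "In general I would rate my sex drive as"),
        ("6B", "sex_drive", None, False, "v2", "Sex drive over the last month compared to normal"),
        ("6C", "sex_drive", None, False, "v2", "Morning erections over the last month"),
        ("6D", "sex_drive", None, False, "v2",
         "Over the last month how does the number of morning erections compare to normal"),
    ]
    return [
        ItemKey(item_id=i, section=s, subscale=sub, reverse_coded=r, version=v, label=lab)
        for i, s, sub, r, v, lab in spec
    ]


#: Sex-drive and wellbeing items entering the EHMC (exercise hypogonadal
#: male condition) composite score: general sex drive, morning erections
#: and their change, plus the six energy/wellbeing statements.
DEFAULT_EHMC_ITEMS = ("6A", "6C", "6D", "5A1", "5A2", "5B1", "5B2", "5E1", "5D3")

#: Items entering the low-sex-drive categorisation rule.
SEX_DRIVE_RULE_ITEMS = ("6A", "6C", "6D")


def default_key() -> ScoringKey:
    """The key shipped with the package (see module docstring)."""
    return ScoringKey(_default_items(), DEFAULT_EHMC_ITEMS)
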