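"""Item dictionary for RAI 2.0 / MDS style assessment records.

The dictionary declares every coded item's value domain and groups items
into the named blocks the audit rules operate on (the 16 mood indicator
items, the 10 paired ADL self-performance/support items, the therapy and
nutrition blocks, the unlikely-to-reverse diagnoses, and the full set of
clinical quarterly variables used for whole-record carry-forward
detection, 231 codes by default).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import yaml

MISSING = ""  # missing token in CSV files

SECTORS = ("CCC", "LTC")
ASSESSMENT_TYPES = ("admission", "quarterly", "annual")

#: identity / date columns that precede the item columns in every record file
IDENTITY_COLUMNS = (
    "person_id",
    "facility_id",
    "sector",
    "assessment_type",
    "reference_date",
    "signoff_date",
    "birthdate",
)

ADL_NAMES = (
    "bed_mobility",
    "transfer",
    "locomotion",
    "dressing",
    "eating",
    "toilet_use",
    "personal_hygiene",
    "bathing",
    "walk_in_room",
    "locomotion_off_unit",
)

#: the seven self-performance items summed by the ADL Long Form scale
ADL_LONG_FORM_NAMES = (
    "bed_mobility",
    "transfer",
    "locomotion",
    "dressing",
    "eating",
    "toilet_use",
    "personal_hygiene",
)

MOOD_ITEMS = tuple(f"mood_{i:02d}" for i in range(1, 17))
#: the seven mood items summed by the Depression Rating Scale
DRS_ITEMS = MOOD_ITEMS[:7]

ABS_ITEMS = ("abs_verbal", "abs_physical", "abs_social", "abs_resists")

THERAPY_DISCIPLINES = ("speech", "ot", "pt")

NURSING_REHAB_ITEMS = tuple(
    f"nrehab_{name}"
    for name in (
        "rom_passive",
        "rom_active",
        "splint",
        "bed_mobility",
        "transfer",
        "walking",
        "dressing",
        "eating",
        "amputation",
        "toileting",
        "communication",
    )
)

DIAGNOSIS_ITEMS = (
    "multiple_sclerosis",
    "quadriplegia",
    "cerebral_palsy",
    "schizophrenia",
)


@dataclass(frozen=True)
class ItemDef:
    """Value domain of one coded item."""

    code: str
    domain: frozenset[int] | None = None  # enumerated; None = numeric range
    lo: float | None = None
    hi: float | None = None

    def in_domain(self, value) -> bool:
        if self.domain is not None:
            return value in self.domain
        if self.lo is not None and value < self.lo:
            return False
        if self.hi is not None and value > self.hi:
            return False
        return True


def _enum(code: str, *values: int) -> ItemDef:
    return ItemDef(code, frozenset(values))


def _rng(code: str, lo: float, hi: float) -> ItemDef:
    return ItemDef(code, None, lo, hi)


@dataclass
class ItemDictionary:
    """Declared items plus named block membership.

    Invariants enforced at construction: every block is a subset of the
    declared codes, the mood block has exactly 16 items, the ADL
    performance and support blocks have 10 one-to-one paired items each.
    """

    items: dict[str, ItemDef]
    blocks: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        declared = set(self.items)
        for name, codes in self.blocks.items():
            unknown = set(codes) - declared
            if unknown:
                raise ValueError(f"block {name} references undeclared codes {sorted(unknown)}")
        if len(self.blocks.get("MOOD", ())) != 16:
            raise ValueError("MOOD block must contain exactly 16 items")
        if len(self.blocks.get("ADL_PERF", ())) != 10 or len(self.blocks.get("ADL_SUPP", ())) != 10:
            raise ValueError("ADL_PERF and ADL_SUPP blocks must contain 10 paired items")

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(self.items)

    def block(self, name: str) -> tuple[str, ...]:
        return self.blocks[name]

    def adl_pairs(self) -> tuple[tuple[str, str], ...]:
        """(performance, support) code pairs, in declaration order."""
        return tuple(zip(self.blocks["ADL_PERF"], self.blocks["ADL_SUPP"]))

    def validate_value(self, code: str, value) -> bool:
        return self.items[code].in_domain(value)

    # -- serialization -------------------------------------------------
    def to_yaml(self, path) -> None:
        doc = {
            "items": {
                c: (
                    {"domain": sorted(d.domain)}
                    if d.domain is not None
                    else {"lo": d.lo, "hi": d.hi}
                )
                for c, d in self.items.items()
            },
            "blocks": {k: list(v) for k, v in self.blocks.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ItemDictionary":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        items = {}
        for code, spec in doc["items"].items():
            if "domain" in spec:
                items[code] = ItemDef(code, frozenset(spec["domain"]))
            else:
                items[code] = ItemDef(code, None, spec.get("lo"), spec.get("hi"))
        return cls(items=items, blocks={k: tuple(v) for k, v in doc["blocks"].items()})


def default_dictionary(n_clinical: int = 231) -> ItemDictionary:
    """Build the default dictionary.

    ``n_clinical`` sets the size of the CLINICAL block (the quarterly
    clinical variables compared wholesale by the carry-forward check);
    generic filler items ``clin_###`` pad the concrete items up to that
    size.  Diagnoses and the birthdate are not part of the CLINICAL
    block: the former are tracked by the longitudinal reversal check,
    the latter is a fixed person attribute.
    """
    items: list[ItemDef] = []
    items.append(_enum("comatose", 0, 1))
    items.append(_enum("mood_persistence", 0, 1, 2))
    items.extend(_enum(c, 0, 1, 2) for c in MOOD_ITEMS)
    for name in ADL_NAMES:
        items.append(_enum(f"adl_{name}_perf", 0, 1, 2, 3, 4, 8))
        items.append(_enum(f"adl_{name}_supp", 0, 1, 2, 3, 8))
    items.extend(_enum(c, 0, 1, 2, 3) for c in ABS_ITEMS)
    items.append(_enum("short_term_memory", 0, 1))
    items.append(_enum("decision_making", 0, 1, 2, 3))
    items.append(_enum("making_self_understood", 0, 1, 2, 3, 4))
    items.append(_enum("pain_frequency", 0, 1, 2))
    items.append(_enum("pain_intensity", 0, 1, 2, 3))
    items.append(_enum("bowel_continence", 0, 1, 2, 3, 4))
    items.append(_enum("parenteral_iv", 0, 1))
    items.append(_enum("feeding_tube", 0, 1))
    items.append(_enum("calories_proportion_code", 0, 1, 2, 3, 4))
    items.append(_enum("fluid_intake_code", 0, 1, 2, 3, 4, 5))
    items.append(_enum("ulcer_highest_stage", 0, 1, 2, 3, 4))
    items.append(_rng("ulcer_count_at_stage", 0, 99))
    for disc in THERAPY_DISCIPLINES:
        items.append(_enum(f"{disc}_days", 0, 1, 2, 3, 4, 5, 6, 7))
        items.append(_rng(f"{disc}_minutes", 0, 10_080))
    items.append(_enum("distinct_therapy_days", 0, 1, 2, 3, 4, 5, 6, 7))
    items.extend(_enum(c, 0, 1, 2, 3, 4, 5, 6, 7) for c in NURSING_REHAB_ITEMS)
    items.extend(_enum(c, 0, 1) for c in DIAGNOSIS_ITEMS)
    items.append(_rng("height_cm", 0, 300))
    items.append(_rng("weight_kg", 0, 400))

    concrete_clinical = [d.code for d in items if d.code not in DIAGNOSIS_ITEMS]
    n_filler = n_clinical - len(concrete_clinical)
    if n_filler < 0:
        raise ValueError(f"n_clinical must be >= {len(concrete_clinical)}")
    filler = [f"clin_{i:03d}" for i in range(1, n_filler + 1)]
    items.extend(_enum(c, 0, 1) for c in filler)

    blocks = {
        "MOOD": MOOD_ITEMS,
        "ADL_PERF": tuple(f"adl_{n}_perf" for n in ADL_NAMES),
        "ADL_SUPP": tuple(f"adl_{n}_supp" for n in ADL_NAMES),
        "CLINICAL": tuple(concrete_clinical + filler),
        "DIAGNOSES": DIAGNOSIS_ITEMS,
        "THERAPY": tuple(
            [f"{d}_days" for d in THERAPY_DISCIPLINES]
            + [f"{d}_minutes" for d in THERAPY_DISCIPLINES]
            + ["distinct_therapy_days"]
        ),
        "NUTRITION": (
            "parenteral_iv",
            "feeding_tube",
            "calories_proportion_code",
            "fluid_intake_code",
        ),
        "ULCER": ("ulcer_highest_stage", "ulcer_count_at_stage"),
        "VITALS": ("height_cm", "weight_kg"),
        "NURSING_REHAB": NURSING_REHAB_ITEMS,
    }
    return ItemDictionary(items={d.code: d for d in items}, blocks=blocks)


def item_columns(dictionary: ItemDictionary) -> tuple[str, ...]:
    return dictionary.codes


def all_columns(dictionary: ItemDictionary) -> tuple[str, ...]:
    return IDENTITY_COLUMNS + dictionary.codes
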