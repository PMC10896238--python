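"""The indicator catalogue: definitions, scales and reference standards.

The catalogue is shipped as YAML (``data/catalogue.yaml``) and is the single
source of truth for what the engine computes: each entry carries the block of
the determinants-of-maternal-death model it belongs to, the calculation
formula in words, the source systems and canonical variables it depends on
(which drive the data-quality alerts), the scale multiplier, and the
reference standard used to benchmark values.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import yaml

from .errors import ConfigError

SCALE_FACTORS = {
    "percent": 100.0,
    "per_100": 100.0,
    "per_1000": 1000.0,
    "per_100k": 100000.0,
    "count": 1.0,
    "km": 1.0,
    "index": 1.0,
}

BLOCKS = ("1", "2", "3", "4", "5", "6", "quality")


@dataclass(frozen=True)
class ReferenceStandard:
    """How one indicator is judged.

    kind: fixed_threshold | range | national_average | band | per_group | none
    direction: higher_better | lower_better | within_range | n/a
    strict: for fixed thresholds, whether the boundary itself fails
        (a "<30" goal fails at exactly 30; a "90%" goal passes at exactly 90).
    """

    kind: str
    direction: str = "n/a"
    value: Optional[float] = None
    lower: Optional[float] = None
    upper: Optional[float] = None
    strict: bool = False
    provenance: str = ""
    groups: Optional[Dict[str, "ReferenceStandard"]] = None

    def __post_init__(self):
        if self.kind == "range" and not (self.lower is not None
                                         and self.upper is not None
                                         and self.lower <= self.upper):
            raise ConfigError(f"range standard needs lower <= upper, got "
                              f"{self.lower}..{self.upper}")
        if self.kind == "fixed_threshold" and self.value is None:
            raise ConfigError("fixed_threshold standard needs a value")

    @classmethod
    def from_dict(cls, raw: dict) -> "ReferenceStandard":
        groups = None
        if raw.get("groups"):
            groups = {str(k): cls.from_dict(v) for k, v in raw["groups"].items()}
        return cls(
            kind=raw["kind"], direction=raw.get("direction", "n/a"),
            value=raw.get("value"), lower=raw.get("lower"),
            upper=raw.get("upper"), strict=bool(raw.get("strict", False)),
            provenance=raw.get("provenance", ""), groups=groups)

    def for_category(self, category: Optional[str]) -> "ReferenceStandard":
        if self.kind != "per_group":
            return self
        if category is None or self.groups is None or category not in self.groups:
            return ReferenceStandard(kind="none")
        return self.groups[category]


@dataclass(frozen=True)
class IndicatorDefinition:
    id: str
    name: str
    block: str
    kind: str            # proportion | rate | composition | count | median | index
    scale: str
    formula: str
    systems: tuple
    source_variables: tuple
    reference: ReferenceStandard
    categories: tuple = ()
    multi_label: bool = False

    @property
    def scale_factor(self) -> float:
        return SCALE_FACTORS[self.scale]


class Catalogue:
    """Ordered collection of indicator definitions with id lookup."""

    def __init__(self, definitions: List[IndicatorDefinition]):
        self._defs = list(definitions)
        self._by_id = {d.id: d for d in self._defs}
        if len(self._by_id) != len(self._defs):
            raise ConfigError("duplicate indicator ids in catalogue")

    def __len__(self) -> int:
        return len(self._defs)

    def __iter__(self):
        return iter(self._defs)

    def __contains__(self, indicator_id: str) -> bool:
        return indicator_id in self._by_id

    def get(self, indicator_id: str) -> IndicatorDefinition:
        try:
            return self._by_id[indicator_id]
        except KeyError:
            raise KeyError(f"unknown indicator id {indicator_id!r}") from None

    def ids(self) -> List[str]:
        return [d.id for d in self._defs]

    def block(self, block: str) -> List[IndicatorDefinition]:
        return [d for d in self._defs if d.block == str(block)]

    @classmethod
    def from_yaml(cls, path) -> "Catalogue":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        defs = []
        for entry in raw["indicators"]:
            block = str(entry["block"])
            if block not in BLOCKS:
                raise ConfigError(f"unknown block {block!r} for {entry['id']}")
            if entry["scale"] not in SCALE_FACTORS:
                raise ConfigError(f"unknown scale {entry['scale']!r} for {entry['id']}")
            defs.append(IndicatorDefinition(
                id=entry["id"], name=entry["name"], block=block,
                kind=entry["kind"], scale=entry["scale"],
                formula=entry.get("formula", ""),
                systems=tuple(entry.get("systems", ())),
                source_variables=tuple(entry.get("source_variables", ())),
                categories=tuple(str(c) for c in entry.get("categories", ())),
                multi_label=bool(entry.get("multi_label", False)),
                reference=ReferenceStandard.from_dict(entry["reference"]),
            ))
        return cls(defs)


def load_catalogue() -> Catalogue:
    """Load the catalogue shipped with the package."""
    ref = importlib.resources.files("matvig").joinpath("data/catalogue.yaml")
    with importlib.resources.as_file(ref) as p:
        return Catalogue.from_yaml(p)
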