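"""Geographic hierarchy: municipality -> health region -> state -> macro-region -> country.

Indicators are computed per municipality and rolled up this tree; the
hierarchy file is the single source of truth for membership (which
municipalities form a health region, etc.).  Codes are opaque strings; the
canonical municipality form is 6 digits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import pandas as pd

from .errors import StructuralError

LEVELS = ("municipality", "health_region", "state", "macro_region", "country")
LEVEL_INDEX = {lv: i for i, lv in enumerate(LEVELS)}


@dataclass(frozen=True)
class GeoUnit:
    code: str
    name: str
    level: str
    parent_code: Optional[str]
    lat: Optional[float] = None
    lon: Optional[float] = None


class GeoHierarchy:
    """Ancestor/descendant index over the five-level geography tree."""

    def __init__(self, units: List[GeoUnit]):
        self._units: Dict[str, GeoUnit] = {}
        for u in units:
            key = (u.level, u.code)
            if any((v.level, v.code) == key for v in self._units.values()):
                raise StructuralError(f"duplicate code {u.code!r} at level {u.level}")
            if u.code in self._units:
                raise StructuralError(f"code {u.code!r} used at two levels")
            self._units[u.code] = u
        self._children: Dict[str, List[str]] = {c: [] for c in self._units}
        self._validate()

    def _validate(self) -> None:
        for u in self._units.values():
            if u.level == "country":
                if u.parent_code:
                    raise StructuralError("country unit must have no parent")
                continue
            if not u.parent_code or u.parent_code not in self._units:
                raise StructuralError(
                    f"orphan unit {u.code!r} ({u.level}): parent "
                    f"{u.parent_code!r} not found")
            parent = self._units[u.parent_code]
            if LEVEL_INDEX[parent.level] != LEVEL_INDEX[u.level] + 1:
                raise StructuralError(
                    f"unit {u.code!r} ({u.level}) has parent at level "
                    f"{parent.level}, expected {LEVELS[LEVEL_INDEX[u.level] + 1]}")
            self._children[u.parent_code].append(u.code)
        # cycle check is implied by the strict level-step rule, but walking up
        # guards against a malformed LEVELS edit
        for u in self._units.values():
            seen = set()
            cur: Optional[GeoUnit] = u
            while cur is not None:
                if cur.code in seen:
                    raise StructuralError(f"cycle through {cur.code!r}")
                seen.add(cur.code)
                cur = self._units.get(cur.parent_code) if cur.parent_code else None

    # -- queries -------------------------------------------------------------
    def __contains__(self, code: str) -> bool:
        return code in self._units

    def unit(self, code: str) -> GeoUnit:
        try:
            return self._units[code]
        except KeyError:
            raise StructuralError(f"unknown geo code {code!r}") from None

    def level_of(self, code: str) -> str:
        return self.unit(code).level

    def ancestors(self, code: str) -> List[GeoUnit]:
        """All strictly higher-level units containing ``code``, nearest first."""
        out = []
        cur = self.unit(code)
        while cur.parent_code:
            cur = self.unit(cur.parent_code)
            out.append(cur)
        return out

    def descendants(self, code: str, level: str = "municipality") -> List[str]:
        """Codes of all ``level`` units under ``code`` (code order)."""
        if level not in LEVEL_INDEX:
            raise StructuralError(f"unknown level {level!r}")
        start = self.unit(code)
        if LEVEL_INDEX[level] > LEVEL_INDEX[start.level]:
            return []
        if start.level == level:
            return [start.code]
        out: List[str] = []
        stack = [start.code]
        while stack:
            cur = stack.pop()
            for child in self._children[cur]:
                if self._units[child].level == level:
                    out.append(child)
                else:
                    stack.append(child)
        return sorted(out)

    def codes_at(self, level: str) -> List[str]:
        return sorted(c for c, u in self._units.items() if u.level == level)

    def siblings(self, code: str) -> List[str]:
        """Other units sharing this unit's parent (e.g. municipalities in the
        same health region)."""
        u = self.unit(code)
        if not u.parent_code:
            return []
        return sorted(c for c in self._children[u.parent_code] if c != code)

    # -- construction / serialization ----------------------------------------
    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeoHierarchy":
        required = {"code", "name", "level", "parent_code"}
        missing = required - set(df.columns)
        if missing:
            raise StructuralError(f"hierarchy file missing columns: {sorted(missing)}")
        units = []
        for row in df.itertuples(index=False):
            parent = getattr(row, "parent_code")
            parent = None if (parent is None or parent != parent or parent == "") else str(parent)
            lat = getattr(row, "lat", None)
            lon = getattr(row, "lon", None)
            units.append(GeoUnit(
                code=str(row.code), name=str(row.name), level=str(row.level),
                parent_code=parent,
                lat=None if lat is None or lat != lat else float(lat),
                lon=None if lon is None or lon != lon else float(lon)))
        bad_levels = {u.level for u in units} - set(LEVELS)
        if bad_levels:
            raise StructuralError(f"unknown levels in hierarchy: {sorted(bad_levels)}")
        return cls(units)

    @classmethod
    def load(cls, path) -> "GeoHierarchy":
        return cls.from_frame(pd.read_csv(path, dtype={"code": str, "parent_code": str}))

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "code": u.code, "name": u.name, "level": u.level,
            "parent_code": u.parent_code or "", "lat": u.lat, "lon": u.lon,
        } for u in sorted(self._units.values(),
                          key=lambda u: (LEVEL_INDEX[u.level], u.code))]
        return pd.DataFrame(rows)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False)
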