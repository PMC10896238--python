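"""Roll-up across the geographic hierarchy, benchmarks and historical series.

Aggregation is component-wise: numerators and denominators are summed over
the child units and the ratio is re-taken — rates are never averaged.
Median-type indicators cannot be rolled up from municipal medians; they are
recomputed from pooled birth-level distances (``indicators.compute_unit``
already does exactly that at any level), and index inputs (MHDI) are simply
not applicable above the municipality.

Benchmarking evaluates each value against its catalogue reference standard;
"national average" standards are dynamic — resolved from the country-level
value computed on the same data and year, never hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .catalogue import Catalogue, ReferenceStandard, load_catalogue
from .errors import MatvigError
from .geo import GeoHierarchy
from .indicators import IndicatorValue

_EPS = 1e-9


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def aggregate(municipal_values: Sequence[IndicatorValue],
              hierarchy: GeoHierarchy, target_geo: str,
              catalogue: Optional[Catalogue] = None) -> List[IndicatorValue]:
    """Aggregate municipal indicator components to ``target_geo``.

    All municipal values must share one year.  Count-based indicators sum
    numerators and denominators exactly; median and index indicators are
    returned as not-applicable placeholders (recompute them from pooled
    records instead).  Member municipalities absent from the input are
    flagged, not imputed.
    """
    catalogue = catalogue or load_catalogue()
    years = {v.year for v in municipal_values}
    if len(years) != 1:
        raise MatvigError(f"aggregation needs a single year, got {sorted(years)}")
    year = years.pop()
    bad_level = [v.geo for v in municipal_values if v.geo_level not in
                 (None, "municipality")]
    if bad_level:
        raise MatvigError("aggregation input must be municipal values")

    members = set(hierarchy.descendants(target_geo, "municipality"))
    level = hierarchy.level_of(target_geo)
    in_scope = [v for v in municipal_values if v.geo in members]
    present = {v.geo for v in in_scope}
    missing = sorted(members - present)

    grouped: Dict[Tuple[str, Optional[str]], List[IndicatorValue]] = {}
    for v in in_scope:
        grouped.setdefault((v.definition_id, v.category), []).append(v)

    out: List[IndicatorValue] = []
    for (ind_id, category), vals in sorted(grouped.items(),
                                           key=lambda kv: (kv[0][0], kv[0][1] or "")):
        defn = catalogue.get(ind_id)
        flags = [f"units_missing:{len(missing)}"] if missing else []
        if defn.kind in ("median", "index"):
            out.append(IndicatorValue(
                definition_id=ind_id, geo=target_geo, year=year, value=None,
                scale=defn.scale, category=category, geo_level=level,
                undefined=True,
                flags=flags + ["not_aggregable:recompute_from_records"
                               if defn.kind == "median"
                               else "not_applicable_above_municipality"]))
            continue
        num = sum(v.numerator for v in vals if v.numerator is not None)
        if defn.kind == "count":
            out.append(IndicatorValue(
                definition_id=ind_id, geo=target_geo, year=year,
                value=float(num), numerator=float(num), denominator=None,
                scale=defn.scale, category=category, geo_level=level,
                flags=flags))
            continue
        den = sum(v.denominator for v in vals if v.denominator is not None)
        undefined = den == 0
        value = None if undefined else num / den * defn.scale_factor
        if undefined:
            flags = flags + ["undefined:zero_denominator"]
        out.append(IndicatorValue(
            definition_id=ind_id, geo=target_geo, year=year, value=value,
            numerator=float(num), denominator=float(den), scale=defn.scale,
            category=category, geo_level=level, undefined=undefined,
            flags=flags))
    return out


# ---------------------------------------------------------------------------
# Benchmarks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BenchmarkResult:
    indicator_id: str
    geo: str
    year: int
    status: str                       # meets | does_not_meet | within | above | below | not_applicable
    comparator_value: Optional[float] = None
    category: Optional[str] = None


def compare(value: IndicatorValue, standard: ReferenceStandard,
            national_value: Optional[float] = None) -> BenchmarkResult:
    """Evaluate one value against one reference standard.

    Fixed thresholds honor their direction and strictness; ranges report
    within/above/below; national-average standards compare against the
    dynamic national value; undefined values and kind none/band standards
    are not applicable.
    """
    std = standard.for_category(value.category)

    def result(status, comparator=None):
        return BenchmarkResult(indicator_id=value.definition_id, geo=value.geo,
                               year=value.year, status=status,
                               comparator_value=comparator,
                               category=value.category)

    if value.undefined or value.value is None or std.kind in ("none", "band"):
        return result("not_applicable")
    v = value.value
    if std.kind == "fixed_threshold":
        t = float(std.value)
        if std.direction == "higher_better":
            ok = v > t if std.strict else v >= t
        elif std.direction == "lower_better":
            ok = v < t if std.strict else v <= t
        else:
            raise MatvigError(f"fixed threshold needs a direction, got "
                              f"{std.direction!r}")
        return result("meets" if ok else "does_not_meet", t)
    if std.kind == "range":
        if v < std.lower:
            return result("below", std.lower)
        if v > std.upper:
            return result("above", std.upper)
        return result("within", None)
    if std.kind == "national_average":
        if national_value is None:
            return result("not_applicable")
        if abs(v - national_value) <= _EPS:
            return result("within", national_value)
        return result("above" if v > national_value else "below", national_value)
    raise MatvigError(f"unknown standard kind {std.kind!r}")


def national_value_map(country_values: Sequence[IndicatorValue]
                       ) -> Dict[Tuple[str, Optional[str]], float]:
    """Index country-level values by (indicator, category) for use as the
    dynamic national-average comparator."""
    out = {}
    for v in country_values:
        if v.value is not None:
            out[(v.definition_id, v.category)] = v.value
    return out


def benchmark_values(values: Sequence[IndicatorValue], catalogue: Catalogue,
                     national: Optional[Dict] = None) -> List[IndicatorValue]:
    """Attach benchmark status and comparator to each value, in place."""
    national = national or {}
    for v in values:
        defn = catalogue.get(v.definition_id)
        std = defn.reference
        nat = national.get((v.definition_id, v.category))
        res = compare(v, std, national_value=nat)
        v.benchmark_status = res.status
        v.comparator_value = res.comparator_value
    return list(values)


# ---------------------------------------------------------------------------
# Historical series with comparators
# ---------------------------------------------------------------------------

def similar_mhdi_municipalities(geo: str, mhdi: pd.DataFrame, k: int) -> List[str]:
    """The k municipalities closest in MHDI to ``geo`` (excluding it); ties
    broken deterministically by geo code order."""
    table = mhdi.set_index("geo")["mhdi"]
    if geo not in table.index:
        return []
    target = table.loc[geo]
    others = table.drop(index=geo)
    # distances rounded so float representation noise cannot reorder ties
    ranked = sorted(others.items(),
                    key=lambda kv: (round(abs(kv[1] - target), 9), kv[0]))
    return [code for code, _ in ranked[:k]]


def historical_series(values_frame: pd.DataFrame, indicator_id: str, geo: str,
                      years: Sequence[int], hierarchy: GeoHierarchy,
                      comparator: Optional[str] = None,
                      mhdi: Optional[pd.DataFrame] = None, k: int = 3,
                      category: Optional[str] = None
                      ) -> Tuple[pd.DataFrame, List[str]]:
    """One row per year per unit for an indicator, for the unit of interest
    plus its comparator units.

    comparator: None, ``"same_region"`` (sibling municipalities of the same
    health region) or ``"similar_mhdi"`` (k nearest by |MHDI difference|).
    Returns (series, warnings); an empty comparator set is a warning, not an
    error.
    """
    warnings: List[str] = []
    units = [geo]
    if comparator == "same_region":
        comps = hierarchy.siblings(geo)
        if not comps:
            warnings.append("empty comparator set: no siblings in hierarchy")
        units += comps
    elif comparator == "similar_mhdi":
        if mhdi is None:
            raise MatvigError("similar_mhdi comparator needs the MHDI table")
        comps = similar_mhdi_municipalities(geo, mhdi, k)
        if not comps:
            warnings.append("empty comparator set: MHDI unavailable")
        units += comps
    elif comparator is not None:
        raise MatvigError(f"unknown comparator {comparator!r}")

    sel = values_frame[
        (values_frame["indicator_id"] == indicator_id)
        & values_frame["geo_code"].isin(units)
        & values_frame["year"].isin(list(years))]
    if category is not None:
        sel = sel[sel["category"] == category]
    sel = sel.sort_values(["year", "geo_code"]).reset_index(drop=True)
    return sel, warnings
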