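"""Information-quality indicators and interpretation alerts.

Every substantive indicator is only as good as the registration systems
behind it.  This module computes the quality companions — system coverage
(recorded events as a share of demographic estimates), investigation
coverage of deaths, and per-variable incompleteness — and wires them to the
substantive indicators as alerts: an indicator built on a variable with high
incompleteness, or on a system with low (or unassessable) coverage, is
delivered with an explicit "interpret with caution" message, never silently.

Boundary conventions: a "90%" goal passes at exactly 90; the "<5%"
incompleteness ceiling fails at exactly 5.  Over-registration (coverage
above 100) is flagged, not clipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .catalogue import Catalogue, load_catalogue
from .errors import DomainError
from .indicators import IndicatorValue, PanelData, ratio_value
from .schemas import fields_for

COVERAGE_THRESHOLD = 90.0          # system coverage adequacy
INCOMPLETENESS_THRESHOLD = 5.0     # per-variable ceiling; >= 5 is flagged
WCA_INVESTIGATION_TARGET = 90.0    # deaths of women 10-49
MATERNAL_INVESTIGATION_TARGET = 100.0


def coverage(recorded: float, estimated: float) -> Tuple[Optional[float], List[str]]:
    """System coverage percent with adequacy flags.

    Returns (pct, flags); pct is None (undefined) when the estimate is zero.
    """
    if recorded < 0 or estimated < 0:
        raise DomainError("counts must be non-negative")
    if estimated == 0:
        return None, ["undefined:zero_estimate"]
    pct = recorded / estimated * 100.0
    flags = []
    if pct < COVERAGE_THRESHOLD:
        flags.append("low_coverage")
    if pct > 100.0:
        flags.append("over_registration")
    return pct, flags


def incompleteness(frame: pd.DataFrame, variable: str,
                   record_kind: str) -> Tuple[Optional[float], List[str]]:
    """Percent of records with ``variable`` blank/ignored, over the frame.

    Sentinel codes were already mapped to missing at load time, so a simple
    null count is the full incompleteness measure here.
    """
    if variable not in {f.name for f in fields_for(record_kind)}:
        raise KeyError(f"unknown variable {variable!r} for {record_kind}")
    n = len(frame)
    if n == 0:
        return None, ["undefined:no_records"]
    pct = float(frame[variable].isna().sum()) / n * 100.0
    flags = ["high_incompleteness"] if pct >= INCOMPLETENESS_THRESHOLD else []
    return pct, flags


#: which record frame holds each canonical variable (for incompleteness)
_VARIABLE_FRAME = {}
for _kind, _attr in (("live_birth", "births"), ("maternal_death", "deaths"),
                     ("hospitalization", "admissions")):
    for _f in fields_for(_kind):
        _VARIABLE_FRAME.setdefault(_f.name, (_kind, _attr))


@dataclass
class QualityAssessment:
    """Quality panel for one geography x year."""

    geo: str
    year: int
    sinasc_coverage_pct: Optional[float] = None
    sim_coverage_pct: Optional[float] = None
    wca_deaths_investigated_pct: Optional[float] = None
    maternal_deaths_investigated_pct: Optional[float] = None
    incompleteness_pct: Dict[str, Optional[float]] = field(default_factory=dict)
    flags: Dict[str, List[str]] = field(default_factory=dict)


def assess_quality(data: PanelData, geo: str, year: int,
                   variables: Sequence[str] = ()) -> QualityAssessment:
    """Compute the quality assessment from the loaded panel data.

    ``variables``: canonical variables whose incompleteness should be
    tracked; defaults to every variable any catalogue indicator declares.
    """
    munis, b, d, a = data.slice(geo, year)
    qa = QualityAssessment(geo=geo, year=year)

    est = data.ref.estimates
    sel = est[est["geo"].isin(munis) & (est["year"] == year)]
    if not sel.empty and sel["estimated_births"].notna().any():
        pct, fl = coverage(float(len(b)), float(sel["estimated_births"].sum()))
        qa.sinasc_coverage_pct = pct
        qa.flags["sinasc_coverage"] = fl
    if not sel.empty and sel["estimated_deaths"].notna().any():
        pct, fl = coverage(float(len(d)), float(sel["estimated_deaths"].sum()))
        qa.sim_coverage_pct = pct
        qa.flags["sim_coverage"] = fl

    inv = data.ref.investigation
    isel = inv[inv["geo"].isin(munis) & (inv["year"] == year)]
    if not isel.empty:
        wt = float(isel["wca_deaths_total"].sum())
        if wt > 0:
            qa.wca_deaths_investigated_pct = \
                float(isel["wca_deaths_investigated"].sum()) / wt * 100.0
        mt = float(isel["maternal_deaths_total"].sum())
        if mt > 0:
            qa.maternal_deaths_investigated_pct = \
                float(isel["maternal_deaths_investigated"].sum()) / mt * 100.0

    frames = {"births": b, "deaths": d, "admissions": a}
    for var in variables:
        if var not in _VARIABLE_FRAME:
            continue
        kind, attr = _VARIABLE_FRAME[var]
        pct, fl = incompleteness(frames[attr], var, kind)
        qa.incompleteness_pct[var] = pct
        qa.flags[f"incompleteness:{var}"] = fl
    return qa


def quality_values(qa: QualityAssessment, data: PanelData,
                   catalogue: Optional[Catalogue] = None) -> List[IndicatorValue]:
    """Express the assessment as catalogue indicator values (quality block)."""
    catalogue = catalogue or load_catalogue()
    munis, b, d, _ = data.slice(qa.geo, qa.year)
    values: List[IndicatorValue] = []

    est = data.ref.estimates
    sel = est[est["geo"].isin(munis) & (est["year"] == qa.year)]
    est_b = float(sel["estimated_births"].sum()) if not sel.empty else 0.0
    est_d = float(sel["estimated_deaths"].sum()) if not sel.empty else 0.0
    v = ratio_value(catalogue.get("sinasc_coverage_pct"), qa.geo, qa.year,
                    float(len(b)), est_b)
    v.flags += qa.flags.get("sinasc_coverage", [])
    values.append(v)
    v = ratio_value(catalogue.get("sim_coverage_pct"), qa.geo, qa.year,
                    float(len(d)), est_d)
    v.flags += qa.flags.get("sim_coverage", [])
    values.append(v)

    inv = data.ref.investigation
    isel = inv[inv["geo"].isin(munis) & (inv["year"] == qa.year)]
    wt = float(isel["wca_deaths_total"].sum()) if not isel.empty else 0.0
    wi = float(isel["wca_deaths_investigated"].sum()) if not isel.empty else 0.0
    mt = float(isel["maternal_deaths_total"].sum()) if not isel.empty else 0.0
    mi = float(isel["maternal_deaths_investigated"].sum()) if not isel.empty else 0.0
    values.append(ratio_value(catalogue.get("wca_deaths_investigated_pct"),
                              qa.geo, qa.year, wi, wt))
    values.append(ratio_value(catalogue.get("maternal_deaths_investigated_pct"),
                              qa.geo, qa.year, mi, mt))

    inc_defn = catalogue.get("incompleteness_pct")
    for var, pct in qa.incompleteness_pct.items():
        val = IndicatorValue(
            definition_id=inc_defn.id, geo=qa.geo, year=qa.year,
            value=pct, scale="percent", category=var,
            undefined=pct is None,
            flags=list(qa.flags.get(f"incompleteness:{var}", [])))
        values.append(val)
    for v in values:
        v.geo_level = data.hierarchy.level_of(qa.geo)
    return values


def attach_alerts(values: Sequence[IndicatorValue], qa: QualityAssessment,
                  catalogue: Optional[Catalogue] = None) -> List[IndicatorValue]:
    """Attach interpretation alerts in place (values are never mutated, only
    their alert lists are filled) and return the same list.

    Rules: SINASC/SIM-based indicators inherit coverage alerts (< 90 low,
    unavailable -> "coverage not assessable"); SIM-based mortality indicators
    inherit investigation-coverage alerts (< 90 for deaths of women of
    childbearing age, < 100 for maternal deaths); each indicator inherits an
    incompleteness alert for every source variable at or above 5%.
    """
    catalogue = catalogue or load_catalogue()
    for v in values:
        defn = catalogue.get(v.definition_id)
        if defn.block == "quality":
            continue
        alerts = []
        for system, cov in (("SINASC", qa.sinasc_coverage_pct),
                            ("SIM", qa.sim_coverage_pct)):
            if system not in defn.systems:
                continue
            if cov is None:
                alerts.append({"severity": "warning",
                               "message": f"{system} coverage not assessable"})
            elif cov < COVERAGE_THRESHOLD:
                alerts.append({
                    "severity": "warning",
                    "message": f"interpret with caution: {system} coverage "
                               f"{cov:.1f}% below {COVERAGE_THRESHOLD:g}%"})
        if "SIM" in defn.systems:
            wca = qa.wca_deaths_investigated_pct
            if wca is not None and wca < WCA_INVESTIGATION_TARGET:
                alerts.append({
                    "severity": "warning",
                    "message": f"investigation of deaths of women of "
                               f"childbearing age at {wca:.1f}% (goal "
                               f"{WCA_INVESTIGATION_TARGET:g}%)"})
            mat = qa.maternal_deaths_investigated_pct
            if mat is not None and mat < MATERNAL_INVESTIGATION_TARGET:
                alerts.append({
                    "severity": "warning",
                    "message": f"maternal-death investigation at {mat:.1f}% "
                               f"(goal {MATERNAL_INVESTIGATION_TARGET:g}%)"})
        for var in defn.source_variables:
            pct = qa.incompleteness_pct.get(var)
            if pct is not None and pct >= INCOMPLETENESS_THRESHOLD:
                alerts.append({
                    "severity": "caution",
                    "message": f"interpret with caution: {var} "
                               f"incompleteness {pct:.1f}%"})
        v.alerts = alerts
    return list(values)
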