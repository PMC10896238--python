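"""Report generation: the panel's three presentation levels as files.

Level 1: every catalogue indicator for one geography and year, one row per
value, with benchmark status and quality alerts.
Level 2: per-block historical series over the loaded period, with optional
comparator units.
Level 3: per-indicator detail — documentation from the catalogue, the
computed components, and the alerts that apply.

All outputs are plain CSV/JSON and deterministic given the inputs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd

from .aggregate import benchmark_values, historical_series, national_value_map
from .catalogue import Catalogue, load_catalogue
from .errors import MatvigError
from .indicators import (AbortionCorrectionConfig, IndicatorValue, PanelData,
                         compute_unit, values_to_frame)
from .quality import assess_quality, attach_alerts, quality_values
from .smm import SMMCodeConfig


def _quality_variables(catalogue: Catalogue) -> List[str]:
    out: List[str] = []
    for defn in catalogue:
        for var in defn.source_variables:
            if var not in out:
                out.append(var)
    return out


def compute_geo_year(data: PanelData, geo: str, year: int,
                     catalogue: Optional[Catalogue] = None,
                     smm_config: Optional[SMMCodeConfig] = None,
                     abortion_config: Optional[AbortionCorrectionConfig] = None,
                     national: Optional[Dict] = None) -> List[IndicatorValue]:
    """All indicators (blocks 1-6 plus quality) for one unit and year, with
    alerts attached and benchmarks evaluated."""
    catalogue = catalogue or load_catalogue()
    smm_config = smm_config or SMMCodeConfig.default()
    abortion_config = abortion_config or AbortionCorrectionConfig.default()
    values = compute_unit(data, geo, year, catalogue=catalogue,
                          smm_config=smm_config,
                          abortion_config=abortion_config)
    qa = assess_quality(data, geo, year,
                        variables=_quality_variables(catalogue))
    values = attach_alerts(values, qa, catalogue=catalogue)
    values += quality_values(qa, data, catalogue=catalogue)
    benchmark_values(values, catalogue, national=national)
    return values


def compute_panel(data: PanelData, geos: Sequence[str], years: Sequence[int],
                  catalogue: Optional[Catalogue] = None,
                  smm_config: Optional[SMMCodeConfig] = None,
                  abortion_config: Optional[AbortionCorrectionConfig] = None
                  ) -> pd.DataFrame:
    """Tidy indicator table for many units and years.  The national-average
    comparator for each year is computed from the country-level values on the
    same data, never hard-coded."""
    catalogue = catalogue or load_catalogue()
    smm_config = smm_config or SMMCodeConfig.default()
    abortion_config = abortion_config or AbortionCorrectionConfig.default()
    frames = []
    for year in sorted(years):
        country = compute_unit(data, "BR" if "BR" in data.hierarchy else
                               data.hierarchy.codes_at("country")[0], year,
                               catalogue=catalogue, smm_config=smm_config,
                               abortion_config=abortion_config)
        national = national_value_map(country)
        for geo in geos:
            values = compute_geo_year(data, geo, year, catalogue=catalogue,
                                      smm_config=smm_config,
                                      abortion_config=abortion_config,
                                      national=national)
            frames.append(values_to_frame(values))
    return pd.concat(frames, ignore_index=True)


def catalogue_listing(catalogue: Optional[Catalogue] = None,
                      block: Optional[str] = None) -> List[dict]:
    """Machine-readable indicator documentation (id, block, formula, sources,
    reference)."""
    catalogue = catalogue or load_catalogue()
    defs = catalogue.block(block) if block is not None else list(catalogue)
    out = []
    for d in defs:
        ref = d.reference
        out.append({
            "id": d.id, "name": d.name, "block": d.block, "kind": d.kind,
            "scale": d.scale, "formula": d.formula,
            "sources": list(d.systems),
            "source_variables": list(d.source_variables),
            "reference": {
                "kind": ref.kind, "direction": ref.direction,
                "value": ref.value, "lower": ref.lower, "upper": ref.upper,
                "strict": ref.strict, "provenance": ref.provenance,
            },
        })
    return out


def run_full_report(data: PanelData, geo: str, year: int, out_dir,
                    catalogue: Optional[Catalogue] = None,
                    smm_config: Optional[SMMCodeConfig] = None,
                    abortion_config: Optional[AbortionCorrectionConfig] = None,
                    comparator: Optional[str] = None) -> Dict[str, str]:
    """Write the three presentation levels under ``out_dir``.

    Returns a map of level name to file path.  Raises on a geography outside
    the hierarchy or a year outside the loaded range.
    """
    catalogue = catalogue or load_catalogue()
    if geo not in data.hierarchy:
        raise MatvigError(f"geography {geo!r} not in the hierarchy")
    years = data.years()
    if year not in years:
        raise MatvigError(f"year {year} outside the loaded range "
                          f"{years[0]}-{years[-1]}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    panel = compute_panel(data, [geo], years, catalogue=catalogue,
                          smm_config=smm_config,
                          abortion_config=abortion_config)

    paths: Dict[str, str] = {}
    level1 = panel[panel["year"] == year].reset_index(drop=True)
    p1 = out_dir / "level1_all_indicators.csv"
    level1.to_csv(p1, index=False)
    paths["level1"] = str(p1)

    for block in ("1", "2", "3", "4", "5", "6", "quality"):
        ids = [d.id for d in catalogue.block(block)]
        frames = []
        for ind_id in ids:
            series, _ = historical_series(panel, ind_id, geo, years,
                                          data.hierarchy,
                                          comparator=comparator,
                                          mhdi=data.ref.mhdi)
            frames.append(series)
        block_frame = pd.concat(frames, ignore_index=True) if frames \
            else pd.DataFrame()
        p2 = out_dir / f"level2_block_{block}_series.csv"
        block_frame.to_csv(p2, index=False)
        paths[f"level2_block_{block}"] = str(p2)

    detail = []
    docs = {d["id"]: d for d in catalogue_listing(catalogue)}
    for _, row in level1.iterrows():
        entry = dict(row)
        entry = {k: (None if pd.isna(v) else v) for k, v in entry.items()}
        entry["documentation"] = docs[row["indicator_id"]]
        detail.append(entry)
    p3 = out_dir / "level3_indicator_detail.json"
    with open(p3, "w", encoding="utf-8") as fh:
        json.dump(detail, fh, indent=2, sort_keys=True, default=str)
    paths["level3"] = str(p3)
    return paths
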