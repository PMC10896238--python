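"""Computation of the surveillance indicators (blocks 1-6).

Every substantive indicator is a ratio ``numerator / denominator x scale``
over microdata pooled for one geographic unit and year; the numerator and
denominator are kept on every value so parents can be aggregated exactly by
summing components.  Records missing a field an indicator needs are excluded
from both numerator and denominator, and the exclusion count travels with the
value as a quality flag (incompleteness is monitored alongside, never
silently absorbed).

Convention: all indicators are keyed to the mother's municipality of
*residence*; only place-of-occurrence and the displacement median also read
the occurrence municipality.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .catalogue import Catalogue, IndicatorDefinition, SCALE_FACTORS, load_catalogue
from .errors import ConfigError, DomainError
from .geo import GeoHierarchy
from .io import F_10_49_BANDS, ReferenceTables, SchemaMap, canonical_schema_map, load_table
from . import robson as robson_mod
from . import smm as smm_mod
from .smm import SMMCodeConfig

MMR_INSTABILITY_DEATHS = 5  # fewer maternal deaths than this flags the ratio unstable

MHDI_BANDS = ("very_low", "low", "medium", "high", "very_high")


@dataclass
class IndicatorValue:
    """One computed indicator value for a geography x year (x category)."""

    definition_id: str
    geo: str
    year: int
    value: Optional[float]
    numerator: Optional[float] = None
    denominator: Optional[float] = None
    scale: str = "percent"
    category: Optional[str] = None
    geo_level: Optional[str] = None
    undefined: bool = False
    flags: List[str] = field(default_factory=list)
    alerts: List[dict] = field(default_factory=list)
    benchmark_status: Optional[str] = None
    comparator_value: Optional[float] = None
    meta: Dict = field(default_factory=dict)


def ratio_value(defn: IndicatorDefinition, geo: str, year: int,
                numerator: float, denominator: float,
                category: Optional[str] = None,
                flags: Optional[List[str]] = None) -> IndicatorValue:
    """Build a value honoring the zero-denominator contract (undefined, not 0)."""
    undefined = denominator == 0
    value = None if undefined else numerator / denominator * SCALE_FACTORS[defn.scale]
    fl = list(flags or [])
    if undefined:
        fl.append("undefined:zero_denominator")
    return IndicatorValue(
        definition_id=defn.id, geo=geo, year=year, value=value,
        numerator=float(numerator), denominator=float(denominator),
        scale=defn.scale, category=category, undefined=undefined, flags=fl)


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def mhdi_band(value: float) -> str:
    """Band an MHDI value: <0.500 very low, then 0.100-wide bands to very high."""
    if not (0.0 <= value <= 1.0):
        raise DomainError(f"MHDI must lie in [0, 1], got {value}")
    if value < 0.500:
        return "very_low"
    if value < 0.600:
        return "low"
    if value < 0.700:
        return "medium"
    if value < 0.800:
        return "high"
    return "very_high"


def _known_mask(frame: pd.DataFrame, columns: Sequence[str]) -> pd.Series:
    mask = pd.Series(True, index=frame.index)
    for c in columns:
        mask &= frame[c].notna()
    return mask


def proportion_indicator(defn: IndicatorDefinition, frame: pd.DataFrame,
                         num_mask: pd.Series, needed: Sequence[str],
                         geo: str, year: int,
                         category: Optional[str] = None) -> IndicatorValue:
    """Share of records satisfying ``num_mask`` among records where all
    ``needed`` fields are present; exclusions are flagged, never dropped
    silently."""
    known = _known_mask(frame, needed)
    n_excluded = int((~known).sum())
    num = int((num_mask.fillna(False) & known).sum())
    den = int(known.sum())
    flags = [f"excluded_missing:{n_excluded}"] if n_excluded else []
    return ratio_value(defn, geo, year, num, den, category=category, flags=flags)


def mmr(deaths: pd.DataFrame, births: pd.DataFrame, geo: str, year: int,
        catalogue: Catalogue) -> List[IndicatorValue]:
    """Maternal mortality ratio plus the raw maternal-death count.

    Computed for every geography, however small; values resting on fewer than
    five deaths carry an instability flag instead of being suppressed.
    """
    n_mat = int((deaths["is_maternal_death"] == True).sum())  # noqa: E712
    n_lb = int(len(births))
    count_defn = catalogue.get("maternal_deaths_count")
    count_val = IndicatorValue(
        definition_id=count_defn.id, geo=geo, year=year, value=float(n_mat),
        numerator=float(n_mat), denominator=None, scale="count")
    defn = catalogue.get("mmr")
    val = ratio_value(defn, geo, year, n_mat, n_lb)
    if n_mat < MMR_INSTABILITY_DEATHS:
        val.flags.append(f"unstable:deaths<{MMR_INSTABILITY_DEATHS}")
    return [count_val, val]


def rate_indicator(defn: IndicatorDefinition, numerator: float,
                   population: Optional[float], geo: str, year: int,
                   flags: Optional[List[str]] = None) -> IndicatorValue:
    """Rate over an external population denominator; a missing population
    cell yields an undefined-flagged value."""
    fl = list(flags or [])
    if population is None:
        fl.append("undefined:missing_population")
        return IndicatorValue(definition_id=defn.id, geo=geo, year=year,
                              value=None, numerator=float(numerator),
                              denominator=None, scale=defn.scale,
                              undefined=True, flags=fl)
    return ratio_value(defn, geo, year, numerator, population, flags=fl)


def exclusive_sus(defn: IndicatorDefinition, population_f10_49: Optional[float],
                  beneficiaries: Optional[float], geo: str,
                  year: int) -> IndicatorValue:
    """Share of women 10-49 with no private health plan.  A beneficiary count
    above the population is a registry anomaly: capped (floor 0) and flagged."""
    if population_f10_49 is None or population_f10_49 == 0:
        return rate_indicator(defn, 0.0, None if population_f10_49 is None else 0.0,
                              geo, year)
    flags = []
    ben = beneficiaries if beneficiaries is not None else 0.0
    if beneficiaries is None:
        flags.append("beneficiaries_unavailable:assumed_0")
    if ben > population_f10_49:
        flags.append("anomaly:beneficiaries_exceed_population")
        ben = population_f10_49
    return ratio_value(defn, geo, year, population_f10_49 - ben,
                       population_f10_49, flags=flags)


@dataclass(frozen=True)
class AbortionCorrectionConfig:
    """Two-step correction for the unsafe-abortion estimate: subtract expected
    hospitalized spontaneous abortions, then inflate for induced abortions
    that never reach hospital."""

    spontaneous_fraction_of_live_births: float
    induced_not_hospitalized_multiplier: float

    def __post_init__(self):
        if self.spontaneous_fraction_of_live_births < 0:
            raise ConfigError("spontaneous fraction must be >= 0")
        if self.induced_not_hospitalized_multiplier < 1:
            raise ConfigError("multiplier must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "AbortionCorrectionConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(
            spontaneous_fraction_of_live_births=float(
                raw["spontaneous_fraction_of_live_births"]),
            induced_not_hospitalized_multiplier=float(
                raw["induced_not_hospitalized_multiplier"]))

    @classmethod
    def default(cls) -> "AbortionCorrectionConfig":
        ref = importlib.resources.files("matvig").joinpath(
            "data/abortion_correction.yaml")
        with importlib.resources.as_file(ref) as p:
            return cls.from_yaml(p)


def estimate_unsafe_abortions(n_abortion_admissions: int,
                              correction: AbortionCorrectionConfig,
                              population_f10_49: Optional[float],
                              n_live_births: int, geo: str, year: int,
                              catalogue: Catalogue) -> List[IndicatorValue]:
    """Unsafe-abortion rate (per 1,000 women 10-49) and ratio (per 100 LB).

    estimated UA = max(0, admissions - spontaneous expectation) x multiplier.
    The configuration used travels in the value metadata; there is no implicit
    default at call time.
    """
    if correction is None:
        raise ConfigError("abortion correction configuration is required "
                          "(no silent defaults)")
    spont = correction.spontaneous_fraction_of_live_births * n_live_births
    corrected = n_abortion_admissions - spont
    floored = corrected < 0
    ua = max(0.0, corrected) * correction.induced_not_hospitalized_multiplier
    flags = ["floor:admissions_below_spontaneous_expectation"] if floored else []
    meta = {
        "n_abortion_admissions": n_abortion_admissions,
        "spontaneous_expectation": spont,
        "multiplier": correction.induced_not_hospitalized_multiplier,
        "estimated_unsafe_abortions": ua,
    }
    rate = rate_indicator(catalogue.get("unsafe_abortion_rate"), ua,
                          population_f10_49, geo, year, flags=list(flags))
    ratio = ratio_value(catalogue.get("unsafe_abortion_ratio"), geo, year,
                        ua, n_live_births, flags=list(flags))
    rate.meta.update(meta)
    ratio.meta.update(meta)
    return [rate, ratio]


def median_displacement(births: pd.DataFrame, ref: ReferenceTables,
                        geo: str, year: int,
                        catalogue: Catalogue) -> List[IndicatorValue]:
    """Median km between residence and occurrence municipality, over births
    occurring OUTSIDE the mother's municipality of residence, stratified by
    the adult-ICU availability of the delivery service."""
    defn = catalogue.get("median_displacement_km")
    known = births["occurrence_muni"].notna() & births["residence_muni"].notna()
    out_of_muni = known & (births["occurrence_muni"] != births["residence_muni"])
    sub = births.loc[out_of_muni]

    dist_key = ref.distances.set_index(["muni_a", "muni_b"])["km"]
    fac = ref.facilities.set_index("facility_id")["has_adult_icu"]

    pairs = pd.MultiIndex.from_arrays(
        [sub["residence_muni"].astype(str), sub["occurrence_muni"].astype(str)])
    km = pd.Series(dist_key.reindex(pairs).to_numpy(), index=sub.index)
    has_icu = sub["facility_id"].map(fac)

    values = []
    n_no_dist = int(km.isna().sum())
    n_no_fac = int((has_icu.isna() & km.notna()).sum())
    for cat, want_icu in (("with_adult_icu", True), ("without_adult_icu", False)):
        stratum = km[(has_icu == want_icu).fillna(False) & km.notna()]
        flags = []
        if n_no_dist:
            flags.append(f"excluded_no_distance:{n_no_dist}")
        if n_no_fac:
            flags.append(f"excluded_unknown_facility:{n_no_fac}")
        if len(stratum) == 0:
            values.append(IndicatorValue(
                definition_id=defn.id, geo=geo, year=year, value=None,
                numerator=None, denominator=float(len(stratum)), scale="km",
                category=cat, undefined=True,
                flags=flags + ["undefined:no_out_of_municipality_births"]))
        else:
            values.append(IndicatorValue(
                definition_id=defn.id, geo=geo, year=year,
                value=float(np.median(stratum)), numerator=None,
                denominator=float(len(stratum)), scale="km", category=cat,
                flags=flags, meta={"n_births": int(len(stratum))}))
    return values


# ---------------------------------------------------------------------------
# Compositions
# ---------------------------------------------------------------------------

AGE_BANDS = (("<20", 0, 19), ("20-34", 20, 34), ("35+", 35, 200))


def _composition(defn: IndicatorDefinition, frame: pd.DataFrame,
                 masks: Dict[str, pd.Series], needed: Sequence[str],
                 geo: str, year: int) -> List[IndicatorValue]:
    known = _known_mask(frame, needed)
    n_excluded = int((~known).sum())
    den = int(known.sum())
    flags = [f"excluded_missing:{n_excluded}"] if n_excluded else []
    out = []
    for cat, mask in masks.items():
        num = int((mask.fillna(False) & known).sum())
        out.append(ratio_value(defn, geo, year, num, den, category=cat,
                               flags=list(flags)))
    return out


# ---------------------------------------------------------------------------
# Panel data container and the per-unit driver
# ---------------------------------------------------------------------------

@dataclass
class PanelData:
    """Everything the engine needs for one run: the geographic hierarchy, the
    three microdata frames and the reference tables."""

    hierarchy: GeoHierarchy
    births: pd.DataFrame
    deaths: pd.DataFrame
    admissions: pd.DataFrame
    ref: ReferenceTables

    FILES = {
        "births": "live_births.csv",
        "deaths": "deaths.csv",
        "admissions": "hospitalizations.csv",
    }

    @classmethod
    def load(cls, directory, schema_maps: Optional[Dict[str, SchemaMap]] = None,
             validate_geo: bool = True) -> "PanelData":
        """Load a panel directory (hierarchy.csv, the three microdata files in
        the given dialects — canonical by default — and ``ref/``)."""
        directory = Path(directory)
        hierarchy = GeoHierarchy.load(directory / "hierarchy.csv")
        kinds = {"births": "live_birth", "deaths": "maternal_death",
                 "admissions": "hospitalization"}
        frames = {}
        for attr, fname in cls.FILES.items():
            smap = (schema_maps or {}).get(attr) or canonical_schema_map(kinds[attr])
            res = load_table(directory / fname, smap, kinds[attr],
                             hierarchy=hierarchy if validate_geo else None)
            frames[attr] = res.records
        ref = ReferenceTables.load(directory / "ref")
        return cls(hierarchy=hierarchy, ref=ref, **frames)

    def years(self) -> List[int]:
        return sorted(set(self.births["year"].dropna().astype(int)))

    def slice(self, geo: str, year: int):
        munis = set(self.hierarchy.descendants(geo, "municipality"))
        b = self.births[(self.births["year"] == year)
                        & self.births["residence_muni"].isin(munis)]
        d = self.deaths[(self.deaths["year"] == year)
                        & self.deaths["residence_muni"].isin(munis)]
        a = self.admissions[(self.admissions["year"] == year)
                            & self.admissions["residence_muni"].isin(munis)]
        return munis, b, d, a


def _pop_sum(df: pd.DataFrame, munis, year: int, value_col: str,
             extra_mask=None) -> Optional[float]:
    sel = df[(df["geo"].isin(munis)) & (df["year"] == year)]
    if extra_mask is not None:
        sel = sel[extra_mask(sel)]
    if sel.empty:
        return None
    return float(sel[value_col].sum())


def compute_unit(data: PanelData, geo: str, year: int,
                 catalogue: Optional[Catalogue] = None,
                 smm_config: Optional[SMMCodeConfig] = None,
                 abortion_config: Optional[AbortionCorrectionConfig] = None
                 ) -> List[IndicatorValue]:
    """Compute every block 1-6 indicator for one geographic unit and year,
    directly from the records pooled over its member municipalities."""
    catalogue = catalogue or load_catalogue()
    smm_config = smm_config or SMMCodeConfig.default()
    if abortion_config is None:
        raise ConfigError("abortion correction configuration is required")

    level = data.hierarchy.level_of(geo)
    munis, b, d, a = data.slice(geo, year)
    values: List[IndicatorValue] = []

    pop = data.ref.population
    f10_19 = _pop_sum(pop, munis, year, "count",
                      lambda s: (s["sex"] == "F") & (s["age_band"] == "10-19"))
    f10_49 = _pop_sum(pop, munis, year, "count",
                      lambda s: (s["sex"] == "F") & s["age_band"].isin(F_10_49_BANDS))
    total_pop = _pop_sum(pop, munis, year, "count")
    beneficiaries = _pop_sum(data.ref.beneficiaries, munis, year,
                             "beneficiaries_f10_49")
    fhs_covered = _pop_sum(data.ref.fhs, munis, year, "fhs_covered_population")
    syphilis = _pop_sum(data.ref.syphilis, munis, year,
                        "congenital_syphilis_cases")

    # --- block 1 -------------------------------------------------------------
    mhdi_defn = catalogue.get("mhdi")
    if level == "municipality":
        row = data.ref.mhdi[data.ref.mhdi["geo"] == geo]
        if row.empty:
            values.append(IndicatorValue(mhdi_defn.id, geo, year, None,
                                         scale="index", undefined=True,
                                         flags=["undefined:mhdi_unavailable"]))
        else:
            v = float(row["mhdi"].iloc[0])
            values.append(IndicatorValue(mhdi_defn.id, geo, year, v,
                                         scale="index",
                                         meta={"band": mhdi_band(v)}))
    else:
        values.append(IndicatorValue(mhdi_defn.id, geo, year, None,
                                     scale="index", undefined=True,
                                     flags=["not_applicable_above_municipality"]))

    age = b["maternal_age"]
    values += _composition(
        catalogue.get("lb_by_maternal_age"), b,
        {cat: (age >= lo) & (age <= hi) for cat, lo, hi in AGE_BANDS},
        ["maternal_age"], geo, year)
    values += _composition(
        catalogue.get("lb_by_race_color"), b,
        {cat: b["race_color"] == cat
         for cat in catalogue.get("lb_by_race_color").categories},
        ["race_color"], geo, year)
    values += _composition(
        catalogue.get("lb_by_education"), b,
        {cat: b["education"] == cat
         for cat in catalogue.get("lb_by_education").categories},
        ["education"], geo, year)
    values.append(exclusive_sus(catalogue.get("exclusive_sus_pct"), f10_49,
                                beneficiaries, geo, year))
    values.append(rate_indicator(catalogue.get("fhs_coverage_pct"),
                                 fhs_covered or 0.0, total_pop, geo, year))

    # --- block 2 -------------------------------------------------------------
    n_u20 = int(((age < 20) & age.notna()).sum())
    values.append(rate_indicator(catalogue.get("adolescent_fertility_rate"),
                                 n_u20, f10_19, geo, year))
    parity = b["prior_vaginal_births"] + b["prior_cesarean_births"]
    values.append(proportion_indicator(
        catalogue.get("multiparity_pct"), b, parity >= 4,
        ["prior_vaginal_births", "prior_cesarean_births"], geo, year))
    n_abortion_adm = int((a["admission_type"] == "abortion").sum())
    values += estimate_unsafe_abortions(n_abortion_adm, abortion_config,
                                        f10_49, len(b), geo, year, catalogue)

    # --- block 3 -------------------------------------------------------------
    visits = b["prenatal_visits"]
    values.append(proportion_indicator(catalogue.get("prenatal_coverage_pct"),
                                       b, visits >= 1, ["prenatal_visits"],
                                       geo, year))
    values.append(proportion_indicator(
        catalogue.get("prenatal_early_start_pct"), b,
        b["prenatal_start_trimester"] == 1, ["prenatal_start_trimester"],
        geo, year))
    values.append(proportion_indicator(
        catalogue.get("prenatal_8plus_visits_pct"), b, visits >= 8,
        ["prenatal_visits"], geo, year))
    values.append(ratio_value(catalogue.get("congenital_syphilis_rate"),
                              geo, year, syphilis or 0.0, len(b)))

    # --- block 4 -------------------------------------------------------------
    values.append(proportion_indicator(
        catalogue.get("cesarean_pct"), b, b["delivery_mode"] == "cesarean",
        ["delivery_mode"], geo, year))

    groups = robson_mod.classify_frame(b)
    dist = robson_mod.robson_distribution(b, groups)
    n_classified = int(dist["n"].sum())
    n_unclassifiable = int(len(b) - n_classified)
    robson_flags = ([f"unclassifiable:{n_unclassifiable}"]
                    if n_unclassifiable else [])
    size_defn = catalogue.get("robson_group_size_pct")
    rate_defn = catalogue.get("robson_group_cesarean_pct")
    contrib_defn = catalogue.get("robson_group_contribution_pct")
    total_cs = int(dist["n_cesarean"].sum())
    for g in range(1, 11):
        row = dist.loc[g]
        cat = str(g)
        values.append(ratio_value(size_defn, geo, year, int(row["n"]),
                                  n_classified, category=cat,
                                  flags=list(robson_flags)))
        values.append(ratio_value(rate_defn, geo, year, int(row["n_cesarean"]),
                                  int(row["n"]), category=cat,
                                  flags=list(robson_flags)))
        values.append(ratio_value(contrib_defn, geo, year,
                                  int(row["n_cesarean"]), total_cs,
                                  category=cat, flags=list(robson_flags)))

    in_muni = b["occurrence_muni"] == b["residence_muni"]
    values += _composition(
        catalogue.get("births_by_place_pct"), b,
        {"in_municipality": in_muni, "out_of_municipality": ~in_muni},
        ["occurrence_muni"], geo, year)
    values += median_displacement(b, data.ref, geo, year, catalogue)

    # --- block 5 -------------------------------------------------------------
    ga = b["gestational_age_weeks"]
    values.append(proportion_indicator(catalogue.get("low_birthweight_pct"), b,
                                       b["birthweight_g"] < 2500,
                                       ["birthweight_g"], geo, year))
    values.append(proportion_indicator(catalogue.get("preterm_pct"), b,
                                       ga < 37, ["gestational_age_weeks"],
                                       geo, year))
    values.append(proportion_indicator(catalogue.get("early_term_pct"), b,
                                       ga.isin([37, 38]),
                                       ["gestational_age_weeks"], geo, year))

    # --- block 6 -------------------------------------------------------------
    values += mmr(d, b, geo, year, catalogue)
    mat = d[(d["is_maternal_death"] == True)]  # noqa: E712
    values.append(proportion_indicator(
        catalogue.get("maternal_direct_cause_pct"), mat,
        mat["obstetric_cause_class"] == "direct", ["obstetric_cause_class"],
        geo, year))
    direct = mat[mat["obstetric_cause_class"] == "direct"]
    values += _composition(
        catalogue.get("maternal_specific_cause_pct"), direct,
        {cat: direct["specific_cause"] == cat
         for cat in catalogue.get("maternal_specific_cause_pct").categories},
        ["specific_cause"], geo, year)

    smm_flags, _smm_skipped = smm_mod.classify_frame(a, smm_config)
    n_adm = int(len(smm_flags))
    n_cases = int(smm_flags["is_case"].sum())
    values.append(ratio_value(catalogue.get("smm_pct"), geo, year,
                              n_cases, n_adm))
    case_rows = smm_flags[smm_flags["is_case"]]
    cause_defn = catalogue.get("smm_cause_pct")
    for cat in cause_defn.categories:
        num = int(case_rows[f"cause_{cat}"].sum())
        values.append(ratio_value(cause_defn, geo, year, num, n_cases,
                                  category=cat))
    mgmt_defn = catalogue.get("smm_management_pct")
    for cat in mgmt_defn.categories:
        num = int(case_rows[f"mgmt_{cat}"].sum())
        values.append(ratio_value(mgmt_defn, geo, year, num, n_cases,
                                  category=cat))

    for v in values:
        v.geo_level = level
    return values


def values_to_frame(values: Sequence[IndicatorValue]) -> pd.DataFrame:
    """Tidy export: one row per value with components, flags and benchmark."""
    rows = []
    for v in values:
        rows.append({
            "indicator_id": v.definition_id,
            "category": v.category or "",
            "geo_code": v.geo,
            "geo_level": v.geo_level or "",
            "year": v.year,
            "numerator": v.numerator,
            "denominator": v.denominator,
            "value": v.value,
            "scale": v.scale,
            "undefined": v.undefined,
            "status": v.benchmark_status or "",
            "comparator_value": v.comparator_value,
            "flags": ";".join(v.flags),
            "alerts": ";".join(al["message"] for al in v.alerts),
        })
    return pd.DataFrame(rows)
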