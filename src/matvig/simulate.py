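"""Synthetic world generator.

Produces a complete, internally consistent synthetic panel — geographic
hierarchy, the three microdata record kinds and every reference table — from
user-controlled true parameters, so the whole engine is testable without any
external data.  The generator is the study-conditions oracle: a truth ledger
records the exact generating parameter for every municipality, and the
downstream indicators are expected to recover those values up to sampling
noise.

Design highlights:

- Per-municipality heterogeneity: each national rate is jittered per
  municipality with a Beta distribution centred on the national value
  (concentration ``beta_concentration``), so aggregation has real
  between-unit variance while national estimates stay close to the target.
- Obstetric profiles are generated *by Robson group*: a mix vector decides
  each birth's group, the profile generator emits fields that classify back
  into exactly that group, and per-group cesarean propensities are rescaled
  on the logit scale so the overall cesarean rate hits the configured value
  in expectation.
- Severe-morbidity cases are created by injecting cause-specific ICD-10
  codes from the shipped code list into admissions, so the classifier's
  recall and false-positive rate on synthetic data are 1 and 0 by
  construction.
- Missingness is missing-completely-at-random per field.

Everything is driven by one ``numpy`` generator seeded from the config, and
identical configs produce byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from .errors import ConfigError
from .geo import GeoHierarchy, GeoUnit
from .indicators import PanelData
from .io import ReferenceTables, write_table
from . import robson as robson_mod

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


class TrueRates(BaseModel):
    """National generating parameters (shares in [0,1] unless stated)."""

    cesarean_rate: float = 0.56
    preterm_rate: float = 0.11
    early_term_rate: float = 0.28
    low_birthweight_rate: float = 0.085
    mmr_per_100k: float = 60.0
    direct_cause_share: float = 0.65
    smm_share_of_admissions: float = 0.03
    abortion_admission_share: float = 0.06
    adolescent_fertility_per_1000: float = 50.0
    multiparity_share: float = 0.06
    prenatal_coverage: float = 0.97
    early_start_share: float = 0.70
    seven_plus_visits_share: float = 0.55
    exclusive_sus_share: float = 0.75
    fhs_coverage: float = 0.65
    out_of_muni_birth_share: float = 0.25

    @field_validator("*")
    @classmethod
    def _bounds(cls, v, info):
        if info.field_name in ("mmr_per_100k", "adolescent_fertility_per_1000"):
            if v < 0:
                raise ValueError(f"{info.field_name} must be >= 0")
            return v
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{info.field_name} must lie in [0, 1]")
        return v


#: default Robson case-mix (probability of each group 1..10); roughly a
#: middle-income country profile with large groups 1-3 and a sizeable group 5
DEFAULT_ROBSON_MIX = (0.25, 0.17, 0.23, 0.08, 0.12,
                      0.04, 0.02, 0.02, 0.01, 0.06)

DEFAULT_MISSINGNESS = {
    "maternal_age": 0.002,
    "race_color": 0.03,
    "education": 0.035,
    "presentation": 0.01,
    "prior_vaginal_births": 0.02,
    "prior_cesarean_births": 0.02,
    "gestational_age_weeks": 0.015,
    "prenatal_visits": 0.01,
    "prenatal_start_trimester": 0.03,
    "birthweight_g": 0.005,
}


class SimulationConfig(BaseModel):
    seed: int = 0
    n_municipalities: int = Field(default=50, ge=1)
    births_per_muni: int = Field(default=2000, ge=1)
    regions_per_state: int = Field(default=2, ge=1)
    states_per_macro: int = Field(default=2, ge=1)
    n_macro_regions: int = Field(default=2, ge=1)
    years: Tuple[int, ...] = (2015,)
    true_rates: TrueRates = Field(default_factory=TrueRates)
    robson_mix: Tuple[float, ...] = DEFAULT_ROBSON_MIX
    missingness: Dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_MISSINGNESS))
    beta_concentration: float = Field(default=5000.0, gt=0)

    @field_validator("robson_mix")
    @classmethod
    def _mix_sums_to_one(cls, v):
        if len(v) != 10:
            raise ValueError("robson_mix needs exactly 10 entries")
        if any(p < 0 for p in v):
            raise ValueError("robson_mix entries must be >= 0")
        if abs(sum(v) - 1.0) > 1e-9:
            raise ValueError(f"robson_mix must sum to 1, got {sum(v)!r}")
        return v

    @field_validator("missingness")
    @classmethod
    def _missingness_probs(cls, v):
        for k, p in v.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"missingness[{k}] must lie in [0, 1]")
        return v

    def model_post_init(self, __context):
        # the preterm share cannot be below the group-10 share: group 10 is
        # by definition single cephalic preterm
        mix10 = self.robson_mix[9]
        mix6to9 = sum(self.robson_mix[5:9])
        pt = self.true_rates.preterm_rate
        if pt < mix10 - 1e-9 or pt > mix10 + mix6to9 + 1e-9:
            raise ConfigError(
                f"preterm_rate {pt} incompatible with robson_mix: feasible "
                f"range is [{mix10}, {mix10 + mix6to9}]")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            return cls(**raw)
        except (ValueError, TypeError) as exc:
            raise ConfigError(str(exc)) from exc


# ---------------------------------------------------------------------------
# Robson machinery
# ---------------------------------------------------------------------------

#: baseline within-group cesarean propensities before logit rescaling
BASE_GROUP_CS = {1: 0.30, 2: 0.55, 3: 0.08, 4: 0.35, 5: 0.78,
                 6: 0.88, 7: 0.88, 8: 0.82, 9: 0.97, 10: 0.42}


def _logit(p: float) -> float:
    p = min(max(p, 1e-9), 1 - 1e-9)
    return math.log(p / (1 - p))


def _sigmoid(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def calibrate_group_cs(mix, target: float) -> Dict[int, float]:
    """Shift the baseline group propensities on the logit scale so the
    mix-weighted overall cesarean rate equals ``target`` exactly."""
    if target <= 0:
        return {g: 0.0 for g in BASE_GROUP_CS}
    if target >= 1:
        return {g: 1.0 for g in BASE_GROUP_CS}
    logits = {g: _logit(p) for g, p in BASE_GROUP_CS.items()}

    def expected(delta):
        return sum(mix[g - 1] * _sigmoid(logits[g] + delta)
                   for g in BASE_GROUP_CS)

    lo, hi = -40.0, 40.0
    for _ in range(100):
        mid = (lo + hi) / 2
        if expected(mid) < target:
            lo = mid
        else:
            hi = mid
    delta = (lo + hi) / 2
    return {g: _sigmoid(logits[g] + delta) for g in BASE_GROUP_CS}


def generate_robson_profile(group_target: int, rng: np.random.Generator) -> dict:
    """Emit obstetric fields that classify into exactly ``group_target``."""
    if not 1 <= group_target <= 10:
        raise ConfigError(f"group_target must be 1..10, got {group_target}")
    g = group_target
    term_ga = int(rng.integers(37, 42))
    preterm_ga = int(rng.integers(26, 37))
    any_ga = int(rng.integers(30, 42))
    profile = dict(plurality="single", presentation="cephalic",
                   gestational_age_weeks=term_ga, prior_cesarean_births=0,
                   prior_vaginal_births=0, labour_onset="spontaneous")
    if g == 8:
        profile.update(plurality="multiple", gestational_age_weeks=any_ga)
    elif g == 9:
        profile.update(presentation="transverse_oblique",
                       gestational_age_weeks=any_ga)
    elif g == 6:
        profile.update(presentation="breech", gestational_age_weeks=any_ga)
    elif g == 7:
        profile.update(presentation="breech", gestational_age_weeks=any_ga,
                       prior_vaginal_births=int(rng.integers(1, 4)),
                       prior_cesarean_births=int(rng.integers(0, 2)))
    elif g == 10:
        profile.update(gestational_age_weeks=preterm_ga,
                       labour_onset=str(rng.choice(
                           ["spontaneous", "induced", "cesarean_before_labour"])))
    elif g == 5:
        profile.update(prior_cesarean_births=int(rng.integers(1, 3)),
                       prior_vaginal_births=int(rng.integers(0, 3)),
                       labour_onset=str(rng.choice(
                           ["spontaneous", "induced", "cesarean_before_labour"])))
    elif g in (1, 2):
        onset = "spontaneous" if g == 1 else str(
            rng.choice(["induced", "cesarean_before_labour"]))
        profile.update(labour_onset=onset)
    else:  # 3, 4
        onset = "spontaneous" if g == 3 else str(
            rng.choice(["induced", "cesarean_before_labour"]))
        profile.update(prior_vaginal_births=int(rng.integers(1, 5)),
                       labour_onset=onset)
    return profile


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def _beta_around(rng, rate: float, kappa: float) -> float:
    """Beta draw with mean ``rate`` and concentration ``kappa``; degenerate
    rates pass through unchanged."""
    if rate <= 0.0 or rate >= 1.0:
        return float(rate)
    return float(rng.beta(rate * kappa, (1 - rate) * kappa))


def _weighted_choice(rng, n, values, weights):
    w = np.asarray(weights, dtype=float)
    return rng.choice(np.asarray(values), size=n, p=w / w.sum())


_PRETERM_WEEKS = np.arange(22, 37)
_PRETERM_W = np.array([1, 1, 2, 2, 3, 4, 5, 7, 9, 11, 13, 14, 14, 12, 12],
                      dtype=float)

_SMM_CAUSE_CODES = {
    "hypertension": ["O141", "O150", "O151", "O159"],
    "hemorrhage": ["O441", "O459", "O460", "O670", "O720", "O721"],
    "infection": ["O85", "O860", "A419"],
}
_BENIGN_DELIVERY_DX = ["O80", "O800", "Z370"]
_BENIGN_ABORTION_DX = ["O039", "O069"]
_BENIGN_PROC = "0310010039"
_SURGICAL_PROCS = ["0409060160", "0407040242"]


@dataclass
class World:
    """The full synthetic panel plus its truth ledger."""

    config: SimulationConfig
    hierarchy: GeoHierarchy
    births: pd.DataFrame
    deaths: pd.DataFrame
    admissions: pd.DataFrame
    ref: ReferenceTables
    truth: pd.DataFrame   # columns: geo, parameter, value

    def to_panel_data(self) -> PanelData:
        return PanelData(hierarchy=self.hierarchy, births=self.births,
                         deaths=self.deaths, admissions=self.admissions,
                         ref=self.ref)

    def truth_value(self, geo: str, parameter: str) -> float:
        t = self.truth
        sel = t[(t["geo"] == geo) & (t["parameter"] == parameter)]
        return float(sel["value"].iloc[0])

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.hierarchy.write(directory / "hierarchy.csv")
        write_table(self.births, directory / "live_births.csv", "live_birth")
        write_table(self.deaths, directory / "deaths.csv", "maternal_death")
        write_table(self.admissions, directory / "hospitalizations.csv",
                    "hospitalization")
        self.ref.write(directory / "ref")
        self.truth.to_csv(directory / "truth.csv", index=False)
        with open(directory / "config.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.config.model_dump(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Hierarchy generation
# ---------------------------------------------------------------------------

def _build_hierarchy(config: SimulationConfig,
                     rng: np.random.Generator) -> Tuple[GeoHierarchy, List[str], Dict[str, List[str]]]:
    units = [GeoUnit("BR", "Country", "country", None)]
    region_codes: List[str] = []
    for m in range(1, config.n_macro_regions + 1):
        mc = f"MA{m}"
        units.append(GeoUnit(mc, f"Macro-region {m}", "macro_region", "BR"))
        for s in range(1, config.states_per_macro + 1):
            sc = f"ST{m}{s}"
            units.append(GeoUnit(sc, f"State {m}{s}", "state", mc))
            for r in range(1, config.regions_per_state + 1):
                rc = f"RE{m}{s}{r}"
                units.append(GeoUnit(rc, f"Health region {m}{s}{r}",
                                     "health_region", sc))
                region_codes.append(rc)

    munis: List[str] = []
    region_members: Dict[str, List[str]] = {rc: [] for rc in region_codes}
    for j in range(config.n_municipalities):
        rc = region_codes[j % len(region_codes)]
        serial = len(region_members[rc]) + 1
        code = f"{rc[2:]}{serial:03d}"          # e.g. region RE112 -> 112001
        lat = float(-25.0 + rng.uniform(0, 8.0))
        lon = float(-52.0 + rng.uniform(0, 8.0))
        units.append(GeoUnit(code, f"Municipality {code}", "municipality",
                             rc, lat=lat, lon=lon))
        munis.append(code)
        region_members[rc].append(code)
    return GeoHierarchy(units), munis, region_members


def _haversine_km(lat1, lon1, lat2, lon2) -> float:
    r = 6371.0
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dp, dl = math.radians(lat2 - lat1), math.radians(lon2 - lon1)
    a = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * r * math.asin(math.sqrt(a))


# ---------------------------------------------------------------------------
# Main generator
# ---------------------------------------------------------------------------

_MUNI_RATE_PARAMS = (
    "cesarean_rate", "preterm_rate", "early_term_rate", "low_birthweight_rate",
    "direct_cause_share", "smm_share_of_admissions", "abortion_admission_share",
    "multiparity_share", "prenatal_coverage", "early_start_share",
    "seven_plus_visits_share", "exclusive_sus_share", "fhs_coverage",
    "out_of_muni_birth_share",
)

_SHARE_U20 = 0.135        # share of live births to women under 20
_NULLIPAROUS_IN_8_9_10 = 0.4


def generate_world(config: SimulationConfig) -> World:
    """Generate the complete synthetic panel for the configured conditions."""
    rng = np.random.default_rng(config.seed)
    rates = config.true_rates
    kappa = config.beta_concentration
    mix = np.asarray(config.robson_mix, dtype=float)

    hierarchy, munis, region_members = _build_hierarchy(config, rng)

    # municipality-level realized parameters
    muni_rates: Dict[str, Dict[str, float]] = {}
    for muni in munis:
        mr = {p: _beta_around(rng, getattr(rates, p), kappa)
              for p in _MUNI_RATE_PARAMS}
        mr["mmr_per_100k"] = _beta_around(rng, rates.mmr_per_100k / 1e5,
                                          kappa) * 1e5
        mr["share_u20"] = _beta_around(rng, _SHARE_U20, kappa)
        mr["mhdi"] = 0.45 + 0.4 * float(rng.beta(5.0, 3.0))
        mr["sinasc_coverage"] = 0.90 + 0.09 * float(rng.beta(6.0, 2.0))
        mr["adolescent_fertility_per_1000"] = rates.adolescent_fertility_per_1000
        muni_rates[muni] = mr

    births_parts, deaths_parts, adm_parts = [], [], []
    pop_rows, ben_rows, fhs_rows, est_rows, inv_rows, syph_rows = \
        [], [], [], [], [], []
    mhdi_rows, fac_rows = [], []

    hubs = {rc: members[0] for rc, members in region_members.items() if members}
    muni_region = {m: rc for rc, members in region_members.items()
                   for m in members}

    # facilities: every municipality has a basic maternity; region hubs also
    # have a higher-complexity service with adult ICU beds
    for muni in munis:
        fac_rows.append({"facility_id": f"F{muni}A", "muni": muni,
                         "has_adult_icu": False})
        if muni == hubs.get(muni_region[muni]):
            fac_rows.append({"facility_id": f"F{muni}B", "muni": muni,
                             "has_adult_icu": True})
    facilities = pd.DataFrame(fac_rows)
    has_icu_muni = {m: hubs.get(muni_region[m]) == m for m in munis}

    for muni in munis:
        mhdi_rows.append({"geo": muni, "mhdi": round(muni_rates[muni]["mhdi"], 3)})

    for year in config.years:
        for muni in munis:
            mr = muni_rates[muni]
            out = _generate_municipality_year(
                rng, config, mix, muni, year, mr, hierarchy, munis,
                region_members, muni_region, hubs, has_icu_muni)
            births_parts.append(out["births"])
            deaths_parts.append(out["deaths"])
            adm_parts.append(out["admissions"])
            pop_rows.extend(out["pop_rows"])
            ben_rows.append(out["ben_row"])
            fhs_rows.append(out["fhs_row"])
            est_rows.append(out["est_row"])
            inv_rows.append(out["inv_row"])
            syph_rows.append(out["syph_row"])

    births = pd.concat(births_parts, ignore_index=True)
    deaths = pd.concat(deaths_parts, ignore_index=True) if deaths_parts else \
        pd.DataFrame()
    admissions = pd.concat(adm_parts, ignore_index=True)

    births = _apply_missingness(births, config.missingness, rng)
    from .io import canonicalize_dtypes
    births = canonicalize_dtypes(births, "live_birth")
    deaths = canonicalize_dtypes(deaths, "maternal_death")
    admissions = canonicalize_dtypes(admissions, "hospitalization")

    # distances (all ordered pairs, symmetric by construction)
    coords = {m: (hierarchy.unit(m).lat, hierarchy.unit(m).lon) for m in munis}
    dist_rows = []
    for a in munis:
        for b in munis:
            km = 0.0 if a == b else round(_haversine_km(*coords[a], *coords[b]), 1)
            dist_rows.append({"muni_a": a, "muni_b": b, "km": km})

    ref = ReferenceTables(
        population=pd.DataFrame(pop_rows),
        beneficiaries=pd.DataFrame(ben_rows),
        fhs=pd.DataFrame(fhs_rows),
        mhdi=pd.DataFrame(mhdi_rows),
        distances=pd.DataFrame(dist_rows),
        facilities=facilities,
        estimates=pd.DataFrame(est_rows),
        investigation=pd.DataFrame(inv_rows),
        syphilis=pd.DataFrame(syph_rows),
    )

    truth_rows = []
    for muni in munis:
        for p, v in sorted(muni_rates[muni].items()):
            truth_rows.append({"geo": muni, "parameter": p, "value": v})
    national = rates.model_dump()
    national["share_u20"] = _SHARE_U20
    for p, v in sorted(national.items()):
        truth_rows.append({"geo": "BR", "parameter": p, "value": v})
    truth = pd.DataFrame(truth_rows)

    return World(config=config, hierarchy=hierarchy, births=births,
                 deaths=deaths, admissions=admissions, ref=ref, truth=truth)


def _generate_municipality_year(rng, config, mix, muni, year, mr, hierarchy,
                                munis, region_members, muni_region, hubs,
                                has_icu_muni) -> dict:
    n = config.births_per_muni
    rates = config.true_rates

    group = rng.choice(np.arange(1, 11), size=n, p=mix)
    p_cs = calibrate_group_cs(mix, mr["cesarean_rate"])
    cs = rng.random(n) < np.array([p_cs[g] for g in group])

    onset = _draw_onset(rng, group, cs)
    pvb, pcs, total_prior = _draw_parity(rng, group, mix, mr["multiparity_share"])
    ga = _draw_ga(rng, group, mix, mr["preterm_rate"], mr["early_term_rate"])
    plurality = np.where(group == 8, "multiple", "single")
    presentation = np.select(
        [group == 9, np.isin(group, (6, 7))],
        ["transverse_oblique", "breech"], default="cephalic")

    age = _draw_age(rng, n, mr["share_u20"])
    race = _weighted_choice(rng, n,
                            ["white", "brown", "black", "indigenous", "asian"],
                            [0.37, 0.47, 0.12, 0.012, 0.028])
    edu = _weighted_choice(rng, n, ["none", "1-3", "4-7", "8-11", "12+"],
                           [0.02, 0.06, 0.22, 0.50, 0.20])

    visits, trimester = _draw_prenatal(rng, n, mr["prenatal_coverage"],
                                       mr["seven_plus_visits_share"],
                                       mr["early_start_share"])
    weight = _draw_birthweight(rng, ga, mr["low_birthweight_rate"],
                               rates.preterm_rate)

    occurrence, facility = _draw_occurrence(rng, n, muni,
                                            mr["out_of_muni_birth_share"],
                                            region_members, muni_region, hubs,
                                            has_icu_muni)

    births = pd.DataFrame({
        "record_id": [f"LB{year}{muni}{i:05d}" for i in range(n)],
        "year": year,
        "residence_muni": muni,
        "occurrence_muni": occurrence,
        "facility_id": facility,
        "maternal_age": age,
        "race_color": race,
        "education": edu,
        "prior_vaginal_births": pvb,
        "prior_cesarean_births": pcs,
        "plurality": plurality,
        "presentation": presentation,
        "gestational_age_weeks": ga,
        "labour_onset": onset,
        "delivery_mode": np.where(cs, "cesarean", "vaginal"),
        "prenatal_visits": visits,
        "prenatal_start_trimester": trimester,
        "birthweight_g": weight,
    })
    for col in ("maternal_age", "prior_vaginal_births", "prior_cesarean_births",
                "gestational_age_weeks", "birthweight_g"):
        births[col] = births[col].astype("Int64")
    births["prenatal_visits"] = pd.array(
        [pd.NA if v < 0 else v for v in visits], dtype="Int64")
    births["prenatal_start_trimester"] = pd.array(
        [pd.NA if t < 0 else t for t in trimester], dtype="Int64")

    public = rng.random(n) < mr["exclusive_sus_share"]

    deaths = _generate_deaths(rng, config, muni, year, n, mr)
    admissions = _generate_admissions(rng, config, muni, year, births, public, mr)

    # reference tables ------------------------------------------------------
    f10_19 = max(1, round(n * mr["share_u20"] * 1000.0
                          / mr["adolescent_fertility_per_1000"]))
    f10_49 = max(f10_19 + 1, round(n / 0.06))   # general fertility ~60/1,000
    rest = f10_49 - f10_19
    pop_rows = [
        {"geo": muni, "year": year, "sex": "F", "age_band": "0-9",
         "count": round(n * 1.9)},
        {"geo": muni, "year": year, "sex": "F", "age_band": "10-19",
         "count": f10_19},
        {"geo": muni, "year": year, "sex": "F", "age_band": "20-29",
         "count": round(rest * 0.40)},
        {"geo": muni, "year": year, "sex": "F", "age_band": "30-39",
         "count": round(rest * 0.32)},
        {"geo": muni, "year": year, "sex": "F", "age_band": "40-49",
         "count": rest - round(rest * 0.40) - round(rest * 0.32)},
        {"geo": muni, "year": year, "sex": "F", "age_band": "50+",
         "count": round(f10_49 * 0.55)},
        {"geo": muni, "year": year, "sex": "M", "age_band": "0-9",
         "count": round(n * 1.95)},
        {"geo": muni, "year": year, "sex": "M", "age_band": "10-49",
         "count": round(f10_49 * 0.97)},
        {"geo": muni, "year": year, "sex": "M", "age_band": "50+",
         "count": round(f10_49 * 0.50)},
    ]
    total_pop = sum(r["count"] for r in pop_rows)
    ben_row = {"geo": muni, "year": year,
               "beneficiaries_f10_49": round((1 - mr["exclusive_sus_share"])
                                             * f10_49)}
    fhs_row = {"geo": muni, "year": year,
               "fhs_covered_population": round(mr["fhs_coverage"] * total_pop)}
    est_row = {"geo": muni, "year": year,
               "estimated_births": round(n / mr["sinasc_coverage"]),
               "estimated_deaths": max(len(deaths),
                                       round(len(deaths) / 0.95))}
    n_mat = int((deaths["is_maternal_death"] == True).sum()) if len(deaths) \
        else 0  # noqa: E712
    n_mat_inv = int(((deaths["is_maternal_death"] == True)  # noqa: E712
                     & (deaths["investigated"] == True)).sum()) \
        if len(deaths) else 0
    inv_row = {"geo": muni, "year": year,
               "wca_deaths_total": int(len(deaths)),
               "wca_deaths_investigated":
                   int((deaths["investigated"] == True).sum())  # noqa: E712
                   if len(deaths) else 0,
               "maternal_deaths_total": n_mat,
               "maternal_deaths_investigated": n_mat_inv}
    syph_row = {"geo": muni, "year": year,
                "congenital_syphilis_cases": int(rng.poisson(n * 0.007))}

    return {"births": births, "deaths": deaths, "admissions": admissions,
            "pop_rows": pop_rows, "ben_row": ben_row, "fhs_row": fhs_row,
            "est_row": est_row, "inv_row": inv_row, "syph_row": syph_row}


def _draw_onset(rng, group, cs):
    n = len(group)
    onset = np.full(n, "spontaneous", dtype=object)
    u = rng.random(n)
    m24 = np.isin(group, (2, 4))
    onset[m24 & cs & (u < 0.55)] = "cesarean_before_labour"
    onset[m24 & cs & (u >= 0.55)] = "induced"
    onset[m24 & ~cs] = "induced"
    m5 = group == 5
    onset[m5 & cs] = np.select(
        [u[m5 & cs] < 0.20, u[m5 & cs] < 0.35],
        ["spontaneous", "induced"], default="cesarean_before_labour")
    onset[m5 & ~cs] = np.where(u[m5 & ~cs] < 0.70, "spontaneous", "induced")
    mrest = np.isin(group, (6, 7, 8, 9, 10))
    onset[mrest & cs] = np.select(
        [u[mrest & cs] < 0.30, u[mrest & cs] < 0.40],
        ["spontaneous", "induced"], default="cesarean_before_labour")
    onset[mrest & ~cs] = np.where(u[mrest & ~cs] < 0.85,
                                  "spontaneous", "induced")
    return onset


def _draw_parity(rng, group, mix, multiparity_share):
    n = len(group)
    nulli_free = rng.random(n) < _NULLIPAROUS_IN_8_9_10
    multiparous = np.isin(group, (3, 4, 5, 7)) | \
        (np.isin(group, (8, 9, 10)) & ~nulli_free)

    p_multi = mix[2] + mix[3] + mix[4] + mix[6] + \
        (1 - _NULLIPAROUS_IN_8_9_10) * (mix[7] + mix[8] + mix[9])
    c = min(1.0, multiparity_share / p_multi) if p_multi > 0 else 0.0

    total = np.zeros(n, dtype=int)
    m = multiparous
    high = m & (rng.random(n) < c)
    total[high] = 4 + rng.poisson(0.7, size=int(high.sum()))
    low = m & ~high
    total[low] = _weighted_choice(rng, int(low.sum()), [1, 2, 3],
                                  [0.60, 0.30, 0.10])

    pcs = np.zeros(n, dtype=int)
    pvb = np.zeros(n, dtype=int)
    g5 = group == 5
    extra = (rng.random(n) < 0.2) & (total > 1)
    pcs[g5] = np.where(extra[g5], 2, 1)
    total5 = np.maximum(total, pcs)          # group 5 needs >=1 prior CS
    pvb[g5] = total5[g5] - pcs[g5]
    g34 = np.isin(group, (3, 4))
    pvb[g34] = total[g34]
    g7 = group == 7
    with_cs7 = rng.random(n) < 0.3
    pcs[g7 & with_cs7] = np.minimum(1, total[g7 & with_cs7])
    pvb[g7] = np.maximum(total[g7] - pcs[g7],
                         np.where(pcs[g7] == 0, 1, 0))
    g8910 = np.isin(group, (8, 9, 10)) & m
    with_cs_free = rng.random(n) < 0.15
    pcs[g8910 & with_cs_free] = np.minimum(1, total[g8910 & with_cs_free])
    pvb[g8910] = total[g8910] - pcs[g8910]
    total_out = pvb + pcs
    return pvb, pcs, total_out


def _draw_ga(rng, group, mix, preterm_rate, early_term_rate):
    n = len(group)
    mix10 = mix[9]
    mix6to9 = mix[5] + mix[6] + mix[7] + mix[8]
    p69 = 0.0 if mix6to9 == 0 else min(1.0, max(0.0, (preterm_rate - mix10)
                                                / mix6to9))
    preterm = np.zeros(n, dtype=bool)
    preterm[group == 10] = True
    m69 = np.isin(group, (6, 7, 8, 9))
    preterm[m69] = rng.random(int(m69.sum())) < p69

    q_early = min(1.0, early_term_rate / max(1e-12, 1.0 - preterm_rate))
    ga = np.empty(n, dtype=int)
    npt = int(preterm.sum())
    ga[preterm] = _weighted_choice(rng, npt, _PRETERM_WEEKS, _PRETERM_W)
    term = ~preterm
    early = term & (rng.random(n) < q_early)
    ga[early] = _weighted_choice(rng, int(early.sum()), [37, 38], [0.52, 0.48])
    full = term & ~early
    ga[full] = _weighted_choice(rng, int(full.sum()), [39, 40, 41, 42],
                                [0.45, 0.38, 0.14, 0.03])
    return ga


def _draw_age(rng, n, share_u20):
    u = rng.random(n)
    age = np.empty(n, dtype=int)
    young = u < share_u20
    old = u > 1 - 0.12
    mid = ~young & ~old
    age[young] = _weighted_choice(rng, int(young.sum()),
                                  [14, 15, 16, 17, 18, 19],
                                  [2, 6, 12, 20, 28, 32])
    age[mid] = _weighted_choice(rng, int(mid.sum()), np.arange(20, 35),
                                [8, 9, 10, 10, 10, 10, 9, 8, 7, 6, 5, 4, 3, 2, 2])
    age[old] = _weighted_choice(rng, int(old.sum()), np.arange(35, 46),
                                [30, 22, 16, 11, 8, 5, 3, 2, 1, 1, 1])
    return age


def _draw_prenatal(rng, n, coverage, seven_plus_share, early_start_share):
    covered = rng.random(n) < coverage
    p8 = min(1.0, seven_plus_share / max(coverage, 1e-12))
    eight_plus = covered & (rng.random(n) < p8)
    visits = np.zeros(n, dtype=int)
    visits[eight_plus] = 8 + rng.poisson(1.5, size=int(eight_plus.sum()))
    few = covered & ~eight_plus
    visits[few] = _weighted_choice(rng, int(few.sum()),
                                   [1, 2, 3, 4, 5, 6, 7],
                                   [4, 6, 9, 13, 18, 24, 26])
    # start trimester is only defined for women with any prenatal care; the
    # early-start parameter is conditional on coverage
    trimester = np.full(n, -1, dtype=int)       # -1 -> missing downstream
    u = rng.random(n)
    trimester[covered & (u < early_start_share)] = 1
    late = covered & (u >= early_start_share)
    trimester[late] = np.where(rng.random(n)[late] < 0.72, 2, 3)
    return visits, trimester


def _draw_birthweight(rng, ga, lbw_rate, national_preterm):
    n = len(ga)
    preterm = ga < 37
    p_lbw_pre = 0.45
    p_lbw_term = min(1.0, max(0.0, (lbw_rate - p_lbw_pre * national_preterm)
                              / max(1e-12, 1 - national_preterm)))
    u = rng.random(n)
    lbw = np.where(preterm, u < p_lbw_pre, u < p_lbw_term)
    weight = np.empty(n, dtype=int)
    nl = int(lbw.sum())
    weight[lbw] = np.clip(2500 - rng.gamma(2.0, 320.0, size=nl), 500,
                          2499).astype(int)
    rest = ~lbw
    base = np.where(preterm[rest], 2900, 3280)
    weight[rest] = np.clip(rng.normal(base, 330), 2500, 5400).astype(int)
    return weight


def _draw_occurrence(rng, n, muni, out_share, region_members, muni_region,
                     hubs, has_icu_muni):
    region = muni_region[muni]
    hub = hubs.get(region)
    candidates = [m for m in (hub,) if m and m != muni]
    if not candidates:
        # the hub itself travels to a hub in a sibling region of the state
        state_hubs = sorted(h for r, h in hubs.items()
                            if r != region and r[:4] == region[:4])
        all_hubs = sorted(h for h in hubs.values() if h != muni)
        candidates = state_hubs or all_hubs
    out = rng.random(n) < out_share
    occurrence = np.full(n, muni, dtype=object)
    if candidates:
        occurrence[out] = rng.choice(np.asarray(candidates, dtype=object),
                                     size=int(out.sum()))
    facility = np.empty(n, dtype=object)
    u = rng.random(n)
    for i in range(n):
        occ = occurrence[i]
        if has_icu_muni.get(occ):
            prefer_icu = 0.75 if occ != muni else 0.55
            facility[i] = f"F{occ}B" if u[i] < prefer_icu else f"F{occ}A"
        else:
            facility[i] = f"F{occ}A"
    return occurrence, facility


def _generate_deaths(rng, config, muni, year, n_births, mr) -> pd.DataFrame:
    p_death = mr["mmr_per_100k"] / 1e5
    n_mat = int(rng.binomial(n_births, min(1.0, p_death)))
    n_other = int(rng.poisson(n_births * 0.04))
    rows = []
    for i in range(n_mat):
        direct = rng.random() < mr["direct_cause_share"]
        if direct:
            cause_class = "direct"
            specific = str(_weighted_choice(
                rng, 1, ["hypertension", "hemorrhage", "infection",
                         "abortion", "other"],
                [0.32, 0.26, 0.13, 0.10, 0.19])[0])
        else:
            cause_class = "indirect" if rng.random() < 0.85 else "unspecified"
            specific = "not_applicable"
        rows.append({
            "record_id": f"MD{year}{muni}{i:04d}", "year": year,
            "residence_muni": muni, "age": int(rng.integers(15, 50)),
            "is_maternal_death": True, "obstetric_cause_class": cause_class,
            "specific_cause": specific,
            "investigated": bool(rng.random() < 0.97)})
    for i in range(n_other):
        rows.append({
            "record_id": f"WD{year}{muni}{i:04d}", "year": year,
            "residence_muni": muni, "age": int(rng.integers(10, 50)),
            "is_maternal_death": False,
            "obstetric_cause_class": "not_applicable",
            "specific_cause": "not_applicable",
            "investigated": bool(rng.random() < 0.92)})
    cols = ["record_id", "year", "residence_muni", "age", "is_maternal_death",
            "obstetric_cause_class", "specific_cause", "investigated"]
    df = pd.DataFrame(rows, columns=cols)
    df["age"] = df["age"].astype("Int64")
    df["is_maternal_death"] = df["is_maternal_death"].astype("boolean")
    df["investigated"] = df["investigated"].astype("boolean")
    return df


def _generate_admissions(rng, config, muni, year, births, public, mr
                         ) -> pd.DataFrame:
    n = len(births)
    rows = []
    serial = 0

    def smm_payload(admission_is_abortion: bool):
        """Inject one SMM case: a cause code, plus optional management
        markers, guaranteed to trip the default classifier."""
        cause = str(_weighted_choice(
            rng, 1, ["hypertension", "hemorrhage", "infection"],
            [0.45, 0.35, 0.20])[0])
        dx = [str(rng.choice(_SMM_CAUSE_CODES[cause]))]
        if admission_is_abortion:
            dx.append(str(rng.choice(_BENIGN_ABORTION_DX)))
        else:
            dx.append(str(rng.choice(_BENIGN_DELIVERY_DX)))
        transfusion = bool(rng.random() < 0.35)
        icu = int(1 + rng.poisson(2.0)) if rng.random() < 0.40 else 0
        surgery = rng.random() < 0.15
        prolonged = rng.random() < 0.30
        stay = int(8 + rng.poisson(3.0)) if prolonged \
            else int(min(7, 3 + rng.poisson(1.5)))
        stay = max(stay, icu)
        procs = [str(rng.choice(_SURGICAL_PROCS))] if surgery else [_BENIGN_PROC]
        return dx, procs, transfusion, icu, stay

    def benign_payload(admission_is_abortion: bool):
        dx = [str(rng.choice(_BENIGN_ABORTION_DX if admission_is_abortion
                             else _BENIGN_DELIVERY_DX))]
        stay = int(min(7, 1 + rng.poisson(1.2))) if admission_is_abortion \
            else int(min(7, 2 + rng.poisson(1.0)))
        return dx, [_BENIGN_PROC], False, 0, stay

    def add(admission_type, payer):
        nonlocal serial
        is_abortion = admission_type == "abortion"
        if payer == "public" and rng.random() < mr["smm_share_of_admissions"]:
            dx, procs, transfusion, icu, stay = smm_payload(is_abortion)
        else:
            dx, procs, transfusion, icu, stay = benign_payload(is_abortion)
        rows.append({
            "record_id": f"HA{year}{muni}{serial:05d}", "year": year,
            "residence_muni": muni, "admission_type": admission_type,
            "diagnosis_codes": "|".join(dx), "procedure_codes": "|".join(procs),
            "icu_days": icu, "length_of_stay_days": stay,
            "transfusion": transfusion, "payer": payer})
        serial += 1

    # one public delivery admission per public-payer birth
    for _ in range(int(public.sum())):
        add("delivery", "public")
    # abortion admissions (public and private services)
    n_abortion = int(rng.binomial(n, mr["abortion_admission_share"]))
    for _ in range(n_abortion):
        add("abortion", "public" if rng.random() < 0.85 else "private")
    # other obstetric admissions (ectopic, hyperemesis, ...)
    for _ in range(int(rng.binomial(n, 0.03))):
        add("other_obstetric", "public")

    cols = ["record_id", "year", "residence_muni", "admission_type",
            "diagnosis_codes", "procedure_codes", "icu_days",
            "length_of_stay_days", "transfusion", "payer"]
    df = pd.DataFrame(rows, columns=cols)
    df["icu_days"] = df["icu_days"].astype("Int64")
    df["length_of_stay_days"] = df["length_of_stay_days"].astype("Int64")
    df["transfusion"] = df["transfusion"].astype("boolean")
    return df


def _apply_missingness(births: pd.DataFrame, missingness: Dict[str, float],
                       rng) -> pd.DataFrame:
    births = births.copy()
    n = len(births)
    for field_name in sorted(missingness):
        p = missingness[field_name]
        if p <= 0 or field_name not in births.columns:
            continue
        mask = rng.random(n) < p
        col = births[field_name]
        if col.dtype == object:
            col = col.astype("string")
        col = col.mask(mask)
        births[field_name] = col
    return births
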