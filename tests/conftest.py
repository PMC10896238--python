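import pandas as pd
import pytest

import matvig as mv


@pytest.fixture(scope="session")
def small_world() -> mv.World:
    """A compact synthetic world shared by read-only tests."""
    cfg = mv.SimulationConfig(seed=11, n_municipalities=6, births_per_muni=400)
    return mv.generate_world(cfg)


@pytest.fixture(scope="session")
def small_panel(small_world) -> mv.PanelData:
    return small_world.to_panel_data()


@pytest.fixture(scope="session")
def abortion_config() -> mv.AbortionCorrectionConfig:
    return mv.AbortionCorrectionConfig.default()


@pytest.fixture(scope="session")
def catalogue() -> mv.Catalogue:
    return mv.load_catalogue()


@pytest.fixture()
def tiny_hierarchy() -> mv.GeoHierarchy:
    """1 country, 1 macro-region, 2 states x 2 regions x 3 municipalities."""
    rows = [("BR", "country", None), ("MA1", "macro_region", "BR")]
    for s in (1, 2):
        rows.append((f"ST{s}", "state", "MA1"))
        for r in (1, 2):
            rows.append((f"RE{s}{r}", "health_region", f"ST{s}"))
            for m in range(1, 4):
                rows.append((f"{s}{r}{m:04d}", "municipality", f"RE{s}{r}"))
    df = pd.DataFrame([{"code": c, "name": c, "level": lv, "parent_code": p}
                       for c, lv, p in rows])
    return mv.GeoHierarchy.from_frame(df)


def make_births(rows: list[dict]) -> pd.DataFrame:
    """Build a canonical live-birth frame from sparse dicts (missing = NA)."""
    defaults = {
        "record_id": None, "year": 2015, "residence_muni": "110001",
        "occurrence_muni": "110001", "facility_id": pd.NA,
        "maternal_age": pd.NA, "race_color": pd.NA, "education": pd.NA,
        "prior_vaginal_births": pd.NA, "prior_cesarean_births": pd.NA,
        "plurality": pd.NA, "presentation": pd.NA,
        "gestational_age_weeks": pd.NA, "labour_onset": pd.NA,
        "delivery_mode": pd.NA, "prenatal_visits": pd.NA,
        "prenatal_start_trimester": pd.NA, "birthweight_g": pd.NA,
    }
    full = []
    for i, row in enumerate(rows):
        d = dict(defaults)
        d["record_id"] = f"R{i:04d}"
        d.update(row)
        full.append(d)
    df = pd.DataFrame(full, columns=list(defaults))
    for col in ("maternal_age", "prior_vaginal_births", "prior_cesarean_births",
                "gestational_age_weeks", "prenatal_visits",
                "prenatal_start_trimester", "birthweight_g", "year"):
        df[col] = df[col].astype("Int64")
    for col in ("residence_muni", "occurrence_muni", "facility_id",
                "race_color", "education", "plurality", "presentation",
                "labour_onset", "delivery_mode", "record_id"):
        df[col] = df[col].astype("string")
    return df


def make_admissions(rows: list[dict]) -> pd.DataFrame:
    defaults = {
        "record_id": None, "year": 2015, "residence_muni": "110001",
        "admission_type": "delivery", "diagnosis_codes": "O80",
        "procedure_codes": "0310010039", "icu_days": 0,
        "length_of_stay_days": 2, "transfusion": False, "payer": "public",
    }
    full = []
    for i, row in enumerate(rows):
        d = dict(defaults)
        d["record_id"] = f"H{i:04d}"
        d.update(row)
        full.append(d)
    df = pd.DataFrame(full, columns=list(defaults))
    for col in ("icu_days", "length_of_stay_days", "year"):
        df[col] = df[col].astype("Int64")
    df["transfusion"] = df["transfusion"].astype("boolean")
    for col in ("record_id", "residence_muni", "admission_type",
                "diagnosis_codes", "procedure_codes", "payer"):
        df[col] = df[col].astype("string")
    return df
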