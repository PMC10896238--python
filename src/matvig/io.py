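"""Reading, validating and writing delimited microdata.

Input files are delimited text (comma or semicolon) with a header row.  A
*schema map* describes one source dialect: which source column feeds each
canonical field, which sentinel tokens mean "ignored/unknown" (the DATASUS
"9"/"99" conventions vary by system and year, so they live in the map, not in
code), optional token recodes, and whether municipality codes carry a 7th
check digit to strip.

Rows that violate a type invariant are never silently dropped: they are
quarantined to a rejection log ``(row_number, field, reason)`` and the loader
guarantees ``rows_in == records_out + rejected_rows``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError
from .schemas import (
    Field,
    GEO_CODE_RE,
    fields_for,
    is_valid_icd10,
    normalize_icd10,
)

_TRUE_TOKENS = {"1", "true", "True", "TRUE", "yes"}
_FALSE_TOKENS = {"0", "false", "False", "FALSE", "no"}


@dataclass
class SchemaMap:
    """A named source dialect mapping source columns to canonical fields."""

    name: str
    delimiter: str = ","
    columns: Mapping[str, str] = dc_field(default_factory=dict)   # source -> canonical
    missing_sentinels: Mapping[str, list] = dc_field(default_factory=dict)
    value_maps: Mapping[str, Mapping[str, Optional[str]]] = dc_field(default_factory=dict)
    strip_geo_check_digit: bool = False
    absent: tuple = ()

    @classmethod
    def from_yaml(cls, path) -> "SchemaMap":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(
            name=raw.get("name", Path(path).stem),
            delimiter=raw.get("delimiter", ","),
            columns=raw.get("columns", {}),
            missing_sentinels=raw.get("missing_sentinels", {}),
            value_maps=raw.get("value_maps", {}),
            strip_geo_check_digit=bool(raw.get("strip_geo_check_digit", False)),
            absent=tuple(raw.get("absent", [])),
        )

    @classmethod
    def builtin(cls, name: str) -> "SchemaMap":
        """Load one of the dialects shipped with the package."""
        ref = importlib.resources.files("matvig").joinpath(
            f"data/schema_maps/{name}.yaml")
        with importlib.resources.as_file(ref) as p:
            return cls.from_yaml(p)


def canonical_schema_map(record_kind: str) -> SchemaMap:
    """Identity dialect: canonical column names, empty cell = missing."""
    specs = fields_for(record_kind)
    return SchemaMap(name="canonical", columns={f.name: f.name for f in specs})


@dataclass
class LoadResult:
    """Validated records plus the quarantine of rows that failed validation."""

    records: pd.DataFrame
    rejections: pd.DataFrame  # columns: row_number, field, reason
    rows_in: int

    @property
    def n_rejected_rows(self) -> int:
        if self.rejections.empty:
            return 0
        return self.rejections["row_number"].nunique()

    def write_rejection_log(self, path) -> None:
        self.rejections.to_csv(path, index=False)


def _parse_column(raw: pd.Series, spec: Field, smap: SchemaMap,
                  hierarchy=None):
    """Parse one raw string column.  Returns (values, reasons) where
    ``reasons`` is a string Series with pd.NA where the cell is fine."""
    s = raw.fillna("").astype(str).str.strip()
    missing = s.eq("")
    sentinels = smap.missing_sentinels.get(spec.name)
    if sentinels:
        missing |= s.isin([str(t) for t in sentinels])
    vmap = smap.value_maps.get(spec.name)
    if vmap:
        mapped = s.map({str(k): v for k, v in vmap.items()})
        hit = s.isin([str(k) for k in vmap])
        missing |= hit & mapped.isna()
        s = s.where(~hit, mapped.fillna(""))

    reasons = pd.Series(pd.NA, index=s.index, dtype="string")
    present = ~missing

    if spec.kind == "int":
        num = pd.to_numeric(s.where(present), errors="coerce")
        bad = present & num.isna()
        bad |= present & ~bad & (num != np.floor(num.fillna(0)))
        reasons[bad] = f"{spec.name}: unparseable integer"
        vals = num.where(~bad).astype("Float64")
        if spec.lo is not None:
            oob = present & ~bad & ((vals < spec.lo) | (vals > spec.hi))
            reasons[oob] = f"{spec.name}: out of range [{spec.lo:g}, {spec.hi:g}]"
            vals = vals.where(~oob)
        values = vals.astype("Int64")
    elif spec.kind == "bool":
        is_true = s.isin(_TRUE_TOKENS)
        is_false = s.isin(_FALSE_TOKENS)
        bad = present & ~is_true & ~is_false
        reasons[bad] = f"{spec.name}: unparseable boolean"
        values = pd.Series(pd.NA, index=s.index, dtype="boolean")
        values[present & is_true] = True
        values[present & is_false] = False
    elif spec.kind == "category":
        bad = present & ~s.isin(spec.categories)
        reasons[bad] = f"{spec.name}: invalid category"
        values = pd.Series(pd.NA, index=s.index, dtype="string")
        ok = present & ~bad
        values[ok] = s[ok]
    elif spec.kind == "codes":
        def norm(cell: str):
            codes = [normalize_icd10(c) for c in cell.split("|") if c.strip()]
            if any(not is_valid_icd10(c) for c in codes):
                return None
            return "|".join(codes)
        out = s.where(present).map(norm, na_action="ignore")
        bad = present & out.isna()
        reasons[bad] = f"{spec.name}: invalid ICD-10 code"
        values = out.astype("string")
    else:  # str / geo
        values = pd.Series(pd.NA, index=s.index, dtype="string")
        values[present] = s[present]
        if spec.geo:
            if smap.strip_geo_check_digit:
                seven = present & s.str.fullmatch(r"[0-9]{7}")
                values[seven] = s[seven].str[:6]
            bad = present & ~values.fillna("").str.fullmatch(GEO_CODE_RE.pattern)
            reasons[bad] = f"{spec.name}: unparseable geo code"
            values = values.where(~bad)
            if hierarchy is not None:
                known = values.isin(hierarchy.codes_at("municipality"))
                unknown = present & ~bad & ~known
                reasons[unknown] = f"{spec.name}: municipality not in hierarchy"
                values = values.where(~unknown)

    if spec.required:
        now_missing = values.isna() & reasons.isna()
        reasons[now_missing] = f"{spec.name}: missing required value"
    return values, reasons


def load_table(path, schema_map: SchemaMap, record_kind: str,
               hierarchy=None) -> LoadResult:
    """Load and validate one delimited microdata file.

    Every canonical field of ``record_kind`` must be either mapped by the
    schema map or listed in its ``absent`` clause; mapped columns must exist
    in the file.  Invalid rows go to the rejection log with one entry per
    offending field.
    """
    specs = fields_for(record_kind)
    raw = pd.read_csv(path, sep=schema_map.delimiter, dtype=str,
                      keep_default_na=False, encoding="utf-8")

    canon_to_source = {v: k for k, v in schema_map.columns.items()}
    missing_cols = []
    for spec in specs:
        if spec.name in schema_map.absent:
            if spec.required:
                missing_cols.append(spec.name)
            continue
        src = canon_to_source.get(spec.name)
        if src is None or src not in raw.columns:
            missing_cols.append(spec.name)
    if missing_cols:
        raise SchemaError(
            f"schema map {schema_map.name!r} does not cover columns for "
            f"canonical fields: {', '.join(sorted(missing_cols))}")

    n = len(raw)
    out = {}
    reason_frames = []
    for spec in specs:
        if spec.name in schema_map.absent:
            dtype = {"int": "Int64", "bool": "boolean"}.get(spec.kind, "string")
            out[spec.name] = pd.Series(pd.NA, index=raw.index, dtype=dtype)
            continue
        values, reasons = _parse_column(raw[canon_to_source[spec.name]], spec,
                                        schema_map, hierarchy=hierarchy)
        out[spec.name] = values
        if reasons.notna().any():
            rf = reasons.dropna().rename("reason").reset_index()
            rf["field"] = spec.name
            reason_frames.append(rf)

    records = pd.DataFrame(out, index=raw.index)

    # cross-field invariants
    cross = _cross_field_violations(records, record_kind)
    reason_frames.extend(cross)

    if reason_frames:
        rej = pd.concat(reason_frames, ignore_index=True)
        rej["row_number"] = rej["index"] + 1  # 1-based data-row numbering
        rej = rej[["row_number", "field", "reason"]].sort_values(
            ["row_number", "field"]).reset_index(drop=True)
        bad_idx = sorted(set(rej["row_number"] - 1))
        records = records.drop(index=bad_idx).reset_index(drop=True)
    else:
        rej = pd.DataFrame(columns=["row_number", "field", "reason"])
    return LoadResult(records=records, rejections=rej, rows_in=n)


def _cross_field_violations(records: pd.DataFrame, record_kind: str):
    frames = []

    def collect(mask: pd.Series, field_name: str, reason: str):
        if mask.any():
            rf = pd.DataFrame({
                "index": records.index[mask.fillna(False)],
                "reason": reason,
                "field": field_name,
            })
            frames.append(rf)

    if record_kind == "maternal_death":
        cls = records["obstetric_cause_class"]
        mat = records["is_maternal_death"]
        collect((mat == True) & (cls == "not_applicable"),  # noqa: E712
                "obstetric_cause_class",
                "obstetric_cause_class: not_applicable on a maternal death")
        collect((mat == False) & cls.notna() & (cls != "not_applicable"),  # noqa: E712
                "obstetric_cause_class",
                "obstetric_cause_class: obstetric cause on a non-maternal death")
    elif record_kind == "hospitalization":
        icu = records["icu_days"]
        los = records["length_of_stay_days"]
        collect(icu.notna() & los.notna() & (icu > los), "icu_days",
                "icu_days: exceeds length of stay")
    return frames


def canonicalize_dtypes(records: pd.DataFrame, record_kind: str) -> pd.DataFrame:
    """Coerce a canonical-form frame onto the nullable dtypes the loader
    produces (``Int64`` / ``boolean`` / ``string``)."""
    records = records.copy()
    for spec in fields_for(record_kind):
        if spec.name not in records.columns:
            continue
        if spec.kind == "int":
            records[spec.name] = records[spec.name].astype("Int64")
        elif spec.kind == "bool":
            records[spec.name] = records[spec.name].astype("boolean")
        else:
            records[spec.name] = records[spec.name].astype("string")
    return records


def write_table(records: pd.DataFrame, path, record_kind: str,
                delimiter: str = ",") -> None:
    """Write canonical records in the identity dialect (round-trip safe)."""
    specs = fields_for(record_kind)
    df = records.copy()
    for spec in specs:
        if spec.kind == "bool" and spec.name in df:
            df[spec.name] = df[spec.name].map({True: "1", False: "0"})
    cols = [f.name for f in specs if f.name in df.columns]
    df[cols].to_csv(path, index=False, sep=delimiter)


# ---------------------------------------------------------------------------
# Reference tables
# ---------------------------------------------------------------------------

F_10_49_BANDS = ("10-19", "20-29", "30-39", "40-49")


@dataclass
class ReferenceTables:
    """Auxiliary denominators and context tables keyed by geography/year.

    population: (geo, year, sex, age_band) -> count
    beneficiaries: female 10-49 health-plan beneficiaries per geo/year
    fhs: annual mean population covered by family health teams
    mhdi: municipal human development index per municipality
    distances: symmetric inter-municipality road distances in km
    facilities: facility registry with adult-ICU availability
    estimates: demographic estimates of births and deaths (coverage denominators)
    investigation: counts of deaths of women of childbearing age and of
        maternal deaths, total and investigated
    syphilis: congenital syphilis case counts
    """

    population: pd.DataFrame
    beneficiaries: pd.DataFrame
    fhs: pd.DataFrame
    mhdi: pd.DataFrame
    distances: pd.DataFrame
    facilities: pd.DataFrame
    estimates: pd.DataFrame
    investigation: pd.DataFrame
    syphilis: pd.DataFrame

    FILES = {
        "population": "population.csv",
        "beneficiaries": "beneficiaries.csv",
        "fhs": "fhs.csv",
        "mhdi": "mhdi.csv",
        "distances": "distances.csv",
        "facilities": "facilities.csv",
        "estimates": "estimates.csv",
        "investigation": "investigation.csv",
        "syphilis": "syphilis.csv",
    }

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        d = self.distances
        if len(d):
            self_pairs = d[d["muni_a"] == d["muni_b"]]
            if (self_pairs["km"] != 0).any():
                raise SchemaError("distance matrix: nonzero self-distance")
            key = d.set_index(["muni_a", "muni_b"])["km"]
            swapped = key.reset_index().rename(
                columns={"muni_a": "muni_b", "muni_b": "muni_a"})
            merged = d.merge(swapped, on=["muni_a", "muni_b"],
                             suffixes=("", "_t"))
            if not np.allclose(merged["km"], merged["km_t"]):
                raise SchemaError("distance matrix: not symmetric")
        if ((self.mhdi["mhdi"] < 0) | (self.mhdi["mhdi"] > 1)).any():
            raise SchemaError("mhdi outside [0, 1]")
        for name in ("population", "beneficiaries", "fhs", "estimates",
                     "investigation", "syphilis"):
            df = getattr(self, name)
            num = df.select_dtypes("number")
            if (num < 0).any().any():
                raise SchemaError(f"{name}: negative count")

    @classmethod
    def load(cls, directory) -> "ReferenceTables":
        directory = Path(directory)
        kwargs = {}
        for attr, fname in cls.FILES.items():
            p = directory / fname
            if not p.exists():
                raise SchemaError(f"missing reference table file: {fname}")
            df = pd.read_csv(p, dtype={"geo": str, "muni_a": str, "muni_b": str,
                                       "muni": str, "facility_id": str})
            kwargs[attr] = df
        return cls(**kwargs)

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for attr, fname in self.FILES.items():
            getattr(self, attr).to_csv(directory / fname, index=False)

    # convenience denominators -------------------------------------------------
    def female_population(self, geo: str, year: int, bands) -> Optional[float]:
        pop = self.population
        sel = pop[(pop["geo"] == geo) & (pop["year"] == year)
                  & (pop["sex"] == "F") & (pop["age_band"].isin(bands))]
        if sel.empty:
            return None
        return float(sel["count"].sum())

    def female_10_19(self, geo, year):
        return self.female_population(geo, year, ["10-19"])

    def female_10_49(self, geo, year):
        return self.female_population(geo, year, F_10_49_BANDS)

    def total_population(self, geo: str, year: int) -> Optional[float]:
        pop = self.population
        sel = pop[(pop["geo"] == geo) & (pop["year"] == year)]
        if sel.empty:
            return None
        return float(sel["count"].sum())

    def scalar(self, table: str, geo: str, year: int, column: str):
        df = getattr(self, table)
        sel = df[(df["geo"] == geo) & (df["year"] == year)]
        if sel.empty or column not in sel or sel[column].isna().all():
            return None
        return float(sel[column].iloc[0])
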