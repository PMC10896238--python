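"""Canonical record schemas for the surveillance engine.

Three microdata record kinds circulate through the engine, emulating the
Brazilian vital-statistics and hospital systems: live births (SINASC-like),
deaths of women of childbearing age (SIM-like) and public obstetric
hospitalizations (SIH/SUS-like).  Each kind is described by a list of
:class:`Field` specs; the specs drive parsing, validation and the rejection
log in :mod:`matvig.io`.

Canonical in-memory form is a :class:`pandas.DataFrame` with nullable dtypes
(``Int64`` / ``Float64`` / ``string``); missing values are ``pd.NA``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Tuple

# ICD-10 lexical form after normalization (dot removed, upper case):
# letter + two digits + optional one-character subcode.
ICD10_RE = re.compile(r"^[A-Z][0-9]{2}[0-9A-Z]?$")

GEO_CODE_RE = re.compile(r"^[0-9]{6}$")


@dataclass(frozen=True)
class Field:
    """Specification of one canonical field.

    kind: "str", "int", "bool", "category", "codes" (pipe-separated code list)
    """

    name: str
    kind: str
    required: bool = False
    categories: Tuple[str, ...] = ()
    lo: Optional[float] = None
    hi: Optional[float] = None
    geo: bool = False


RACE_COLOR = ("white", "black", "brown", "indigenous", "asian")
EDUCATION = ("none", "1-3", "4-7", "8-11", "12+")
PLURALITY = ("single", "multiple")
PRESENTATION = ("cephalic", "breech", "transverse_oblique")
LABOUR_ONSET = ("spontaneous", "induced", "cesarean_before_labour")
DELIVERY_MODE = ("vaginal", "cesarean")
ADMISSION_TYPE = ("delivery", "abortion", "other_obstetric", "non_obstetric")
PAYER = ("public", "private")
OBSTETRIC_CAUSE_CLASS = ("direct", "indirect", "unspecified", "not_applicable")
SPECIFIC_CAUSE = ("abortion", "hypertension", "hemorrhage", "infection",
                  "other", "not_applicable")

LIVE_BIRTH = "live_birth"
MATERNAL_DEATH = "maternal_death"
HOSPITALIZATION = "hospitalization"

LIVE_BIRTH_FIELDS = [
    Field("record_id", "str", required=True),
    Field("year", "int", required=True, lo=1990, hi=2100),
    Field("residence_muni", "str", required=True, geo=True),
    Field("occurrence_muni", "str", required=True, geo=True),
    Field("facility_id", "str"),
    Field("maternal_age", "int", lo=8, hi=60),
    Field("race_color", "category", categories=RACE_COLOR),
    Field("education", "category", categories=EDUCATION),
    Field("prior_vaginal_births", "int", lo=0, hi=30),
    Field("prior_cesarean_births", "int", lo=0, hi=20),
    Field("plurality", "category", categories=PLURALITY),
    Field("presentation", "category", categories=PRESENTATION),
    Field("gestational_age_weeks", "int", lo=20, hi=45),
    Field("labour_onset", "category", categories=LABOUR_ONSET),
    Field("delivery_mode", "category", categories=DELIVERY_MODE),
    Field("prenatal_visits", "int", lo=0, hi=60),
    Field("prenatal_start_trimester", "int", lo=1, hi=3),
    Field("birthweight_g", "int", lo=200, hi=7000),
]

MATERNAL_DEATH_FIELDS = [
    Field("record_id", "str", required=True),
    Field("year", "int", required=True, lo=1990, hi=2100),
    Field("residence_muni", "str", required=True, geo=True),
    Field("age", "int", required=True, lo=8, hi=60),
    Field("is_maternal_death", "bool", required=True),
    Field("obstetric_cause_class", "category", categories=OBSTETRIC_CAUSE_CLASS),
    Field("specific_cause", "category", categories=SPECIFIC_CAUSE),
    Field("investigated", "bool"),
]

HOSPITALIZATION_FIELDS = [
    Field("record_id", "str", required=True),
    Field("year", "int", required=True, lo=1990, hi=2100),
    Field("residence_muni", "str", required=True, geo=True),
    Field("admission_type", "category", required=True, categories=ADMISSION_TYPE),
    Field("diagnosis_codes", "codes"),
    Field("procedure_codes", "str"),
    Field("icu_days", "int", lo=0, hi=365),
    Field("length_of_stay_days", "int", lo=0, hi=365),
    Field("transfusion", "bool"),
    Field("payer", "category", required=True, categories=PAYER),
]

SCHEMAS = {
    LIVE_BIRTH: LIVE_BIRTH_FIELDS,
    MATERNAL_DEATH: MATERNAL_DEATH_FIELDS,
    HOSPITALIZATION: HOSPITALIZATION_FIELDS,
}


def fields_for(record_kind: str) -> list[Field]:
    try:
        return SCHEMAS[record_kind]
    except KeyError:
        raise KeyError(f"unknown record kind: {record_kind!r}; "
                       f"expected one of {sorted(SCHEMAS)}") from None


def normalize_icd10(code: str) -> str:
    """Normalize an ICD-10 code to dot-free upper case (``o14.1`` -> ``O141``)."""
    return code.replace(".", "").replace(" ", "").upper()


def is_valid_icd10(code: str) -> bool:
    return bool(ICD10_RE.match(normalize_icd10(code)))


def split_codes(cell) -> list[str]:
    """Split a pipe-separated code cell into a list (missing -> empty list)."""
    if cell is None or cell != cell or cell == "":  # NaN-safe
        return []
    return [c for c in str(cell).split("|") if c]
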