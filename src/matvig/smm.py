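"""Severe maternal morbidity (potentially life-threatening conditions).

A public obstetric hospitalization is flagged as a severe-maternal-morbidity
(SMM) case when it carries a diagnosis in one of the configured cause groups
(hypertensive, hemorrhagic, infectious) or shows a severe-management marker:
blood transfusion, severe surgical procedure, ICU admission, or a prolonged
stay.  Classification is multi-label: a case retains every cause and every
management marker it matches, so cause/management percentage breakdowns may
sum to more than 100.

Only public admissions are eligible — privately financed hospitalizations do
not reach the hospital system emulated here, which is the panel's stated
limitation for municipalities with high health-plan coverage.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import pandas as pd
import yaml

from .errors import ConfigError
from .schemas import is_valid_icd10, normalize_icd10, split_codes

MANAGEMENT_MARKERS = ("transfusion", "surgery", "icu_admission", "prolonged_stay")


@dataclass
class SMMCodeConfig:
    """Cause code sets (ICD-10 prefixes, dot-free) and management thresholds."""

    cause_code_sets: Dict[str, List[str]]
    surgical_procedure_codes: List[str] = field(default_factory=list)
    icu_criterion_days: int = 1
    prolonged_stay_days: int = 7

    def __post_init__(self):
        if not self.cause_code_sets:
            raise ConfigError("cause_code_sets must not be empty")
        norm = {}
        for cause, codes in self.cause_code_sets.items():
            if not codes:
                raise ConfigError(f"cause code set {cause!r} is empty")
            normed = [normalize_icd10(str(c)) for c in codes]
            bad = [c for c in normed if not _valid_prefix(c)]
            if bad:
                raise ConfigError(f"invalid ICD-10 prefixes for {cause!r}: {bad}")
            norm[cause] = normed
        self.cause_code_sets = norm
        self.surgical_procedure_codes = [str(c) for c in self.surgical_procedure_codes]

    @classmethod
    def from_yaml(cls, path) -> "SMMCodeConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(
            cause_code_sets=raw["cause_code_sets"],
            surgical_procedure_codes=raw.get("surgical_procedure_codes", []),
            icu_criterion_days=int(raw.get("icu_criterion_days", 1)),
            prolonged_stay_days=int(raw.get("prolonged_stay_days", 7)),
        )

    @classmethod
    def default(cls) -> "SMMCodeConfig":
        ref = importlib.resources.files("matvig").joinpath("data/smm_codes.yaml")
        with importlib.resources.as_file(ref) as p:
            return cls.from_yaml(p)

    @property
    def causes(self) -> List[str]:
        return list(self.cause_code_sets)


def _valid_prefix(code: str) -> bool:
    # a prefix may be a bare letter+2digits stem or a full 4-char code
    return len(code) >= 3 and (is_valid_icd10(code) or is_valid_icd10(code + "0"))


@dataclass
class SMMCase:
    record_id: str
    causes: List[str]
    management: List[str]

    def __post_init__(self):
        if not self.causes and not self.management:
            raise ValueError("an SMM case needs at least one cause or marker")


def _match_any_prefix(codes: List[str], prefixes: List[str]) -> bool:
    return any(c.startswith(p) for c in codes for p in prefixes)


def classify_smm(record, config: SMMCodeConfig) -> Optional[SMMCase]:
    """Classify one hospitalization record (mapping/Series of canonical fields).

    Raises :class:`ValueError` for records outside the contract (private payer
    or non-obstetric admission); frame-level callers skip and count those.
    """
    def get(name, default=None):
        v = record.get(name, default) if hasattr(record, "get") else getattr(record, name, default)
        return default if v is None or v is pd.NA or v != v else v

    if get("payer") != "public" or get("admission_type") == "non_obstetric":
        raise ValueError("SMM classification applies to public obstetric "
                         "admissions only")

    dx = [normalize_icd10(c) for c in split_codes(get("diagnosis_codes", ""))]
    procs = split_codes(get("procedure_codes", ""))

    causes = [cause for cause, prefixes in config.cause_code_sets.items()
              if _match_any_prefix(dx, prefixes)]
    management = []
    if bool(get("transfusion", False)):
        management.append("transfusion")
    if _match_any_prefix(procs, config.surgical_procedure_codes):
        management.append("surgery")
    if int(get("icu_days", 0) or 0) >= config.icu_criterion_days:
        management.append("icu_admission")
    if int(get("length_of_stay_days", 0) or 0) > config.prolonged_stay_days:
        management.append("prolonged_stay")

    if not causes and not management:
        return None
    return SMMCase(record_id=str(get("record_id", "")), causes=causes,
                   management=management)


def classify_frame(admissions: pd.DataFrame,
                   config: SMMCodeConfig) -> Tuple[pd.DataFrame, int]:
    """Vectorized classification over a canonical hospitalization frame.

    Returns ``(flags, n_skipped)`` where ``flags`` is indexed like the
    eligible (public obstetric) subset with one boolean column per cause
    (``cause_<name>``), per management marker (``mgmt_<name>``) and
    ``is_case``; ``n_skipped`` counts out-of-contract records.
    """
    eligible = (admissions["payer"].astype("string") == "public") \
        .fillna(False).to_numpy(dtype=bool)
    eligible &= (admissions["admission_type"].astype("string") != "non_obstetric") \
        .fillna(False).to_numpy(dtype=bool)
    n_skipped = int((~eligible).sum())
    sub = admissions.loc[eligible]

    dx_lists = [split_codes(c) for c in sub["diagnosis_codes"]]
    proc_lists = [split_codes(c) for c in sub["procedure_codes"]]

    flags = pd.DataFrame(index=sub.index)
    for cause, prefixes in config.cause_code_sets.items():
        flags[f"cause_{cause}"] = pd.Series(
            [_match_any_prefix(codes, prefixes) for codes in dx_lists],
            index=sub.index, dtype=bool)
    flags["mgmt_transfusion"] = sub["transfusion"].fillna(False).astype(bool)
    flags["mgmt_surgery"] = pd.Series(
        [_match_any_prefix(codes, config.surgical_procedure_codes)
         for codes in proc_lists], index=sub.index, dtype=bool)
    icu = sub["icu_days"].fillna(0).astype(int)
    los = sub["length_of_stay_days"].fillna(0).astype(int)
    flags["mgmt_icu_admission"] = (icu >= config.icu_criterion_days).to_numpy(dtype=bool)
    flags["mgmt_prolonged_stay"] = (los > config.prolonged_stay_days).to_numpy(dtype=bool)
    flags["is_case"] = flags.any(axis=1)
    return flags, n_skipped


def smm_indicators(admissions: pd.DataFrame, config: SMMCodeConfig) -> dict:
    """Block-6 morbidity indicators for one geography x year slice.

    Returns numerators/denominators and percentages:

    - ``smm_pct``: cases / public obstetric admissions x 100 (undefined when
      there is no eligible admission);
    - ``cause_pct`` / ``management_pct``: share of SMM cases carrying each
      label, denominator = total SMM cases (multi-label; may sum to > 100).
    """
    flags, n_skipped = classify_frame(admissions, config)
    n_adm = len(flags)
    n_cases = int(flags["is_case"].sum())
    out = {
        "n_public_obstetric_admissions": n_adm,
        "n_cases": n_cases,
        "n_skipped_out_of_contract": n_skipped,
        "smm_pct": (n_cases / n_adm * 100.0) if n_adm else None,
        "undefined": n_adm == 0,
        "cause_pct": {}, "management_pct": {},
    }
    for cause in config.causes:
        k = int(flags.loc[flags["is_case"], f"cause_{cause}"].sum())
        out["cause_pct"][cause] = (k / n_cases * 100.0) if n_cases else None
    for marker in MANAGEMENT_MARKERS:
        k = int(flags.loc[flags["is_case"], f"mgmt_{marker}"].sum())
        out["management_pct"][marker] = (k / n_cases * 100.0) if n_cases else None
    return out
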