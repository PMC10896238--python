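"""Robson ten-group classification of births and its three panel indicators.

The Robson system partitions all deliveries into ten mutually exclusive,
totally inclusive groups from six obstetric variables: plurality,
fetal presentation/lie, gestational age, history of cesarean section, parity,
and onset of labour.  The WHO recommends it as the standard lens for
analysing cesarean-section rates: for each group one inspects its relative
size, its internal cesarean rate, and its contribution to the overall
cesarean rate.

Precedence implemented here (the canonical decision table):

1. multiple pregnancy                                      -> group 8
2. transverse or oblique lie                               -> group 9
3. breech                                                  -> group 6 (nulliparous) / 7 (multiparous, incl. prior CS)
4. single cephalic preterm (GA < 37 weeks)                 -> group 10
5. single cephalic term with >=1 prior cesarean            -> group 5
6. nulliparous term cephalic single: spontaneous labour    -> group 1
                                      induced / pre-labour CS -> group 2
7. multiparous term cephalic single (no prior CS):
   spontaneous -> group 3; induced / pre-labour CS -> group 4

Parity is prior vaginal + prior cesarean births.  A record missing a field
that the decision path actually needs is *unclassifiable* and reports the
missing fields; fields not needed on the path taken (e.g. labour onset for a
woman with a prior cesarean at term) do not block classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd

TERM_WEEKS = 37  # completed weeks; GA < 37 is preterm

UNCLASSIFIABLE = 0  # sentinel group value in vectorized output

#: WHO reference bands for group-level cesarean rates (percent); groups with
#: no fixed band are benchmarked against the national average.
GROUP_CESAREAN_REFERENCE = {
    1: (10.0, 10.0),
    2: (20.0, 35.0),
    3: (3.0, 3.0),
    4: (15.0, 15.0),
    5: (50.0, 60.0),
    10: (30.0, 30.0),
}


@dataclass
class RobsonResult:
    group: Optional[int]  # 1..10, or None if unclassifiable
    missing_fields: List[str] = field(default_factory=list)

    @property
    def classifiable(self) -> bool:
        return self.group is not None


def classify_robson(plurality=None, presentation=None,
                    gestational_age_weeks=None, prior_cesarean_births=None,
                    prior_vaginal_births=None, labour_onset=None) -> RobsonResult:
    """Classify a single birth; any argument may be None (missing)."""

    def parity_at_least_one():
        # multiparity is established by either prior count >= 1, even when
        # the other is missing; nulliparity needs both counts present and zero
        if prior_cesarean_births is not None and prior_cesarean_births >= 1:
            return True
        if prior_vaginal_births is not None and prior_vaginal_births >= 1:
            return True
        if prior_cesarean_births is None or prior_vaginal_births is None:
            return None
        return False

    if plurality is None:
        return RobsonResult(None, ["plurality"])
    if plurality == "multiple":
        return RobsonResult(8)

    if presentation is None:
        return RobsonResult(None, ["presentation"])
    if presentation == "transverse_oblique":
        return RobsonResult(9)
    if presentation == "breech":
        multi = parity_at_least_one()
        if multi is None:
            return RobsonResult(
                None, ["prior_vaginal_births", "prior_cesarean_births"])
        return RobsonResult(7 if multi else 6)

    # single cephalic from here on
    if gestational_age_weeks is None:
        return RobsonResult(None, ["gestational_age_weeks"])
    if gestational_age_weeks < TERM_WEEKS:
        return RobsonResult(10)

    # term, single, cephalic
    if prior_cesarean_births is None:
        return RobsonResult(None, ["prior_cesarean_births"])
    if prior_cesarean_births >= 1:
        return RobsonResult(5)

    multi = parity_at_least_one()
    if multi is None:
        return RobsonResult(None, ["prior_vaginal_births"])
    if labour_onset is None:
        return RobsonResult(None, ["labour_onset"])
    if multi:
        return RobsonResult(3 if labour_onset == "spontaneous" else 4)
    return RobsonResult(1 if labour_onset == "spontaneous" else 2)


def classify_record(record) -> RobsonResult:
    """Classify a mapping/Series holding canonical live-birth fields."""
    def get(name):
        v = record.get(name) if hasattr(record, "get") else getattr(record, name)
        return None if v is None or v is pd.NA or v != v else v
    return classify_robson(
        plurality=get("plurality"), presentation=get("presentation"),
        gestational_age_weeks=get("gestational_age_weeks"),
        prior_cesarean_births=get("prior_cesarean_births"),
        prior_vaginal_births=get("prior_vaginal_births"),
        labour_onset=get("labour_onset"))


def classify_frame(births: pd.DataFrame) -> pd.Series:
    """Vectorized classification of a canonical live-birth frame.

    Returns an ``Int64`` series of group numbers with 0 marking
    unclassifiable records.
    """
    n = len(births)
    group = np.zeros(n, dtype=np.int64)

    plur = births["plurality"].astype("string")
    pres = births["presentation"].astype("string")
    ga = births["gestational_age_weeks"].astype("Float64")
    pcs = births["prior_cesarean_births"].astype("Float64")
    pvb = births["prior_vaginal_births"].astype("Float64")
    onset = births["labour_onset"].astype("string")

    pcs_np = pcs.to_numpy(dtype=float, na_value=np.nan)
    pvb_np = pvb.to_numpy(dtype=float, na_value=np.nan)
    ga_np = ga.to_numpy(dtype=float, na_value=np.nan)

    multi = np.where(
        (pcs_np >= 1) | (pvb_np >= 1), 1.0,
        np.where(np.isnan(pcs_np) | np.isnan(pvb_np), np.nan, 0.0))

    unresolved = np.ones(n, dtype=bool)

    def assign(mask, g):
        nonlocal unresolved
        m = np.asarray(mask, dtype=bool) & unresolved
        group[m] = g
        unresolved &= ~m

    def block(mask):
        """Mark records as unresolvable (stay unclassifiable)."""
        nonlocal unresolved
        unresolved &= ~np.asarray(mask, dtype=bool)

    plur_na = plur.isna().to_numpy()
    block(plur_na)
    assign((plur == "multiple").fillna(False).to_numpy(dtype=bool), 8)

    pres_na = pres.isna().to_numpy()
    block(pres_na)
    assign((pres == "transverse_oblique").fillna(False).to_numpy(dtype=bool), 9)

    breech = (pres == "breech").fillna(False).to_numpy(dtype=bool)
    block(breech & np.isnan(multi))
    assign(breech & (multi == 1), 7)
    assign(breech & (multi == 0), 6)

    block(np.isnan(ga_np))
    assign(ga_np < TERM_WEEKS, 10)

    block(np.isnan(pcs_np))
    assign(pcs_np >= 1, 5)

    block(np.isnan(multi))
    onset_na = onset.isna().to_numpy()
    block(onset_na)
    spont = (onset == "spontaneous").fillna(False).to_numpy(dtype=bool)
    assign((multi == 1) & spont, 3)
    assign((multi == 1) & ~spont, 4)
    assign((multi == 0) & spont, 1)
    assign((multi == 0) & ~spont, 2)

    return pd.Series(group, index=births.index, dtype="Int64", name="robson_group")


def robson_distribution(births: pd.DataFrame,
                        groups: Optional[pd.Series] = None) -> pd.DataFrame:
    """Per-group size, cesarean rate and relative contribution (percent).

    Unclassifiable births are excluded from numerator and denominator; the
    share excluded is reported separately by the caller as a completeness
    metric.  Groups with no births have size 0 and an *undefined* (NaN,
    flagged) cesarean rate rather than 0; relative contributions are
    undefined when no cesarean was performed at all.

    Returns a frame indexed by group 1..10 with columns ``n``, ``n_cesarean``,
    ``size_pct``, ``cesarean_rate_pct``, ``relative_contribution_pct``,
    ``undefined_rate``, ``undefined_contribution``.
    """
    if groups is None:
        groups = classify_frame(births)
    classified = groups.notna() & (groups != UNCLASSIFIABLE)
    sub = births.loc[classified]
    g = groups.loc[classified].astype(int)
    cesarean = (sub["delivery_mode"].astype("string") == "cesarean") \
        .fillna(False).to_numpy(dtype=bool)

    idx = pd.Index(range(1, 11), name="robson_group")
    n = pd.Series(0, index=idx, dtype=int)
    ncs = pd.Series(0, index=idx, dtype=int)
    counts = g.value_counts()
    n.loc[counts.index] = counts
    cs_counts = g[cesarean].value_counts()
    ncs.loc[cs_counts.index] = cs_counts

    total = int(n.sum())
    total_cs = int(ncs.sum())
    out = pd.DataFrame({"n": n, "n_cesarean": ncs})
    out["size_pct"] = np.where(total > 0, n / max(total, 1) * 100.0, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["cesarean_rate_pct"] = np.where(n > 0, ncs / n.replace(0, 1) * 100.0,
                                            np.nan)
        out["relative_contribution_pct"] = np.where(
            total_cs > 0, ncs / max(total_cs, 1) * 100.0, np.nan)
    out["undefined_rate"] = n == 0
    out["undefined_contribution"] = total_cs == 0
    return out
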