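"""Indicator arithmetic: proportions, rates, MMR, abortion estimate,
displacement medians and MHDI banding."""

import numpy as np
import pandas as pd
import pytest

import matvig as mv
from matvig.indicators import proportion_indicator, rate_indicator, exclusive_sus

from .conftest import make_births


@pytest.fixture(scope="module")
def cat():
    return mv.load_catalogue()


def test_low_birthweight_proportion_direct_arithmetic(cat):
    rows = [{"birthweight_g": 2400} for _ in range(12)]
    rows += [{"birthweight_g": 3200} for _ in range(88)]
    b = make_births(rows)
    v = proportion_indicator(cat.get("low_birthweight_pct"), b,
                             b["birthweight_g"] < 2500, ["birthweight_g"],
                             "110001", 2015)
    assert v.value == pytest.approx(12.0)
    assert (v.numerator, v.denominator) == (12, 100)


def test_missing_values_excluded_from_both_terms_and_flagged(cat):
    rows = [{"gestational_age_weeks": 34} for _ in range(18)]
    rows += [{"gestational_age_weeks": 39} for _ in range(72)]
    rows += [{"gestational_age_weeks": pd.NA} for _ in range(10)]
    b = make_births(rows)
    v = proportion_indicator(cat.get("preterm_pct"), b,
                             b["gestational_age_weeks"] < 37,
                             ["gestational_age_weeks"], "110001", 2015)
    assert v.value == pytest.approx(20.0)
    assert v.denominator == 90
    assert "excluded_missing:10" in v.flags


def test_mmr_direct_arithmetic_and_instability_flag(cat):
    deaths = pd.DataFrame({"is_maternal_death": [True, True]})
    births = make_births([{} for _ in range(100)])
    births = pd.concat([births] * 100, ignore_index=True)  # 10,000 births
    count_v, mmr_v = mv.mmr(deaths, births, "g", 2015, cat)
    assert count_v.value == 2
    assert mmr_v.value == pytest.approx(20.0)
    assert any(f.startswith("unstable") for f in mmr_v.flags)

    one = pd.DataFrame({"is_maternal_death": [True]})
    small = make_births([{} for _ in range(500)])
    _, v = mv.mmr(one, small, "g", 2015, cat)
    assert v.value == pytest.approx(200.0)
    assert any(f.startswith("unstable") for f in v.flags)


def test_mmr_zero_deaths_is_zero_and_meets_goal(cat):
    deaths = pd.DataFrame({"is_maternal_death": pd.Series([], dtype="boolean")})
    births = pd.concat([make_births([{} for _ in range(100)])] * 80,
                       ignore_index=True)
    _, v = mv.mmr(deaths, births, "g", 2015, cat)
    assert v.value == 0.0
    res = mv.compare(v, cat.get("mmr").reference)
    assert res.status == "meets"


def test_mmr_zero_births_with_deaths_is_undefined(cat):
    deaths = pd.DataFrame({"is_maternal_death": [True]})
    births = make_births([]).iloc[0:0]
    _, v = mv.mmr(deaths, births, "g", 2015, cat)
    assert v.undefined and v.value is None
    assert (v.numerator, v.denominator) == (1, 0)


def test_adolescent_fertility_rate_arithmetic(cat):
    v = rate_indicator(cat.get("adolescent_fertility_rate"), 300, 10000.0,
                       "g", 2015)
    assert v.value == pytest.approx(30.0)
    assert v.scale == "per_1000"


def test_missing_population_cell_is_undefined(cat):
    v = rate_indicator(cat.get("adolescent_fertility_rate"), 300, None,
                       "g", 2015)
    assert v.undefined
    assert "undefined:missing_population" in v.flags


def test_exclusive_sus_arithmetic_and_beneficiary_cap(cat):
    defn = cat.get("exclusive_sus_pct")
    v = exclusive_sus(defn, 50000.0, 10000.0, "g", 2015)
    assert v.value == pytest.approx(80.0)
    capped = exclusive_sus(defn, 50000.0, 55000.0, "g", 2015)
    assert capped.value == pytest.approx(0.0)
    assert "anomaly:beneficiaries_exceed_population" in capped.flags


def test_unsafe_abortion_two_step_correction(cat):
    corr = mv.AbortionCorrectionConfig(
        spontaneous_fraction_of_live_births=0.02,
        induced_not_hospitalized_multiplier=4.0)
    rate, ratio = mv.estimate_unsafe_abortions(
        120, corr, 100000.0, 1000, "g", 2015, cat)
    # spontaneous expectation = 0.02 * 1000 = 20; UA = (120-20)*4 = 400
    assert rate.meta["estimated_unsafe_abortions"] == pytest.approx(400.0)
    assert rate.value == pytest.approx(4.0)
    assert ratio.value == pytest.approx(40.0)
    assert rate.meta["multiplier"] == 4.0


def test_unsafe_abortion_identity_configuration_passthrough(cat):
    corr = mv.AbortionCorrectionConfig(
        spontaneous_fraction_of_live_births=0.0,
        induced_not_hospitalized_multiplier=1.0)
    rate, _ = mv.estimate_unsafe_abortions(75, corr, 50000.0, 2000, "g",
                                           2015, cat)
    assert rate.meta["estimated_unsafe_abortions"] == pytest.approx(75.0)


def test_unsafe_abortion_floor_at_zero_with_flag(cat):
    corr = mv.AbortionCorrectionConfig(
        spontaneous_fraction_of_live_births=0.05,
        induced_not_hospitalized_multiplier=3.0)
    rate, ratio = mv.estimate_unsafe_abortions(10, corr, 50000.0, 1000, "g",
                                               2015, cat)
    assert rate.value == 0.0
    assert "floor:admissions_below_spontaneous_expectation" in rate.flags
    assert ratio.value == 0.0


def test_unsafe_abortion_requires_explicit_config(cat):
    with pytest.raises(mv.ConfigError):
        mv.estimate_unsafe_abortions(10, None, 1000.0, 100, "g", 2015, cat)


def test_unsafe_abortion_monotone_in_admissions_and_multiplier(cat):
    pop, lb = 80000.0, 2000
    corr = mv.AbortionCorrectionConfig(
        spontaneous_fraction_of_live_births=0.03,
        induced_not_hospitalized_multiplier=3.0)
    rates = [mv.estimate_unsafe_abortions(n, corr, pop, lb, "g", 2015,
                                          cat)[0].value
             for n in (0, 40, 80, 160, 320)]
    assert rates == sorted(rates)
    by_mult = []
    for mult in (1.0, 2.0, 5.0):
        c = mv.AbortionCorrectionConfig(
            spontaneous_fraction_of_live_births=0.03,
            induced_not_hospitalized_multiplier=mult)
        by_mult.append(mv.estimate_unsafe_abortions(200, c, pop, lb, "g",
                                                    2015, cat)[0].value)
    assert by_mult == sorted(by_mult)


def _displacement_world(distances_km):
    """Births from muni A delivering in muni B (with-ICU facility)."""
    rows = []
    dist_rows = []
    for i, km in enumerate(distances_km):
        dest = f"22000{i+1}"
        rows.append({"residence_muni": "110001", "occurrence_muni": dest,
                     "facility_id": f"F{dest}B"})
        dist_rows += [
            {"muni_a": "110001", "muni_b": dest, "km": km},
            {"muni_a": dest, "muni_b": "110001", "km": km},
            {"muni_a": dest, "muni_b": dest, "km": 0.0},
        ]
    dist_rows.append({"muni_a": "110001", "muni_b": "110001", "km": 0.0})
    fac_rows = [{"facility_id": f"F22000{i+1}B", "muni": f"22000{i+1}",
                 "has_adult_icu": True} for i in range(len(distances_km))]
    fac_rows.append({"facility_id": "F110001A", "muni": "110001",
                     "has_adult_icu": False})
    empty = pd.DataFrame({"geo": [], "year": [], "count": []})
    ref = mv.ReferenceTables(
        population=pd.DataFrame({"geo": [], "year": [], "sex": [],
                                 "age_band": [], "count": []}),
        beneficiaries=empty.rename(columns={"count": "beneficiaries_f10_49"}),
        fhs=empty.rename(columns={"count": "fhs_covered_population"}),
        mhdi=pd.DataFrame({"geo": ["110001"], "mhdi": [0.7]}),
        distances=pd.DataFrame(dist_rows).drop_duplicates(
            subset=["muni_a", "muni_b"]),
        facilities=pd.DataFrame(fac_rows),
        estimates=pd.DataFrame({"geo": [], "year": [], "estimated_births": [],
                                "estimated_deaths": []}),
        investigation=pd.DataFrame({"geo": [], "year": [],
                                    "wca_deaths_total": [],
                                    "wca_deaths_investigated": [],
                                    "maternal_deaths_total": [],
                                    "maternal_deaths_investigated": []}),
        syphilis=empty.rename(columns={"count": "congenital_syphilis_cases"}),
    )
    return make_births(rows), ref


def test_median_displacement_odd_and_even_counts(cat):
    from matvig.indicators import median_displacement
    births, ref = _displacement_world([30.0, 50.0, 70.0])
    vals = median_displacement(births, ref, "110001", 2015, cat)
    with_icu = next(v for v in vals if v.category == "with_adult_icu")
    assert with_icu.value == pytest.approx(50.0)

    births, ref = _displacement_world([10.0, 20.0])
    vals = median_displacement(births, ref, "110001", 2015, cat)
    with_icu = next(v for v in vals if v.category == "with_adult_icu")
    assert with_icu.value == pytest.approx(15.0)


def test_all_births_at_home_leaves_median_undefined(cat):
    from matvig.indicators import median_displacement
    births, ref = _displacement_world([10.0])
    births["occurrence_muni"] = "110001"
    births["facility_id"] = "F110001A"
    vals = median_displacement(births, ref, "110001", 2015, cat)
    assert all(v.undefined for v in vals)


@pytest.mark.parametrize("value,band", [
    (0.650, "medium"),
    (0.499, "very_low"),
    (0.800, "very_high"),
    (0.500, "low"),
    (0.599, "low"),
    (0.600, "medium"),
    (0.700, "high"),
    (0.799, "high"),
    (0.0, "very_low"),
    (1.0, "very_high"),
])
def test_mhdi_banding_boundaries(value, band):
    assert mv.mhdi_band(value) == band


def test_mhdi_band_domain_error():
    with pytest.raises(mv.DomainError):
        mv.mhdi_band(1.2)
    with pytest.raises(mv.DomainError):
        mv.mhdi_band(-0.1)


def test_age_composition_sums_to_100_over_known(small_panel, catalogue,
                                                abortion_config):
    vals = mv.compute_unit(small_panel, "BR", 2015, catalogue=catalogue,
                           abortion_config=abortion_config)
    for ind in ("lb_by_maternal_age", "lb_by_race_color", "lb_by_education"):
        total = sum(v.value for v in vals if v.definition_id == ind)
        assert total == pytest.approx(100.0, abs=1e-9)


def test_scale_constant_rescales_linearly(cat):
    defn_1000 = cat.get("adolescent_fertility_rate")
    v = rate_indicator(defn_1000, 50, 10000.0, "g", 2015)
    assert v.value == pytest.approx(50 / 10000 * 1000)
    # same components under a percent-scaled definition differ by x10
    defn_pct = cat.get("fhs_coverage_pct")
    w = rate_indicator(defn_pct, 50, 10000.0, "g", 2015)
    assert w.value == pytest.approx(v.value / 10)
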