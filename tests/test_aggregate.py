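"""Hierarchy roll-up, benchmark logic and historical series."""

import pandas as pd
import pytest

import matvig as mv
from matvig.aggregate import national_value_map, similar_mhdi_municipalities
from matvig.catalogue import ReferenceStandard


@pytest.fixture(scope="module")
def muni_values(small_panel, catalogue, abortion_config):
    vals = []
    for m in small_panel.hierarchy.codes_at("municipality"):
        vals += mv.compute_unit(small_panel, m, 2015, catalogue=catalogue,
                                abortion_config=abortion_config)
    return vals


def test_state_mmr_is_component_rollup_not_mean_of_rates(tiny_hierarchy,
                                                         catalogue):
    vals = [
        mv.IndicatorValue("mmr", "110001", 2015, 20.0, numerator=2,
                          denominator=10000, scale="per_100k",
                          geo_level="municipality"),
        mv.IndicatorValue("mmr", "110002", 2015, 0.0, numerator=0,
                          denominator=10000, scale="per_100k",
                          geo_level="municipality"),
    ]
    out = mv.aggregate(vals, tiny_hierarchy, "ST1", catalogue)
    state = next(v for v in out if v.definition_id == "mmr")
    assert state.value == pytest.approx(10.0)          # not (20+0)/2
    assert state.numerator == 2 and state.denominator == 20000
    assert any(f.startswith("units_missing") for f in state.flags)


def test_rollup_equals_direct_pooled_computation(small_panel, catalogue,
                                                 abortion_config, muni_values):
    direct = {(v.definition_id, v.category): v
              for v in mv.compute_unit(small_panel, "BR", 2015,
                                       catalogue=catalogue,
                                       abortion_config=abortion_config)}
    rolled = mv.aggregate(muni_values, small_panel.hierarchy, "BR", catalogue)
    checked = 0
    for v in rolled:
        d = direct[(v.definition_id, v.category)]
        defn = catalogue.get(v.definition_id)
        if defn.kind in ("median", "index"):
            assert v.undefined        # recompute-from-records placeholder
            continue
        assert v.numerator == pytest.approx(d.numerator, abs=1e-9)
        if v.denominator is not None:
            assert v.denominator == pytest.approx(d.denominator, abs=1e-9)
        if v.value is None:
            assert d.value is None
        else:
            assert v.value == pytest.approx(d.value, abs=1e-9)
        checked += 1
    assert checked > 50


def test_rollup_is_associative_through_intermediate_levels(small_panel,
                                                           catalogue,
                                                           muni_values):
    h = small_panel.hierarchy
    states = h.codes_at("state")
    via_states = []
    for st in states:
        via_states += mv.aggregate(muni_values, h, st, catalogue)
    country_direct = mv.aggregate(muni_values, h, "BR", catalogue)
    by_key = {(v.definition_id, v.category): v for v in country_direct}
    sums = {}
    for v in via_states:
        if v.numerator is None:
            continue
        key = (v.definition_id, v.category)
        sums[key] = sums.get(key, 0.0) + v.numerator
    for key, total in sums.items():
        assert total == pytest.approx(by_key[key].numerator, abs=1e-9)


def test_mixed_years_are_a_contract_error(tiny_hierarchy, catalogue):
    vals = [mv.IndicatorValue("mmr", "110001", 2015, 0.0, numerator=0,
                              denominator=100, geo_level="municipality"),
            mv.IndicatorValue("mmr", "110002", 2016, 0.0, numerator=0,
                              denominator=100, geo_level="municipality")]
    with pytest.raises(mv.MatvigError):
        mv.aggregate(vals, tiny_hierarchy, "ST1", catalogue)


# --- benchmark logic ---------------------------------------------------------

def _val(v, ind="mmr", category=None, undefined=False):
    return mv.IndicatorValue(ind, "g", 2015, v, category=category,
                             undefined=undefined)


def test_mmr_threshold_is_strict_below_30(catalogue):
    std = catalogue.get("mmr").reference
    assert mv.compare(_val(25.0), std).status == "meets"
    assert mv.compare(_val(29.999), std).status == "meets"
    assert mv.compare(_val(30.0), std).status == "does_not_meet"
    assert mv.compare(_val(30.001), std).status == "does_not_meet"


def test_cesarean_range_10_to_15(catalogue):
    std = catalogue.get("cesarean_pct").reference
    assert mv.compare(_val(48.0, "cesarean_pct"), std).status == "above"
    assert mv.compare(_val(9.999, "cesarean_pct"), std).status == "below"
    assert mv.compare(_val(10.0, "cesarean_pct"), std).status == "within"
    assert mv.compare(_val(15.0, "cesarean_pct"), std).status == "within"
    assert mv.compare(_val(15.001, "cesarean_pct"), std).status == "above"


def test_preterm_meets_at_exact_boundary(catalogue):
    std = catalogue.get("preterm_pct").reference
    assert mv.compare(_val(10.0, "preterm_pct"), std).status == "meets"
    assert mv.compare(_val(10.001, "preterm_pct"), std).status == "does_not_meet"


def test_coverage_goal_passes_at_exactly_90(catalogue):
    std = catalogue.get("sinasc_coverage_pct").reference
    assert mv.compare(_val(90.0, "sinasc_coverage_pct"), std).status == "meets"
    assert mv.compare(_val(89.999, "sinasc_coverage_pct"), std).status == \
        "does_not_meet"


def test_incompleteness_fails_at_exactly_5(catalogue):
    std = catalogue.get("incompleteness_pct").reference
    assert mv.compare(_val(4.999, "incompleteness_pct"), std).status == "meets"
    assert mv.compare(_val(5.0, "incompleteness_pct"), std).status == \
        "does_not_meet"


def test_robson_group_bands_match_reference_rates(catalogue):
    std = catalogue.get("robson_group_cesarean_pct").reference
    expected = {"1": (10.0, 10.0), "2": (20.0, 35.0), "3": (3.0, 3.0),
                "4": (15.0, 15.0), "5": (50.0, 60.0), "10": (30.0, 30.0)}
    for g, (lo, hi) in expected.items():
        sub = std.for_category(g)
        assert (sub.lower, sub.upper) == (lo, hi)
    for g in ("6", "7", "8", "9"):
        assert std.for_category(g).kind == "national_average"
    # group 2 band behaviour
    assert mv.compare(_val(25.0, "robson_group_cesarean_pct", category="2"),
                      std).status == "within"
    assert mv.compare(_val(40.0, "robson_group_cesarean_pct", category="2"),
                      std).status == "above"


def test_national_average_comparison_and_undefined_values():
    std = ReferenceStandard(kind="national_average")
    assert mv.compare(_val(12.0), std, national_value=10.0).status == "above"
    assert mv.compare(_val(8.0), std, national_value=10.0).status == "below"
    assert mv.compare(_val(10.0), std, national_value=10.0).status == "within"
    assert mv.compare(_val(12.0), std).status == "not_applicable"
    assert mv.compare(_val(None, undefined=True),
                      ReferenceStandard(kind="fixed_threshold",
                                        direction="lower_better",
                                        value=30.0)).status == "not_applicable"


def test_every_catalogue_indicator_has_exactly_one_reference(catalogue):
    for defn in catalogue:
        assert isinstance(defn.reference, ReferenceStandard)
        assert defn.reference.kind in ("fixed_threshold", "range",
                                       "national_average", "band",
                                       "per_group", "none")


# --- historical series -------------------------------------------------------

@pytest.fixture(scope="module")
def multi_year_frame():
    cfg = mv.SimulationConfig(seed=3, n_municipalities=4, births_per_muni=60,
                              years=tuple(range(2012, 2021)))
    world = mv.generate_world(cfg)
    data = world.to_panel_data()
    ab = mv.AbortionCorrectionConfig.default()
    frames = []
    for year in range(2012, 2021):
        for m in data.hierarchy.codes_at("municipality"):
            frames.append(mv.values_to_frame(
                mv.compute_unit(data, m, year, abortion_config=ab)))
    return data, pd.concat(frames, ignore_index=True)


def test_nine_year_series_has_nine_rows(multi_year_frame):
    data, frame = multi_year_frame
    muni = data.hierarchy.codes_at("municipality")[0]
    series, warnings = mv.historical_series(frame, "mmr", muni,
                                            range(2012, 2021), data.hierarchy)
    assert len(series) == 9
    assert warnings == []
    assert list(series["year"]) == list(range(2012, 2021))


def test_same_region_comparator_includes_all_siblings(multi_year_frame):
    data, frame = multi_year_frame
    h = data.hierarchy
    muni = h.codes_at("municipality")[0]
    siblings = h.siblings(muni)
    series, _ = mv.historical_series(frame, "cesarean_pct", muni, [2015], h,
                                     comparator="same_region")
    assert set(series["geo_code"]) == {muni, *siblings}


def test_similar_mhdi_ties_break_by_code_order():
    mhdi = pd.DataFrame({
        "geo": ["100001", "100002", "100003", "100004", "100005"],
        "mhdi": [0.70, 0.72, 0.68, 0.72, 0.75],
    })
    picked = similar_mhdi_municipalities("100001", mhdi, k=3)
    # |d|: 100002 -> .02, 100003 -> .02, 100004 -> .02, 100005 -> .05
    assert picked == ["100002", "100003", "100004"]


def test_national_value_map_keys_by_indicator_and_category(small_panel,
                                                           catalogue,
                                                           abortion_config):
    country = mv.compute_unit(small_panel, "BR", 2015, catalogue=catalogue,
                              abortion_config=abortion_config)
    nat = national_value_map(country)
    assert ("cesarean_pct", None) in nat
    assert ("robson_group_size_pct", "1") in nat
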