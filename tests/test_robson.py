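"""Robson ten-group classifier and its three indicators."""

import numpy as np
import pytest

import matvig as mv
from matvig.robson import classify_frame, robson_distribution

from .conftest import make_births
from .oracle_robson import full_cross_product, oracle_group


@pytest.mark.parametrize("fields,expected", [
    # nulliparous term cephalic single in spontaneous labour
    (dict(plurality="single", presentation="cephalic",
          gestational_age_weeks=39, prior_cesarean_births=0,
          prior_vaginal_births=0, labour_onset="spontaneous"), 1),
    # multiple pregnancy takes precedence over GA and prior cesarean
    (dict(plurality="multiple", presentation="cephalic",
          gestational_age_weeks=35, prior_cesarean_births=1,
          prior_vaginal_births=0, labour_onset="spontaneous"), 8),
    # prior cesarean, term, cephalic, single: group 5 even without onset
    (dict(plurality="single", presentation="cephalic",
          gestational_age_weeks=38, prior_cesarean_births=1), 5),
    # transverse lie
    (dict(plurality="single", presentation="transverse_oblique",
          gestational_age_weeks=40), 9),
    # preterm single cephalic
    (dict(plurality="single", presentation="cephalic",
          gestational_age_weeks=33, prior_cesarean_births=0,
          prior_vaginal_births=2, labour_onset="induced"), 10),
    # multiparous breech with prior cesarean
    (dict(plurality="single", presentation="breech",
          prior_cesarean_births=1), 7),
])
def test_classifier_examples(fields, expected):
    assert mv.classify_robson(**fields).group == expected


def test_missing_presentation_is_unclassifiable_and_lists_field():
    res = mv.classify_robson(plurality="single", gestational_age_weeks=40)
    assert res.group is None
    assert res.missing_fields == ["presentation"]


def test_classifier_matches_bruteforce_oracle_on_full_cross_product():
    mismatches = []
    for plurality, presentation, ga, pcs, pvb, onset in full_cross_product():
        got = mv.classify_robson(
            plurality=plurality, presentation=presentation,
            gestational_age_weeks=ga, prior_cesarean_births=pcs,
            prior_vaginal_births=pvb, labour_onset=onset).group
        want = oracle_group(plurality, presentation, ga, pcs, pvb, onset)
        if got != want:
            mismatches.append((plurality, presentation, ga, pcs, pvb, onset,
                               got, want))
    assert not mismatches, mismatches[:5]


def test_vectorized_classifier_agrees_with_scalar(small_world):
    births = small_world.births
    vec = classify_frame(births)
    sample = births.sample(n=300, random_state=0)
    for idx, rec in sample.iterrows():
        scalar = mv.robson.classify_record(rec)
        expected = scalar.group if scalar.group is not None else 0
        assert vec.loc[idx] == expected


def test_every_record_in_exactly_one_group_or_unclassifiable(small_world):
    groups = classify_frame(small_world.births)
    assert groups.notna().all()
    assert set(groups.unique()) <= set(range(0, 11))


def test_distribution_hand_example():
    rows = []
    for i in range(6):  # group 1, one cesarean
        rows.append(dict(plurality="single", presentation="cephalic",
                         gestational_age_weeks=39, prior_cesarean_births=0,
                         prior_vaginal_births=0, labour_onset="spontaneous",
                         delivery_mode="cesarean" if i == 0 else "vaginal"))
    for _ in range(4):  # group 5, all cesarean
        rows.append(dict(plurality="single", presentation="cephalic",
                         gestational_age_weeks=39, prior_cesarean_births=1,
                         prior_vaginal_births=0, labour_onset="induced",
                         delivery_mode="cesarean"))
    dist = robson_distribution(make_births(rows))
    assert dist.loc[1, "size_pct"] == pytest.approx(60.0)
    assert dist.loc[5, "size_pct"] == pytest.approx(40.0)
    assert dist.loc[1, "cesarean_rate_pct"] == pytest.approx(100 / 6)
    assert dist.loc[5, "cesarean_rate_pct"] == pytest.approx(100.0)
    assert dist.loc[1, "relative_contribution_pct"] == pytest.approx(20.0)
    assert dist.loc[5, "relative_contribution_pct"] == pytest.approx(80.0)
    assert dist["size_pct"].sum() == pytest.approx(100.0, abs=1e-9)
    assert dist.loc[[1, 5], "relative_contribution_pct"].sum() == \
        pytest.approx(100.0, abs=1e-9)


def test_no_cesareans_flags_contributions_undefined_not_zero():
    rows = [dict(plurality="single", presentation="cephalic",
                 gestational_age_weeks=39, prior_cesarean_births=0,
                 prior_vaginal_births=0, labour_onset="spontaneous",
                 delivery_mode="vaginal") for _ in range(5)]
    dist = robson_distribution(make_births(rows))
    assert dist.loc[1, "cesarean_rate_pct"] == 0.0
    assert dist["undefined_contribution"].all()
    assert dist["relative_contribution_pct"].isna().all()


def test_singleton_cesarean_birth_dominates_every_metric():
    rows = [dict(plurality="single", presentation="cephalic",
                 gestational_age_weeks=40, prior_cesarean_births=0,
                 prior_vaginal_births=0, labour_onset="induced",
                 delivery_mode="cesarean")]
    dist = robson_distribution(make_births(rows))
    assert dist.loc[2, "size_pct"] == pytest.approx(100.0)
    assert dist.loc[2, "cesarean_rate_pct"] == pytest.approx(100.0)
    assert dist.loc[2, "relative_contribution_pct"] == pytest.approx(100.0)
    assert dist.loc[1, "size_pct"] == 0.0
    assert dist.loc[1, "undefined_rate"]


def test_overall_cesarean_rate_is_size_weighted_group_rates(small_world):
    births = small_world.births
    groups = classify_frame(births)
    dist = robson_distribution(births, groups)
    classified = births[(groups > 0).to_numpy(dtype=bool)]
    overall = (classified["delivery_mode"] == "cesarean").mean() * 100
    weighted = np.nansum(dist["size_pct"] * dist["cesarean_rate_pct"]) / 100
    assert weighted == pytest.approx(overall, abs=1e-9)
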