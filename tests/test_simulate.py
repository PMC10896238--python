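"""Synthetic-world generator: determinism, degenerate configs, internal
consistency and profile generation."""

import numpy as np
import pandas as pd
import pytest

import matvig as mv
from matvig.robson import classify_frame
from matvig.simulate import calibrate_group_cs


def test_same_config_gives_identical_frames():
    cfg = mv.SimulationConfig(seed=42, n_municipalities=3, births_per_muni=150)
    w1, w2 = mv.generate_world(cfg), mv.generate_world(cfg)
    pd.testing.assert_frame_equal(w1.births, w2.births)
    pd.testing.assert_frame_equal(w1.deaths, w2.deaths)
    pd.testing.assert_frame_equal(w1.admissions, w2.admissions)
    pd.testing.assert_frame_equal(w1.truth, w2.truth)


def test_different_seed_gives_different_data():
    a = mv.generate_world(mv.SimulationConfig(seed=1, n_municipalities=2,
                                              births_per_muni=100))
    b = mv.generate_world(mv.SimulationConfig(seed=2, n_municipalities=2,
                                              births_per_muni=100))
    assert not a.births.equals(b.births)


def test_zero_cesarean_rate_world_is_all_vaginal():
    cfg = mv.SimulationConfig(
        seed=9, n_municipalities=2, births_per_muni=200,
        true_rates=mv.TrueRates(cesarean_rate=0.0))
    w = mv.generate_world(cfg)
    assert (w.births["delivery_mode"] == "vaginal").all()
    assert not (w.births["labour_onset"] == "cesarean_before_labour").any()


def test_robson_mix_must_sum_to_one():
    with pytest.raises(Exception, match="sum to 1"):
        mv.SimulationConfig(robson_mix=(0.5, 0.5, 0.1, 0, 0, 0, 0, 0, 0, 0))


def test_infeasible_preterm_rate_is_config_error():
    # group 10 alone is 20% of births but only 5% may be preterm
    mix = (0.20, 0.15, 0.20, 0.08, 0.12, 0.02, 0.01, 0.01, 0.01, 0.20)
    with pytest.raises(mv.ConfigError, match="preterm"):
        mv.SimulationConfig(robson_mix=mix,
                            true_rates=mv.TrueRates(preterm_rate=0.05))


def test_expected_maternal_deaths_track_generating_mmr():
    cfg = mv.SimulationConfig(
        seed=1, n_municipalities=4, births_per_muni=1000,
        true_rates=mv.TrueRates(mmr_per_100k=100.0))
    w = mv.generate_world(cfg)
    n_mat = int((w.deaths["is_maternal_death"] == True).sum())  # noqa: E712
    # expectation 4; allow a generous Poisson band
    assert 0 <= n_mat <= 12
    assert w.truth_value("BR", "mmr_per_100k") == 100.0


@pytest.mark.parametrize("target", list(range(1, 11)))
def test_generated_profiles_classify_into_their_target_group(target):
    rng = np.random.default_rng(123 + target)
    for _ in range(50):
        profile = mv.generate_robson_profile(target, rng)
        assert mv.classify_robson(**profile).group == target


def test_group_cs_calibration_hits_target_exactly():
    mix = mv.simulate.DEFAULT_ROBSON_MIX
    for target in (0.2, 0.45, 0.56, 0.8):
        p = calibrate_group_cs(mix, target)
        overall = sum(mix[g - 1] * p[g] for g in range(1, 11))
        assert overall == pytest.approx(target, abs=1e-9)
    assert all(v == 0.0 for v in calibrate_group_cs(mix, 0.0).values())
    assert all(v == 1.0 for v in calibrate_group_cs(mix, 1.0).values())


def test_delivery_admissions_match_public_births(small_world):
    # one public delivery admission is generated per public-payer birth
    adm = small_world.admissions
    n_deliveries = int((adm["admission_type"] == "delivery").sum())
    n_births = len(small_world.births)
    sus = small_world.config.true_rates.exclusive_sus_share
    se = 4 * np.sqrt(sus * (1 - sus) / n_births)
    assert abs(n_deliveries / n_births - sus) < se
    assert (adm.loc[adm["admission_type"] == "delivery", "payer"]
            == "public").all()


def test_maternal_deaths_subset_of_wca_deaths(small_world):
    d = small_world.deaths
    assert (d["is_maternal_death"].isin([True, False])).all()
    n_mat = int((d["is_maternal_death"] == True).sum())  # noqa: E712
    assert n_mat <= len(d)
    # cross-field contract: cause class consistent with the maternal flag
    mat = d[d["is_maternal_death"] == True]  # noqa: E712
    assert (mat["obstetric_cause_class"] != "not_applicable").all()
    non = d[d["is_maternal_death"] == False]  # noqa: E712
    assert (non["obstetric_cause_class"] == "not_applicable").all()


def test_generated_world_passes_schema_validation(tmp_path, small_world):
    small_world.write(tmp_path / "w")
    from matvig.io import canonical_schema_map, load_table
    from matvig.geo import GeoHierarchy
    h = GeoHierarchy.load(tmp_path / "w" / "hierarchy.csv")
    for fname, kind in (("live_births.csv", "live_birth"),
                        ("deaths.csv", "maternal_death"),
                        ("hospitalizations.csv", "hospitalization")):
        res = load_table(tmp_path / "w" / fname, canonical_schema_map(kind),
                         kind, hierarchy=h)
        assert res.n_rejected_rows == 0, res.rejections.head()


def test_icu_days_never_exceed_length_of_stay(small_world):
    adm = small_world.admissions
    assert (adm["icu_days"] <= adm["length_of_stay_days"]).all()


def test_truth_ledger_covers_every_municipality(small_world):
    munis = small_world.hierarchy.codes_at("municipality")
    t = small_world.truth
    for m in munis:
        assert t[(t["geo"] == m) & (t["parameter"] == "cesarean_rate")].shape[0] == 1


def test_robson_groups_in_world_follow_the_mix(small_world):
    groups = classify_frame(small_world.births)
    classified = groups[groups > 0]
    n = len(classified)
    mix = small_world.config.robson_mix
    for g in range(1, 11):
        share = (classified == g).mean()
        se = 4 * np.sqrt(mix[g - 1] * (1 - mix[g - 1]) / n)
        assert abs(share - mix[g - 1]) < max(se, 0.02)
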