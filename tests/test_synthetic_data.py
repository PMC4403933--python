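"""Effect-model transcription and simulator behaviour."""

import math
from dataclasses import replace

import numpy as np
import pytest

from bpqc import cuff_matching as cm
from bpqc import qc_battery as qb
from bpqc.survey_data import CuffSpec
from bpqc.synthetic_data import (
    ConfigError,
    FactorEffect,
    ObserverModel,
    SimulationConfig,
    default_effect_model,
    inject_misscuffing,
    simulate_survey,
)


class TestEffectModel:
    def test_point_effects(self):
        model = default_effect_model()
        assert model["talking"] == FactorEffect(17, 17, 13, 13)
        assert model["cold_room"] == FactorEffect(14, 14, 15, 15)
        assert model["arm_below_heart"] == FactorEffect(10, 10, 10, 10)

    def test_range_effects_and_directions(self):
        model = default_effect_model()
        assert (model["cuff_too_large"].sbp_low, model["cuff_too_large"].sbp_high) == (-30, -10)
        assert (model["heavy_exercise"].sbp_low, model["heavy_exercise"].sbp_high) == (-20, -18)
        assert (model["no_rest"].sbp_low, model["no_rest"].sbp_high) == (10, 20)
        # left arm lowers systolic but nudges diastolic up
        assert model["left_arm"].sbp_high < 0 < model["left_arm"].dbp_low

    def test_unreported_diastolic_effect_is_zero(self):
        assert default_effect_model()["cuff_over_clothing"].dbp_high == 0

    def test_extreme_magnitudes_are_separate_factors(self):
        model = default_effect_model()
        assert model["full_bladder"].sbp_high == 15
        assert model["full_bladder_extreme"].sbp_low == 40
        assert model["cuff_too_small_extreme"].sbp_low == 30

    def test_midpoint_and_uniform_draws(self):
        e = FactorEffect(10, 20, 14, 14)
        assert e.draw("sbp", "midpoint", 0.77) == 15.0
        assert e.draw("sbp", "uniform_in_range", 0.5) == 15.0
        assert e.draw("sbp", "uniform_in_range", 0.0) == 10.0
        assert e.draw("dbp", "midpoint", 0.2) == 14.0

    def test_inverted_range_rejected(self):
        with pytest.raises(ConfigError):
            FactorEffect(5, 3, 0, 0)


class TestSimulateSurvey:
    def test_identical_seeds_identical_datasets(self):
        cfg = SimulationConfig(n_participants=50, seed=123)
        assert simulate_survey(cfg) == simulate_survey(cfg)

    def test_different_seeds_differ(self):
        cfg = SimulationConfig(n_participants=50, seed=123)
        assert simulate_survey(cfg) != simulate_survey(replace(cfg, seed=124))

    def test_degenerate_config_gives_constant_readings(self):
        cfg = SimulationConfig(
            n_participants=10,
            true_sbp_mean=120,
            true_sbp_sd=0,
            true_dbp_mean=70,
            true_dbp_sd=0,
            within_person_sd=0,
            seed=0,
        )
        ds = simulate_survey(cfg)
        values = {(r.sbp, r.dbp) for p in ds.participants for r in p.readings}
        assert values == {(120, 70)}

    def test_full_zero_preference_on_mercury(self):
        cfg = SimulationConfig(
            n_participants=100,
            device_type="mercury",
            observer=ObserverModel(zero_preference_prob=1.0),
            seed=2,
        )
        counts = qb.terminal_digit_counts(simulate_survey(cfg), "SBP")
        assert counts[0] == counts.sum()

    def test_mercury_rounding_gives_even_digits(self):
        cfg = SimulationConfig(n_participants=300, device_type="mercury", seed=3)
        for pressure in ("SBP", "DBP"):
            counts = qb.terminal_digit_counts(simulate_survey(cfg), pressure)
            assert counts[[1, 3, 5, 7, 9]].sum() == 0

    def test_talking_effect_recovered_with_common_random_numbers(self):
        cfg = SimulationConfig(n_participants=2000, seed=11)
        silent = simulate_survey(cfg)
        talking = simulate_survey(replace(cfg, factor_prevalence={"talking": 1.0}))

        def mean_sbp(ds):
            return np.mean([r.sbp for p in ds.participants for r in p.readings])

        assert mean_sbp(talking) - mean_sbp(silent) == pytest.approx(17.0, abs=1.0)

    def test_copy_probability_recovered(self):
        cfg = SimulationConfig(
            n_participants=1000,
            within_person_sd=10.0,
            observer=ObserverModel(identical_copy_prob=0.3),
            seed=21,
        )
        stats = qb.identical_pairs(simulate_survey(cfg))
        se = math.sqrt(0.3 * 0.7 / 1000)
        for pair in ("1-2", "2-3"):
            assert stats.proportion("SBP", pair) == pytest.approx(0.3, abs=3 * se)

    def test_zero_preference_recovered(self):
        cfg = SimulationConfig(
            n_participants=1000,
            observer=ObserverModel(zero_preference_prob=0.3),
            seed=22,
        )
        counts = qb.terminal_digit_counts(simulate_survey(cfg), "SBP")
        result = qb.digit_chisq_test(counts, "oscillometric")
        z_hat = qb.estimate_zero_preference(result)
        p0 = 0.3 + 0.7 * 0.1  # digit-zero share under the mixture
        se = math.sqrt(p0 * (1 - p0) / 3000) / 0.9
        assert z_hat == pytest.approx(0.3, abs=3 * se)

    @pytest.mark.parametrize(
        "bad",
        [
            {"n_participants": 0},
            {"within_person_sd": -1.0},
            {"effect_draw": "mode"},
            {"factor_prevalence": {"talking": 1.5}},
            {"factor_prevalence": {"whistling": 0.1}},
            {"device_type": "wrist"},
        ],
    )
    def test_invalid_config_rejected_before_sampling(self, bad):
        with pytest.raises(ConfigError):
            simulate_survey(SimulationConfig(**bad))

    def test_observer_probabilities_validated(self):
        with pytest.raises(ConfigError):
            ObserverModel(zero_preference_prob=1.2)


class TestInjectMisscuffing:
    def test_fraction_zero_is_identity(self):
        ds = simulate_survey(SimulationConfig(n_participants=100, seed=5))
        assert inject_misscuffing(ds, 0.0, seed=1) == ds

    def test_fraction_one_too_small_misscuffs_everyone_classifiable(self):
        # arm circumferences concentrated at ~30 cm so the small cuff always exists
        cfg = SimulationConfig(
            n_participants=100, seed=6, arm_circ_mean=30.0, arm_circ_sd=1.0
        )
        injected = inject_misscuffing(simulate_survey(cfg), 1.0, "too_small", seed=2)
        report = cm.misscuff_report(injected)
        assert report.n_too_small == report.n_classified == 100

    def test_partial_fraction_recovered(self):
        cfg = SimulationConfig(n_participants=500, seed=7)
        injected = inject_misscuffing(simulate_survey(cfg), 0.2, "too_small", seed=3)
        report = cm.misscuff_report(injected)
        se = math.sqrt(0.2 * 0.8 / 500)
        assert report.proportion == pytest.approx(0.2, abs=3 * se)

    def test_too_large_direction_raises_other_branch(self):
        cfg = SimulationConfig(
            n_participants=100, seed=8, arm_circ_mean=25.0, arm_circ_sd=1.0
        )
        injected = inject_misscuffing(simulate_survey(cfg), 1.0, "too_large", seed=4)
        report = cm.misscuff_report(injected)
        assert report.n_too_large == report.n_classified

    def test_cuff_effect_applied_to_readings(self):
        cfg = SimulationConfig(
            n_participants=200,
            seed=9,
            within_person_sd=0.0,
            arm_circ_mean=30.0,
            arm_circ_sd=1.0,
        )
        base = simulate_survey(cfg)
        injected = inject_misscuffing(base, 1.0, "too_small", seed=5)

        def mean_sbp(ds):
            return np.mean([r.sbp for p in ds.participants for r in p.readings])

        # midpoint of the too-small-cuff systolic range is +7.5 mmHg
        assert mean_sbp(injected) - mean_sbp(base) == pytest.approx(7.5, abs=0.6)

    def test_impossible_direction_skipped_and_logged(self):
        cfg = SimulationConfig(
            n_participants=20,
            seed=10,
            arm_circ_mean=18.0,
            arm_circ_sd=0.5,  # below every larger cuff: no smaller cuff exists
        )
        ds = simulate_survey(cfg)
        injected = inject_misscuffing(ds, 1.0, "too_small", seed=6)
        assert len(injected.log.warnings) > 0
        assert cm.misscuff_report(injected).n_too_small == 0

    def test_bad_fraction_rejected(self):
        ds = simulate_survey(SimulationConfig(n_participants=10, seed=1))
        with pytest.raises(ConfigError):
            inject_misscuffing(ds, 1.5)
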