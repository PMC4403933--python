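"""Digit-preference tests, identical-reading stats, missingness, flags."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bpqc import qc_battery as qb
from bpqc import survey_data as sd
from conftest import make_participant


def brute_force_chi2(counts, support):
    """From-definition chi-square: sum over the support of (O-E)^2/E."""
    n = sum(counts[d] for d in support)
    e = n / len(support)
    return sum((counts[d] - e) ** 2 / e for d in support)


class TestTerminalDigitCounts:
    def test_all_zero_digits_counted_per_pressure(self, make_dataset):
        ds = make_dataset(
            [
                make_participant(f"p{i}", [(120, 80), (130, 90), (110, 70)])
                for i in range(3)
            ]
        )
        counts = qb.terminal_digit_counts(ds, "SBP")
        assert counts[0] == 9 and counts.sum() == 9

    def test_mixed_digits(self, make_dataset):
        ds = make_dataset([make_participant("p1", [(120, 80), (134, 80), (142, 80)])])
        counts = qb.terminal_digit_counts(ds, "SBP")
        assert counts[0] == 1 and counts[4] == 1 and counts[2] == 1

    def test_missing_readings_skipped(self, make_dataset):
        ds = make_dataset([make_participant("p1", [(121, 81), (None, 83), (125, None)])])
        assert qb.terminal_digit_counts(ds, "SBP").sum() == 2
        assert qb.terminal_digit_counts(ds, "DBP").sum() == 2

    def test_all_missing_is_an_error(self, make_dataset):
        ds = make_dataset([make_participant("p1", [(None, None)] * 3)])
        with pytest.raises(ValueError):
            qb.terminal_digit_counts(ds, "SBP")

    def test_pooling_over_concatenation_is_additive(self, make_dataset):
        a = [make_participant("a1", [(120, 80), (134, 82), (142, 78)])]
        b = [make_participant("b1", [(117, 81), (129, 85), (133, 79)])]
        ds_a, ds_b, ds_ab = make_dataset(a), make_dataset(b), make_dataset(a + b)
        np.testing.assert_array_equal(
            qb.terminal_digit_counts(ds_ab, "SBP"),
            qb.terminal_digit_counts(ds_a, "SBP") + qb.terminal_digit_counts(ds_b, "SBP"),
        )


class TestDigitChisqTest:
    def test_uniform_even_counts_mercury(self):
        counts = [20, 0, 20, 0, 20, 0, 20, 0, 20, 0]
        r = qb.digit_chisq_test(counts, "mercury")
        assert r.chi2 == 0.0
        assert r.p_value == pytest.approx(1.0)
        assert r.support.digits == qb.MERCURY_DIGITS
        assert r.df == 4

    def test_known_statistic_against_closed_form(self):
        # counts (50,10,10,10,20) on the even digits, n=100: chi2 = 60, df 4.
        counts = [50, 0, 10, 0, 10, 0, 10, 0, 20, 0]
        r = qb.digit_chisq_test(counts, "mercury")
        assert r.chi2 == pytest.approx(60.0, abs=1e-12)
        assert r.df == 4
        # survival function of chi-square with 4 df has the closed form
        # exp(-x/2) * (1 + x/2); independent of the implementation's route
        assert r.p_value == pytest.approx(math.exp(-30.0) * 31.0, rel=1e-9)

    def test_mercury_odd_digits_fall_back_to_full_support(self):
        counts = [30, 5, 20, 0, 15, 0, 10, 0, 15, 5]
        r = qb.digit_chisq_test(counts, "mercury")
        assert r.support.digits == qb.ALL_DIGITS
        assert r.df == 9
        assert r.off_support_proportion == pytest.approx(0.10)

    def test_chi2_matches_brute_force_on_random_counts(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            counts = rng.integers(0, 60, size=10)
            counts[0] += 1  # never empty
            r = qb.digit_chisq_test(counts, "oscillometric")
            assert r.chi2 == pytest.approx(
                brute_force_chi2(counts, qb.ALL_DIGITS), abs=1e-9
            )

    def test_p_value_matches_monte_carlo_null(self):
        # moderate case with expected counts of 100 per digit
        counts = np.array([110, 95, 100, 105, 90, 100, 108, 92, 103, 97])
        r = qb.digit_chisq_test(counts, "oscillometric")
        rng = np.random.default_rng(5)
        reps = 100_000
        sims = rng.multinomial(int(counts.sum()), [0.1] * 10, size=reps)
        e = counts.sum() / 10
        chi2_sims = ((sims - e) ** 2 / e).sum(axis=1)
        p_mc = float((chi2_sims >= r.chi2 - 1e-9).mean())
        se = math.sqrt(p_mc * (1 - p_mc) / reps)
        assert abs(r.p_value - p_mc) <= 3 * se

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            qb.digit_chisq_test([5, -1, 0, 0, 0, 0, 0, 0, 0, 0], "oscillometric")

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(k1=st.integers(0, 200), k2=st.integers(0, 200))
    def test_zero_digit_excess_never_decreases_chi2(self, k1, k2):
        lo, hi = sorted((k1, k2))
        base = np.full(10, 30)
        less, more = base.copy(), base.copy()
        less[0] += lo
        more[0] += hi
        r_less = qb.digit_chisq_test(less, "oscillometric")
        r_more = qb.digit_chisq_test(more, "oscillometric")
        assert r_more.chi2 >= r_less.chi2 - 1e-12


class TestCountsFromPercentages:
    def test_degenerate(self):
        counts = qb.counts_from_percentages([100] + [0] * 9, 50)
        assert counts[0] == 50 and counts.sum() == 50

    def test_uniform_apportionment(self):
        counts = qb.counts_from_percentages([10.0] * 10, 333)
        assert counts.sum() == 333
        assert set(counts) <= {33, 34}

    def test_survey_a_row_sums_exactly(self):
        row = sd.load_fixture("table4").set_index("survey_id").loc["A"]
        pcts = [row[f"pct_digit_{d}"] for d in range(10)]
        counts = qb.counts_from_percentages(pcts, 369)  # 123 participants x 3
        assert counts.sum() == 369

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        raw=st.lists(
            st.floats(0.01, 1.0, allow_nan=False), min_size=10, max_size=10
        ),
        total=st.floats(96, 104, allow_nan=False),
        n=st.integers(0, 5000),
    )
    def test_counts_always_sum_to_n(self, raw, total, n):
        scale = total / sum(raw)
        pcts = [r * scale for r in raw]
        assert qb.counts_from_percentages(pcts, n).sum() == n

    def test_bad_total_rejected(self):
        with pytest.raises(ValueError):
            qb.counts_from_percentages([5.0] * 10, 100)


class TestIdenticalPairs:
    def test_identical_triplets_give_all_ones(self, make_dataset):
        ds = make_dataset(
            [make_participant(f"p{i}", [(120, 80)] * 3) for i in range(5)]
        )
        stats = qb.identical_pairs(ds)
        assert stats.proportions() == [1.0] * 4

    def test_single_equal_pair_among_four(self, make_dataset):
        ds = make_dataset(
            [
                make_participant("p1", [(120, 80), (120, 82), (118, 78)]),
                make_participant("p2", [(121, 81), (123, 83), (119, 79)]),
                make_participant("p3", [(131, 84), (133, 86), (129, 82)]),
                make_participant("p4", [(141, 87), (143, 89), (139, 85)]),
            ]
        )
        stats = qb.identical_pairs(ds)
        assert stats.proportion("SBP", "1-2") == pytest.approx(0.25)
        assert stats.stats[("SBP", "1-2")].denominator == 4

    def test_incomplete_pairs_drop_from_denominator(self, make_dataset):
        ds = make_dataset(
            [
                make_participant("p1", [(120, 80), (120, 80), (118, 78)]),
                make_participant("p2", [(121, 81), (None, None), (119, 79)]),
            ]
        )
        stats = qb.identical_pairs(ds)
        assert stats.stats[("SBP", "1-2")].denominator == 1
        assert stats.proportion("SBP", "1-2") == 1.0

    def test_zero_denominator_undefined(self, make_dataset):
        ds = make_dataset([make_participant("p1", [(120, 80), (None, None), (118, 78)])])
        stats = qb.identical_pairs(ds)
        assert stats.proportion("SBP", "1-2") is None


class TestMissingness:
    def test_complete_dataset_all_zero(self, make_dataset):
        ds = make_dataset(
            [
                make_participant(
                    "p1",
                    [(120, 80), (122, 82), (118, 78)],
                    arm_circumference_cm=30.0,
                    cuff_label="22–32 cm",
                    room_temp_c=22.0,
                )
            ]
        )
        assert all(v == 0.0 for v in qb.missingness(ds).proportions.values())

    def test_one_in_ten_missing(self, make_dataset):
        ps = [
            make_participant(
                f"p{i}",
                [(120, 80), (122, 82), (118, 78 if i else None)],
                arm_circumference_cm=30.0,
                cuff_label="22–32 cm",
                room_temp_c=22.0,
            )
            for i in range(10)
        ]
        report = qb.missingness(make_dataset(ps))
        assert report.proportions["dbp3"] == pytest.approx(0.1)
        assert report.proportions["sbp3"] == 0.0


def fixture_digit_result(survey_id, n_readings, table="table4"):
    row = sd.load_fixture(table).set_index("survey_id").loc[survey_id]
    counts = qb.counts_from_percentages(
        [row[f"pct_digit_{d}"] for d in range(10)], n_readings
    )
    return qb.digit_chisq_test(counts, "mercury")


def fixture_identical_stats(survey_id):
    row = sd.load_fixture("table3").set_index("survey_id").loc[survey_id]
    stats = {}
    for pressure in ("SBP", "DBP"):
        for pair, col in (("1-2", "12"), ("2-3", "23")):
            pct = float(row[f"pct_identical_{pressure.lower()}_{col}"])
            stats[(pressure, pair)] = qb.PairStat(proportion=pct / 100, denominator=0)
    return qb.IdenticalPairStats(stats=stats)


class TestFlagQuality:
    def test_survey_b_raises_both_flags(self):
        # 111 participants x 3 readings; zero preference and high identicals
        digit = fixture_digit_result("B", 333)
        flags = qb.flag_quality(digit, fixture_identical_stats("B"))
        assert flags == {"digit_preference", "identical_readings"}

    def test_survey_a_raises_identical_flag_only(self):
        digit = fixture_digit_result("A", 369)
        flags = qb.flag_quality(digit, fixture_identical_stats("A"))
        assert flags == {"identical_readings"}

    def test_clean_statistics_raise_nothing(self, make_dataset):
        digit = qb.digit_chisq_test([30] * 10, "oscillometric")
        ds = make_dataset(
            [
                make_participant("p1", [(121, 81), (123, 83), (119, 79)]),
                make_participant("p2", [(134, 86), (136, 88), (132, 84)]),
            ]
        )
        assert qb.flag_quality(digit, qb.identical_pairs(ds)) == set()
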