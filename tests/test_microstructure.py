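"""ILIs, bouts, frequency, preference, circadian bins, intake correlation."""

import datetime as dt

import numpy as np
import pytest

from lickometry import (
    LickGenParams,
    ParameterError,
    UndefinedMetricError,
    generate_lick_train,
    intake_correlation,
    interlick_intervals,
    lick_frequency,
    preference_index,
    segment_bouts,
    simulate_intake_sessions,
    time_binned_counts,
)


class TestInterlickIntervals:
    @pytest.mark.parametrize(
        "times,expected",
        [
            ([0.0, 200.0, 400.0], [200.0, 200.0]),
            ([42.0], []),
            ([0.0, 100.0, 350.0], [100.0, 250.0]),
            ([], []),
        ],
    )
    def test_successive_differences(self, times, expected):
        assert interlick_intervals(times).tolist() == expected

    def test_length_is_n_minus_one(self, default_train):
        ilis = interlick_intervals(default_train.onsets)
        assert ilis.size == default_train.n_licks - 1
        assert ilis.min() >= LickGenParams().refractory_floor - 1e-9


def brute_force_partition(times, bout_break):
    """Direct scan partition oracle."""
    bouts = []
    current = [times[0]]
    for prev, cur in zip(times[:-1], times[1:]):
        if cur - prev > bout_break:
            bouts.append(current)
            current = []
        current.append(cur)
    bouts.append(current)
    return bouts


class TestBoutSegmentation:
    def test_uniform_fast_licking_is_one_bout(self):
        times = np.arange(50) * 120.0
        bouts = segment_bouts(times)
        assert bouts.n_bouts == 1
        assert bouts.licks_per_bout.tolist() == [50]

    def test_long_gap_splits_bouts(self):
        times = np.array([0.0, 120.0, 240.0, 5000.0, 5120.0])
        bouts = segment_bouts(times, bout_break=1000.0)
        assert bouts.licks_per_bout.tolist() == [3, 2]
        assert bouts.inter_bout_intervals.tolist() == [4760.0]

    def test_matches_gap_partition_oracle_on_100_seeded_instances(self):
        """Partition property: every lick in exactly one bout, sizes equal
        to an independent direct-scan partition."""
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(1, 200))
            gaps = rng.choice([80.0, 150.0, 2500.0], size=n, p=[0.6, 0.3, 0.1])
            times = np.cumsum(gaps)
            brk = float(rng.choice([500.0, 1000.0, 2000.0]))
            got = segment_bouts(times, bout_break=brk)
            want = brute_force_partition(list(times), brk)
            assert got.licks_per_bout.tolist() == [len(b) for b in want]
            assert got.licks_per_bout.sum() == n
            assert got.bout_onsets.tolist() == [b[0] for b in want]
            assert got.bout_offsets.tolist() == [b[-1] for b in want]


class TestLickFrequency:
    def test_uniform_session_rate(self):
        times = np.linspace(0, 10_000, 85, endpoint=False)
        prof = lick_frequency(times, window=10_000.0, session_duration=10_000.0)
        assert prof.overall_rate == pytest.approx(8.5)

    def test_empty_events_zero_everywhere(self):
        prof = lick_frequency([], window=1000.0, session_duration=5000.0)
        assert prof.overall_rate == 0.0
        assert prof.within_bout_rate == 0.0
        assert np.all(prof.rates == 0.0)

    def test_within_bout_rate_is_reciprocal_mean_ili(self):
        times = np.arange(20) * 125.0
        prof = lick_frequency(times, window=60_000.0, session_duration=60_000.0)
        assert prof.within_bout_rate == pytest.approx(8.0)


class TestPreference:
    @pytest.mark.parametrize(
        "n_a,n_b,expected", [(300, 100, 0.75), (0, 10, 0.0), (50, 50, 0.5)]
    )
    def test_fraction_on_a(self, n_a, n_b, expected):
        a = np.arange(n_a, dtype=float) * 100.0
        b = np.arange(n_b, dtype=float) * 100.0
        assert preference_index(a, b) == pytest.approx(expected)

    def test_no_licks_undefined(self):
        with pytest.raises(UndefinedMetricError):
            preference_index([], [])


class TestTimeBinnedCounts:
    START = dt.datetime(2024, 1, 1, 17, 0)  # 2 h before lights-off at 19:00

    def test_counts_conserved_across_bins(self, default_train):
        table = time_binned_counts(
            default_train.onsets, 10.0, self.START, 600_000.0
        )
        assert table["count"].sum() == default_train.n_licks

    def test_overnight_session_light_dark_tagging(self):
        """16 h session starting 2 h before lights-off: 16 hourly bins,
        first two tagged light, then dark until lights-on at 07:00."""
        table = time_binned_counts([], 60.0, self.START, 16 * 3_600_000.0)
        assert len(table) == 16
        assert table["is_dark"].tolist() == [False] * 2 + [True] * 12 + [False] * 2

    def test_single_hot_bin(self):
        times = np.linspace(120_000, 170_000, 30)
        table = time_binned_counts(times, 1.0, self.START, 600_000.0)
        assert table["count"].iloc[2] == 30
        assert table["count"].sum() == 30


class TestIntakeCorrelation:
    def test_proportional_mapping_gives_rho_one(self):
        """Grams exactly proportional to licks: rank correlation is 1."""
        import pandas as pd

        licks = np.array([120, 800, 450, 90, 1500, 333, 610, 75])
        frame = pd.DataFrame(
            {
                "animal_id": np.arange(licks.size),
                "session_id": 1,
                "bottle_id": "A",
                "liquid": "water",
                "weight_before": 45.0,
                "weight_after": 45.0 - licks * 1.5e-3,
                "total_licks": licks,
            }
        )
        res = intake_correlation(frame)
        assert res.spearman_rho == pytest.approx(1.0)
        assert res.n == licks.size

    def test_zero_volume_zero_noise_weights_unchanged(self):
        frame = simulate_intake_sessions(
            n_animals=2, n_sessions=1, ul_per_lick=0.0, weighing_noise_sd=0.0, seed=0
        )
        assert np.all(frame["weight_before"] == frame["weight_after"])

    def test_simulated_sessions_deterministic_under_seed(self):
        a = simulate_intake_sessions(n_animals=3, n_sessions=2, seed=9)
        b = simulate_intake_sessions(n_animals=3, n_sessions=2, seed=9)
        assert a.equals(b)

    def test_independent_shuffle_null_rho_small(self):
        """Shuffled lick counts (n=48): |rho| < 0.3 in >= 95% of seeds."""
        frame = simulate_intake_sessions(n_animals=12, n_sessions=2, seed=1)
        licks = frame["total_licks"].to_numpy().copy()
        ok = 0
        n_seeds = 200
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            shuffled = frame.copy()
            shuffled["total_licks"] = rng.permutation(licks)
            res = intake_correlation(shuffled)
            ok += abs(res.spearman_rho) < 0.3
        assert ok / n_seeds >= 0.95

    def test_noisy_default_generator_recovers_strong_correlation(self):
        """Default noisy lick->volume mapping at n=96 gives rho > 0.8,
        the qualitative in vivo relationship between licks and intake."""
        frame = simulate_intake_sessions(seed=2)  # 24 animals x 2 sessions x 2 bottles
        res = intake_correlation(frame)
        assert res.n == 96
        assert res.spearman_rho > 0.8
        assert res.p_value < 1e-4

    def test_by_liquid_splits_water_and_ethanol(self):
        frame = simulate_intake_sessions(n_animals=8, n_sessions=2, seed=3)
        results = intake_correlation(frame, by_liquid=True)
        assert set(results) == {"water", "ethanol"}
        assert all(r.n == 16 for r in results.values())

    def test_rank_invariance_under_monotone_transform(self):
        frame = simulate_intake_sessions(n_animals=10, n_sessions=2, seed=4)
        res = intake_correlation(frame)
        transformed = frame.copy()
        # strictly monotone transform of the lick counts
        transformed["total_licks"] = np.expm1(
            0.001 * transformed["total_licks"].to_numpy(float)
        )
        res_t = intake_correlation(transformed)
        assert res_t.spearman_rho == pytest.approx(res.spearman_rho)

    def test_constant_vector_undefined(self):
        frame = simulate_intake_sessions(
            n_animals=3, n_sessions=1, ul_per_lick=0.0, weighing_noise_sd=0.0, seed=0
        )
        with pytest.raises(UndefinedMetricError):
            intake_correlation(frame)

    def test_too_few_sessions_rejected(self):
        frame = simulate_intake_sessions(n_animals=1, n_sessions=1, seed=0).head(2)
        with pytest.raises(ParameterError):
            intake_correlation(frame)
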