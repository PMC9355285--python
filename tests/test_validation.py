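"""Event matching, precision/recall, and the in-silico protocol grid."""

import itertools

import numpy as np
import pytest
from scipy import stats

from lickometry import (
    ConfusionCounts,
    DataError,
    LossModel,
    UndefinedMetricError,
    match_events,
    precision,
    recall,
    run_insilico_protocol,
)


def optimal_match_count(det, onsets, ends):
    """Brute-force maximum bipartite matching oracle (<= 12 events).

    Enumerates truth orderings assigned to detections via recursion over
    detection index x used-truth bitmask.
    """
    n_d, n_t = len(det), len(onsets)
    compatible = [
        [onsets[j] <= det[i] <= ends[j] for j in range(n_t)] for i in range(n_d)
    ]
    best = {}

    def go(i, mask):
        if i == n_d:
            return 0
        key = (i, mask)
        if key in best:
            return best[key]
        res = go(i + 1, mask)  # leave detection i unmatched
        for j in range(n_t):
            if not mask >> j & 1 and compatible[i][j]:
                res = max(res, 1 + go(i + 1, mask | 1 << j))
        best[key] = res
        return res

    return go(0, 0)


class TestMatchEvents:
    def test_identity_match_is_perfect(self):
        truth = np.array([100.0, 300.0, 700.0])
        c = match_events(truth, truth, tolerance=10.0)
        assert (c.true_positives, c.false_positives, c.false_negatives) == (3, 0, 0)

    def test_empty_detections_are_all_false_negatives(self):
        c = match_events([], np.arange(10) * 200.0, tolerance=60.0)
        assert (c.true_positives, c.false_positives, c.false_negatives) == (0, 0, 10)

    def test_spurious_detection_counts_as_false_positive(self):
        truth = np.array([0.0, 200.0, 400.0, 600.0, 800.0])
        detected = np.array([10.0, 210.0, 410.0, 505.0, 610.0])  # 505 matches nothing
        c = match_events(truth=truth, detected=detected, tolerance=30.0)
        assert (c.true_positives, c.false_positives, c.false_negatives) == (4, 1, 1)

    def test_unsorted_input_rejected(self):
        with pytest.raises(DataError):
            match_events([200.0, 100.0], [0.0, 150.0])

    def test_equals_optimal_oracle_on_random_small_instances(self, rng):
        """Greedy matching attains the exhaustive-optimum TP on every
        random instance with <= 12 events (including nested windows)."""
        for _ in range(300):
            n_t = int(rng.integers(0, 7))
            n_d = int(rng.integers(0, 7))
            onsets = np.sort(rng.uniform(0, 1000, n_t))
            contacts = rng.uniform(1, 300, n_t)
            det = np.sort(rng.uniform(0, 1200, n_d))
            tol = float(rng.uniform(0, 120))
            c = match_events(det, onsets, tolerance=tol, contacts=contacts)
            want_tp = optimal_match_count(det, onsets, onsets + contacts + tol)
            assert c.true_positives == want_tp
            assert c.true_positives + c.false_negatives == n_t
            assert c.true_positives + c.false_positives == n_d


class TestPrecisionRecall:
    @pytest.mark.parametrize(
        "tp,fp,expected", [(10, 0, 1.0), (0, 5, 0.0), (91, 9, 0.91)]
    )
    def test_precision(self, tp, fp, expected):
        assert precision(ConfusionCounts(tp, fp, 0)) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "tp,fn,expected", [(10, 0, 1.0), (0, 7, 0.0), (90, 9, 90 / 99)]
    )
    def test_recall(self, tp, fn, expected):
        assert recall(ConfusionCounts(tp, 0, fn)) == pytest.approx(expected)

    def test_undefined_denominators_raise(self):
        with pytest.raises(UndefinedMetricError):
            precision(ConfusionCounts(0, 0, 5))
        with pytest.raises(UndefinedMetricError):
            recall(ConfusionCounts(0, 5, 0))


class TestInsilicoProtocol:
    def test_lossless_chain_has_zero_errors(self):
        report = run_insilico_protocol(
            phases=(1, 3),
            frequencies=(5.0,),
            cage_counts=(1, 2),
            replicates=2,
            n_pulses=500,
            miss_prob=0.0,
            loss_model=LossModel(loss_prob=0.0),
            seed=0,
        )
        assert np.all(report.frame["reading_error_pct"] == 0.0)
        assert np.all(report.frame["transmission_error_pct"] == 0.0)

    def test_phase2_has_no_output_a_rows(self):
        report = run_insilico_protocol(
            phases=(2,), frequencies=(5.0,), cage_counts=(1, 8),
            replicates=1, n_pulses=100, seed=1,
        )
        assert set(report.frame["output"]) == {"B"}

    def test_grid_shape_and_conservation(self):
        """Emitted = detected + misses and received = detected - drops (+dups)
        hold exactly for every cell."""
        report = run_insilico_protocol(
            phases=(1, 2, 3), frequencies=(5.0, 10.0), cage_counts=(1, 3),
            replicates=2, n_pulses=1000, seed=3,
        )
        f = report.frame
        # phases 1 and 2 contribute 1 row per cell, phase 3 two rows (A and B)
        assert len(f) == (1 + 1 + 2) * 2 * 2 * 2
        assert np.all(f["emitted"] >= f["central_detected"])
        assert np.all(f["emitted"] == 1000 * f["active_cages"])  # n_pulses per output per cage

    def test_phase1_single_cage_reading_error_within_binomial_bounds(self):
        """miss 5e-4 over 12,000 pulses: reading error in [0, 0.2] % across seeds."""
        for seed in range(5):
            report = run_insilico_protocol(
                phases=(1,), frequencies=(5.0,), cage_counts=(1,),
                replicates=1, n_pulses=12_000, seed=seed,
            )
            err = float(report.frame["reading_error_pct"].iloc[0])
            assert 0.0 <= err <= 0.2

    def test_reading_error_independent_of_cage_count(self):
        """Per-pulse miss model: regression of cell means on cage count over
        >= 50 replicates has a slope CI containing 0."""
        report = run_insilico_protocol(
            phases=(1,), frequencies=(5.0,), cage_counts=tuple(range(1, 9)),
            replicates=50, n_pulses=2000, seed=11,
        )
        cell_means = (
            report.frame.groupby("active_cages")["reading_error_pct"].mean()
        )
        x = cell_means.index.to_numpy(float)
        fit = stats.linregress(x, cell_means.to_numpy())
        # analytic slope SE under the binomial miss model: cell mean over
        # 50 replicates of 2000*c pulses has variance 100^2 p(1-p)/(2000*c*50)
        p, reps, pulses = 5e-4, 50, 2000
        var = 100.0**2 * p * (1 - p) / (pulses * x * reps)
        w = (x - x.mean()) / np.sum((x - x.mean()) ** 2)
        se_slope = np.sqrt(np.sum(w**2 * var))
        assert abs(fit.slope) <= 3 * se_slope

    def test_cells_reproducible_in_isolation(self):
        kwargs = dict(
            phases=(3,), frequencies=(10.0,), cage_counts=(2,),
            replicates=1, n_pulses=1000, seed=5,
        )
        a = run_insilico_protocol(**kwargs)
        b = run_insilico_protocol(**kwargs)
        assert a.frame.equals(b.frame)


class TestFastPathEquivalence:
    def test_protocol_counts_match_dense_multiplex_route(self):
        """The grid's arithmetic frame-assignment path detects exactly the
        same per-channel counts as dense multiplex + latched detection."""
        from lickometry import (
            PulseProtocol,
            SensorParams,
            detect_wireless,
            generate_pulse_trains,
            multiplex,
            render_continuous,
        )

        n = 300
        protocol = PulseProtocol(phase=3, frequency=10.0, n_pulses=n, active_cages=2)
        trains = generate_pulse_trains(protocol)
        duration = n * 100.0 + 200.0
        quiet = SensorParams(baseline_noise_sd=0.0)
        sigs = {ch: render_continuous(tr, quiet, duration=duration) for ch, tr in trains.items()}
        frames = multiplex(sigs, duration=duration)
        dense = detect_wireless(frames, mode="latched", miss_prob=0.0)
        report = run_insilico_protocol(
            phases=(3,), frequencies=(10.0,), cage_counts=(2,),
            replicates=1, n_pulses=n, miss_prob=0.0,
            loss_model=LossModel(loss_prob=0.0), seed=0,
        )
        for output in ("A", "B"):
            dense_total = sum(
                len(ev) for (cage, bottle), ev in dense.items() if bottle == output
            )
            row = report.frame[report.frame["output"] == output].iloc[0]
            assert dense_total == row["central_detected"] == row["emitted"]
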