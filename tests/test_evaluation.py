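"""Dynamic segment-based scoring, metrics and prediction times."""

import numpy as np
import pytest

import hybridmp as h
from hybridmp.evaluation import ConfusionCounts


def _session(onset=10.0, end=11.0, n=500):
    """One-movement session on a 40 ms grid starting at 0.04 s."""
    grid = np.arange(1, n + 1) * 0.04
    markers = [h.EventMarker(onset, "movement_onset"),
               h.EventMarker(end, "movement_end")]
    return grid, markers


def _stream(grid, positive_times):
    values = np.isin(np.round(grid / 0.04).astype(int),
                     [int(round(t / 0.04)) for t in positive_times]).astype(np.uint8)
    return h.PredictionStream(grid, values, "emg")


class TestMetrics:
    def test_balanced_accuracy_formula(self):
        assert h.balanced_accuracy(ConfusionCounts(9, 90, 10, 1)) == pytest.approx(0.9)
        assert h.balanced_accuracy(ConfusionCounts(5, 7, 7, 5)) == 0.5
        assert h.balanced_accuracy(ConfusionCounts(3, 8, 0, 0)) == 1.0

    def test_error_rates(self):
        fnr, fpr, prec = h.error_rates(ConfusionCounts(1, 10, 0, 3))
        assert fnr == 0.75 and fpr == 0.0 and prec == 1.0
        fnr, fpr, prec = h.error_rates(ConfusionCounts(3, 8, 0, 0))
        assert (fnr, fpr, prec) == (0.0, 0.0, 1.0)

    def test_fnr_tpr_identity(self, rng):
        for _ in range(20):
            c = ConfusionCounts(*(int(v) for v in rng.integers(1, 50, 4)))
            fnr, _, _ = h.error_rates(c)
            tpr = c.tp / (c.tp + c.fn)
            assert fnr + tpr == pytest.approx(1.0)

    def test_empty_class_raises(self):
        with pytest.raises(ValueError):
            h.balanced_accuracy(ConfusionCounts(0, 5, 5, 0))
        with pytest.raises(ValueError):
            h.error_rates(ConfusionCounts(2, 0, 0, 2))

    def test_undefined_precision_reported_as_missing(self):
        _, _, prec = h.error_rates(ConfusionCounts(0, 10, 0, 2))
        assert prec is None


class TestDynamicScheme:
    def test_perfect_predictor_scores_one(self):
        grid, markers = _session()
        stream = _stream(grid, [10.0 - 0.08, 10.0 - 0.04])
        res = h.evaluate_stream(stream, markers)
        assert res.ba == 1.0 and res.fnr == 0.0 and res.fpr == 0.0

    def test_all_zero_predictor_scores_half(self):
        grid, markers = _session()
        stream = h.PredictionStream(grid, np.zeros(len(grid)), "emg")
        res = h.evaluate_stream(stream, markers)
        assert res.ba == 0.5
        assert res.counts.tp == 0 and res.counts.fp == 0

    def test_gap_tolerant_run_counts_unknown_positives_as_tp(self):
        # positives -480..-40 ms with one gap at -200: all positives are TP
        grid, markers = _session()
        pos = [10.0 + r for r in (-0.48, -0.44, -0.40, -0.36, -0.32, -0.28,
                                  -0.24, -0.16, -0.12, -0.08, -0.04)]
        res = h.evaluate_stream(_stream(grid, pos), markers)
        assert res.counts.tp == len(pos)
        assert res.counts.fp == 0
        assert res.fnr == 0.0  # the tolerated gap is not a movement segment

    def test_run_stops_at_second_gap(self):
        # positives at -400..-320 are disconnected (two gaps at -280, -240)
        grid, markers = _session()
        pos = [10.0 + r for r in (-0.40, -0.36, -0.32, -0.12, -0.08, -0.04)]
        res = h.evaluate_stream(_stream(grid, pos), markers)
        # connected: -120, -80, -40 (TP); disconnected block -> FP
        assert res.counts.tp == 3
        assert res.counts.fp == 3

    def test_post_movement_predictions_are_not_counted(self):
        grid, markers = _session()
        pos = [10.0 - 0.08, 10.0 - 0.04, 10.3, 10.9, 11.1]  # in-movement + tol
        res = h.evaluate_stream(_stream(grid, pos), markers)
        assert res.counts.fp == 0 and res.ba == 1.0

    def test_counts_conserve_non_excluded_grid_points(self):
        grid, markers = _session(onset=10.0, end=11.0, n=500)
        stream = _stream(grid, [10.0 - 0.04, 5.0])
        res = h.evaluate_stream(stream, markers)
        oi, ei = 250, 275
        tol = 5
        excluded = (ei + tol) - oi + 1
        assert res.counts.total == 500 - excluded

    def test_adding_positives_moves_rates_one_way(self, rng):
        grid, markers = _session()
        base_vals = np.zeros(len(grid), dtype=np.uint8)
        base_vals[100] = 1
        base = h.evaluate_stream(h.PredictionStream(grid, base_vals, "emg"), markers)
        more_vals = base_vals.copy()
        extra = rng.choice(np.nonzero(more_vals == 0)[0], size=20, replace=False)
        more_vals[extra] = 1
        more = h.evaluate_stream(h.PredictionStream(grid, more_vals, "emg"), markers)
        assert more.fnr <= base.fnr
        assert more.counts.fp >= base.counts.fp


class TestPredictionTime:
    def test_minimal_run_gives_80ms(self):
        grid, markers = _session()
        stream = _stream(grid, [10.0 - 0.08, 10.0 - 0.04])
        assert h.prediction_time(stream, 10.0, movement_end=11.0) == pytest.approx(0.08)

    def test_consecutive_run_extends_time(self):
        grid, markers = _session()
        pos = [10.0 + r for r in np.arange(-0.48, -0.01, 0.04)]
        stream = _stream(grid, pos)
        assert h.prediction_time(stream, 10.0, movement_end=11.0) == pytest.approx(0.48)

    def test_isolated_early_positive_is_not_connected(self):
        grid, markers = _session()
        stream = _stream(grid, [10.0 - 0.90 + 0.02, 10.0 - 0.04])  # -0.88, -0.04
        assert h.prediction_time(stream, 10.0, movement_end=11.0) == pytest.approx(0.04)

    def test_no_positives_gives_none(self):
        grid, markers = _session()
        stream = h.PredictionStream(grid, np.zeros(len(grid)), "emg")
        assert h.prediction_time(stream, 10.0, movement_end=11.0) is None

    def test_quartiles_ordered_and_nearest_rank(self):
        grid = np.arange(1, 2001) * 0.04
        markers = []
        vals = np.zeros(len(grid), dtype=np.uint8)
        onsets = [10.0, 30.0, 50.0, 70.0]
        runs = [1, 3, 6, 12]  # run lengths in segments ending at -40 ms
        for onset, k in zip(onsets, runs):
            markers += [h.EventMarker(onset, "movement_onset"),
                        h.EventMarker(onset + 1.0, "movement_end")]
            oi = int(round(onset / 0.04))
            vals[oi - 1 - k : oi - 1] = 1  # grid positions oi-k .. oi-1
        res = h.evaluate_stream(h.PredictionStream(grid, vals, "emg"), markers)
        assert len(res.prediction_times) == 4
        np.testing.assert_allclose(sorted(res.prediction_times),
                                   [0.04 * k for k in runs])
        assert res.qt75 <= res.qt50 <= res.qt25
        # nearest-rank on 4 values: 25th pct -> 1st, 50th -> 2nd, 75th -> 3rd
        assert res.qt75 == pytest.approx(0.04 * 1)
        assert res.qt50 == pytest.approx(0.04 * 3)
        assert res.qt25 == pytest.approx(0.04 * 6)
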