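"""EMG branch: running variance, adaptive threshold, voting, grid search."""

import numpy as np
import pytest

import hybridmp as h
from hybridmp.emg import _decision_indices


def two_pass_variance(x, w):
    """Independent sliding-window oracle: per-window two-pass sample variance."""
    out = np.full(len(x), np.nan)
    for t in range(w - 1, len(x)):
        win = x[t - w + 1 : t + 1]
        mean = win.sum() / w
        out[t] = ((win - mean) ** 2).sum() / (w - 1)
    return out


class TestRunningVariance:
    def test_constant_signal_has_zero_variance(self):
        params = h.VarianceFilterParams(w_vf=10, fs=1000)  # 10 samples
        v = h.running_variance(np.full(100, 3.7), params)
        assert np.all(v[9:] == 0)
        assert np.all(np.isnan(v[:9]))  # warm-up undefined

    def test_three_sample_window_hand_value(self):
        # window {-1, 1, -1}: mean -1/3, unbiased variance 4/3
        params = h.VarianceFilterParams(w_vf=3, fs=1000)
        v = h.running_variance(np.array([-1.0, 1.0, -1.0]), params)
        assert np.isclose(v[2], 4.0 / 3.0, rtol=1e-12)

    def test_matches_two_pass_oracle_on_random_series(self, rng):
        x = rng.standard_normal(1000) * 40 + 100
        params = h.VarianceFilterParams(w_vf=50, fs=1000)  # 50 samples
        v = h.running_variance(x, params)
        ref = two_pass_variance(x, 50)
        valid = ~np.isnan(ref)
        np.testing.assert_allclose(v[valid], ref[valid], rtol=1e-9)

    def test_window_longer_than_series_raises(self):
        with pytest.raises(ValueError):
            h.running_variance(np.zeros(5), h.VarianceFilterParams(10, 1000))


class TestAdaptiveThreshold:
    def test_constant_variance_gives_threshold_equal_to_it(self):
        params = h.AdaptiveThresholdParams(w_at=10, p=5.0)
        t = h.adaptive_threshold(np.full(50, 2.5), params, fs=1000.0)
        np.testing.assert_allclose(t[9:], 2.5)

    def test_monotone_in_sensitivity_factor(self, rng):
        v = np.abs(rng.standard_normal(200))
        lo = h.adaptive_threshold(v, h.AdaptiveThresholdParams(50, 3.0), 1000.0)
        hi = h.adaptive_threshold(v, h.AdaptiveThresholdParams(50, 8.0), 1000.0)
        valid = ~np.isnan(lo)
        assert np.all(hi[valid] >= lo[valid])

    def test_hand_computed_window(self):
        # window {1,2,3}: mean 2, sample std 1, T = 2 + 3*1 = 5
        params = h.AdaptiveThresholdParams(w_at=3, p=3.0)
        t = h.adaptive_threshold(np.array([1.0, 2.0, 3.0]), params, fs=1000.0)
        assert np.isclose(t[2], 5.0)


class TestVoting:
    @pytest.mark.parametrize(
        "v, thr, n_cot, expected",
        [
            ([0.1, 0.1, 0.1], [1, 1, 1], 1, 0),  # all below
            ([2.0, 0.1, 0.1], [1, 1, 1], 1, 1),  # one above, n_cot=1
            ([2.0, 0.1, 0.1], [1, 1, 1], 2, 0),  # one above, n_cot=2
            ([2.0, 3.0, 0.1], [1, 1, 1], 2, 1),
        ],
    )
    def test_vote_rule(self, v, thr, n_cot, expected):
        setup = h.ChannelSetup((0, 1, 2), n_cot)
        assert h.detect_segment(np.array(v, float), np.array(thr, float),
                                setup) == expected

    def test_absent_channel_raises(self):
        with pytest.raises(IndexError):
            h.detect_segment(np.zeros(2), np.zeros(2), h.ChannelSetup((0, 5), 1))

    def test_invalid_setup_raises(self):
        with pytest.raises(ValueError):
            h.ChannelSetup((0, 1), 3)


def test_detection_needs_no_trained_classifier_and_flags_bursts_only():
    """Zero-noise bursts: >=1 positive per movement inside the burst,
    none in pure-baseline regions; the branch runs with no fitted model."""
    paradigm = h.ParadigmConfig(n_movements=6)
    templates = h.TemplateConfig(noise_sd=0.0)
    _, emg = h.generate_session(paradigm, templates, 8, 4, seed=5)
    times, preds = h.detect_stream(
        emg.samples,
        h.VarianceFilterParams(50, emg.fs),
        h.AdaptiveThresholdParams(2000, 3.0),
        h.ChannelSetup((0, 1, 2, 3), 1),
    )
    onsets = emg.marker_times("movement_onset")
    lead, dur = templates.emg_lead, templates.emg_burst_duration
    in_any_burst = np.zeros(len(times), dtype=bool)
    for onset in onsets:
        sel = (times >= onset - lead) & (times <= onset - lead + dur + 0.1)
        in_any_burst |= sel
        assert preds[sel].sum() >= 1, f"movement at {onset} not detected"
    far = ~in_any_burst
    # exclude the threshold's recovery tail right after each burst
    for onset in onsets:
        far &= ~((times > onset - lead) & (times < onset + dur + 2.0))
    assert preds[far].sum() == 0


class TestGridSearch:
    @staticmethod
    def _eval_ba(end_times, preds, markers):
        stream = h.PredictionStream(end_times, preds, "emg")
        return h.evaluate_stream(stream, markers).ba

    def test_grid_of_size_one_returns_that_point(self):
        paradigm = h.ParadigmConfig(n_movements=4)
        _, emg = h.generate_session(paradigm, h.TemplateConfig(noise_sd=1.0),
                                    8, 4, seed=6)
        grid = h.EMGGrid(w_vf_ms=(50,), w_at_ms=(2000,), p=(3,),
                         setups=(h.ChannelSetup((0,), 1),))
        vf, at, setup, ba = h.grid_search_emg([emg], grid, self._eval_ba)
        assert (vf.w_vf, at.w_at, at.p) == (50, 2000, 3)
        assert setup == h.ChannelSetup((0,), 1)

    def test_recovers_active_channel_and_ba_is_reproducible(self):
        # bursts planted on channel 0 only
        paradigm = h.ParadigmConfig(n_movements=6)
        templates = h.TemplateConfig(noise_sd=1.0)
        _, emg = h.generate_session(
            paradigm, templates, 8, 4, seed=7,
            emg_topography=np.array([1.0, 0.0, 0.0, 0.0]),
        )
        grid = h.EMGGrid(w_vf_ms=(20, 50), w_at_ms=(1000, 2000), p=(3, 6))
        vf, at, setup, ba = h.grid_search_emg([emg], grid, self._eval_ba)
        assert 0 in setup.channels
        # returned BA equals an independent re-evaluation at the optimum
        times, preds = h.detect_stream(emg.samples, vf, at, setup)
        assert np.isclose(ba, self._eval_ba(times, preds, emg.markers))

    def test_empty_training_raises(self):
        with pytest.raises(ValueError):
            h.grid_search_emg([], h.EMGGrid(), self._eval_ba)


def test_decision_indices_one_per_40ms_segment():
    dec = _decision_indices(1000, 5000.0)
    np.testing.assert_array_equal(dec, [199, 399, 599, 799, 999])
    assert len(_decision_indices(1234 * 200, 5000.0)) == 1234
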