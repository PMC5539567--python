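"""EMG movement-onset detection.

A causal running-variance filter smooths baseline noise and amplifies burst
activity; an adaptive threshold T(t) = mu(t) + p * sigma(t), computed over a
long trailing window of the variance-filtered signal, tracks slow drifts and
changing noise floors.  A 40 ms segment is classified as *movement* when the
variance sample at the segment end exceeds the threshold on at least ``n_cot``
channels.  The branch needs no trained classifier; its three parameters
(variance-window length W_VF, threshold-window length W_AT and sensitivity
factor p) are picked by an exhaustive grid search maximizing segment-based
balanced accuracy on training runs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VarianceFilterParams",
    "AdaptiveThresholdParams",
    "ChannelSetup",
    "EMGGrid",
    "running_variance",
    "adaptive_threshold",
    "detect_segment",
    "detect_stream",
    "grid_search_emg",
]

SEGMENT_S = 0.040  # decision granularity


@dataclass(frozen=True)
class VarianceFilterParams:
    """Causal running-variance window; ``w_vf`` in milliseconds."""

    w_vf: float = 50.0
    fs: float = 5000.0

    @property
    def n_samples(self) -> int:
        n = int(round(self.w_vf * 1e-3 * self.fs))
        if n < 2:
            raise ValueError("variance window must span >= 2 samples")
        return n


@dataclass(frozen=True)
class AdaptiveThresholdParams:
    """Trailing mean/std window ``w_at`` (ms) and sensitivity factor ``p``."""

    w_at: float = 1000.0
    p: float = 6.0

    def __post_init__(self) -> None:
        if self.w_at <= 0:
            raise ValueError("w_at must be > 0")
        if self.p <= 0:
            raise ValueError("p must be > 0")

    def n_samples(self, fs: float) -> int:
        return max(int(round(self.w_at * 1e-3 * fs)), 2)


@dataclass(frozen=True)
class ChannelSetup:
    """Channels entering the vote and the count ``n_cot`` that must agree."""

    channels: tuple[int, ...] = (0,)
    n_cot: int = 1

    def __post_init__(self) -> None:
        if not (1 <= self.n_cot <= len(self.channels)):
            raise ValueError("need 1 <= n_cot <= len(channels)")


def running_variance(x: np.ndarray, params: VarianceFilterParams) -> np.ndarray:
    """Unbiased sample variance over the causal window ending at each t.

    Output is aligned with the input; the leading ``W_VF - 1`` samples, where
    the window is not yet filled, are NaN (warm-up region).  The computation
    is shift-invariant, so the global mean is removed first for numerical
    stability; results match a two-pass per-window variance to ~1e-12.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("running_variance expects a single channel")
    w = params.n_samples
    if len(x) < w:
        raise ValueError(f"series length {len(x)} shorter than window {w}")
    xc = x - x.mean()
    v = pd.Series(xc).rolling(w, min_periods=w).var(ddof=1).to_numpy()
    np.maximum(v, 0.0, out=v, where=~np.isnan(v))
    return v


def adaptive_threshold(v: np.ndarray, params: AdaptiveThresholdParams, fs: float) -> np.ndarray:
    """T(t) = mean + p * std of the trailing W_AT window of ``v``.

    Sample statistics (N-1 denominator); NaN during warm-up.
    """
    v = np.asarray(v, dtype=np.float64)
    w = params.n_samples(fs)
    s = pd.Series(v)
    mu = s.rolling(w, min_periods=w).mean()
    sd = s.rolling(w, min_periods=w).std(ddof=1)
    return (mu + params.p * sd).to_numpy()


def detect_segment(
    v_decision: np.ndarray, thresholds: np.ndarray, setup: ChannelSetup
) -> int:
    """Vote over one decision sample per channel: 1 iff >= n_cot channels
    exceed their thresholds.  NaN (warm-up) never exceeds."""
    v_decision = np.asarray(v_decision, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    idx = np.asarray(setup.channels)
    if idx.max() >= v_decision.shape[0]:
        raise IndexError("channel setup references an absent channel")
    with np.errstate(invalid="ignore"):
        above = v_decision[idx] > thresholds[idx]
    return int(np.count_nonzero(above) >= setup.n_cot)


def _decision_indices(n_samples: int, fs: float) -> np.ndarray:
    """Indices of the last sample of each complete 40 ms segment."""
    seg = int(round(SEGMENT_S * fs))
    n_seg = n_samples // seg
    return np.arange(1, n_seg + 1) * seg - 1


def detect_stream(
    samples: np.ndarray,
    vf: VarianceFilterParams,
    at: AdaptiveThresholdParams,
    setup: ChannelSetup,
) -> tuple[np.ndarray, np.ndarray]:
    """Run the full EMG branch on a (n_time, n_channels) array.

    Returns ``(end_times, predictions)`` with one binary prediction per 40 ms
    segment.  Predictions are forced to 0 until both windows are filled.
    """
    samples = np.asarray(samples, dtype=np.float64)
    dec = _decision_indices(samples.shape[0], vf.fs)
    n_ch = samples.shape[1]
    v_dec = np.empty((n_ch, len(dec)))
    t_dec = np.empty((n_ch, len(dec)))
    for c in range(n_ch):
        v = running_variance(samples[:, c], vf)
        t = adaptive_threshold(v, at, vf.fs)
        v_dec[c] = v[dec]
        t_dec[c] = t[dec]
    idx = np.asarray(setup.channels)
    if idx.max() >= n_ch:
        raise IndexError("channel setup references an absent channel")
    with np.errstate(invalid="ignore"):
        above = v_dec[idx] > t_dec[idx]
    preds = (above.sum(axis=0) >= setup.n_cot).astype(np.uint8)
    end_times = (dec + 1) / vf.fs
    return end_times, preds


# ---------------------------------------------------------------------------
# grid search


@dataclass(frozen=True)
class EMGGrid:
    """Exhaustive search space for the EMG branch."""

    w_vf_ms: tuple[float, ...] = (10, 20, 50, 100, 200)
    w_at_ms: tuple[float, ...] = (100, 200, 500, 1000, 2000, 5000)
    p: tuple[float, ...] = tuple(range(3, 13))
    setups: tuple[ChannelSetup, ...] | None = None  # None -> standard setups

    def channel_setups(self, n_channels: int) -> tuple[ChannelSetup, ...]:
        if self.setups is not None:
            return self.setups
        setups = [ChannelSetup((c,), 1) for c in range(n_channels)]
        if n_channels >= 8:
            for n_cot in (1, 2, 4):
                setups.append(ChannelSetup(tuple(range(8)), n_cot))
        if n_channels >= 4:
            for n_cot in (1, 2):
                setups.append(ChannelSetup(tuple(range(4)), n_cot))
        return tuple(setups)


def grid_search_emg(
    recordings,
    grid: EMGGrid,
    evaluate_ba,
    fs: float = 5000.0,
):
    """Exhaustive grid search maximizing mean balanced accuracy.

    ``recordings`` is a list of EMG Recordings with movement markers;
    ``evaluate_ba(end_times, preds, markers) -> float`` scores one run with
    the segment-based scheme.  Ties break lexicographically toward smaller
    W_VF, then W_AT, then p, then fewer channels (then lower indices).

    Returns ``(VarianceFilterParams, AdaptiveThresholdParams, ChannelSetup,
    best_ba)``.
    """
    if not recordings:
        raise ValueError("grid search needs at least one labeled recording")
    n_ch = recordings[0].samples.shape[1]
    setups = grid.channel_setups(n_ch)

    # Precompute per-run decision-sample variance and rolling stats per
    # (channel, w_vf, w_at): the costly rolling passes are shared across p
    # and channel setups.
    runs = []
    for rec in recordings:
        dec = _decision_indices(rec.samples.shape[0], fs)
        end_times = (dec + 1) / fs
        v_dec = {}
        mu_dec = {}
        sd_dec = {}
        for w_vf in grid.w_vf_ms:
            vf = VarianceFilterParams(w_vf, fs)
            for c in range(n_ch):
                v = running_variance(rec.samples[:, c], vf)
                v_dec[(w_vf, c)] = v[dec]
                s = pd.Series(v)
                for w_at in grid.w_at_ms:
                    w = AdaptiveThresholdParams(w_at, 3.0).n_samples(fs)
                    mu = s.rolling(w, min_periods=w).mean().to_numpy()[dec]
                    sd = s.rolling(w, min_periods=w).std(ddof=1).to_numpy()[dec]
                    mu_dec[(w_vf, w_at, c)] = mu
                    sd_dec[(w_vf, w_at, c)] = sd
        runs.append((rec, end_times, v_dec, mu_dec, sd_dec))

    best = None
    best_key = None
    for w_vf, w_at, p in itertools.product(grid.w_vf_ms, grid.w_at_ms, grid.p):
        # per-channel exceedance masks for this parameter point, per run
        per_run_above = []
        for rec, end_times, v_dec, mu_dec, sd_dec in runs:
            above = np.empty((n_ch, len(end_times)), dtype=bool)
            for c in range(n_ch):
                v = v_dec[(w_vf, c)]
                t = mu_dec[(w_vf, w_at, c)] + p * sd_dec[(w_vf, w_at, c)]
                with np.errstate(invalid="ignore"):
                    above[c] = v > t
            per_run_above.append(above)
        for setup in setups:
            idx = np.asarray(setup.channels)
            bas = []
            for (rec, end_times, *_), above in zip(runs, per_run_above):
                preds = (above[idx].sum(axis=0) >= setup.n_cot).astype(np.uint8)
                bas.append(evaluate_ba(end_times, preds, rec.markers))
            ba = float(np.mean(bas))
            key = (-ba, w_vf, w_at, p, len(setup.channels), setup.channels,
                   setup.n_cot)
            if best_key is None or key < best_key:
                best_key = key
                best = (
                    VarianceFilterParams(w_vf, fs),
                    AdaptiveThresholdParams(w_at, p),
                    setup,
                    ba,
                )
    return best
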