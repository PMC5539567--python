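"""Shared EEG preprocessing: streaming detrend and two-stage decimation.

The raw 5 kHz EEG is (3) detrended by a first-order IIR DC blocker
``y[t] = x[t] - x[t-1] + a * y[t-1]`` and (4) decimated in two FIR
anti-aliased stages, 5 kHz -> 125 Hz -> 25 Hz.  The second-stage low-pass
attenuates everything above ~4 Hz, leaving the slow cortical band the MRCP
lives in.  Both operations are causal and carry per-channel state across
blocks, so streaming a recording in arbitrary block sizes is bit-identical
to single-shot processing.  Each 40 ms block at 5 kHz (200 samples) yields
exactly one output sample per channel at 25 Hz; group delay is not
compensated (all timestamps are segment end times, so the delay is uniform
across modalities).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "DetrendState",
    "DecimationStage",
    "PreprocessingChain",
    "detrend",
    "design_antialias_fir",
    "decimate",
]

DEFAULT_POLE = 0.999


@dataclass
class DetrendState:
    """First-order DC-blocker state: ``y[t] = x[t] - x[t-1] + pole*y[t-1]``."""

    pole: float = DEFAULT_POLE
    n_channels: int = 1
    zi: np.ndarray | None = None  # per-channel lfilter state, shape (1, C)

    def __post_init__(self) -> None:
        if not (0.0 < self.pole < 1.0):
            raise ValueError("pole must be in (0, 1)")
        if self.zi is None:
            self.zi = np.zeros((1, self.n_channels))


def detrend(block: np.ndarray, state: DetrendState) -> tuple[np.ndarray, DetrendState]:
    """High-pass the block (samples x channels), carrying filter state."""
    block = np.atleast_2d(np.asarray(block, dtype=np.float64))
    if block.size == 0:
        return block.reshape(0, state.n_channels), state
    if block.shape[1] != state.n_channels:
        raise ValueError(
            f"block has {block.shape[1]} channels, state has {state.n_channels}"
        )
    b = np.array([1.0, -1.0])
    a = np.array([1.0, -state.pole])
    out, zf = signal.lfilter(b, a, block, axis=0, zi=state.zi)
    new_state = DetrendState(state.pole, state.n_channels, zf)
    return out, new_state


def design_antialias_fir(
    fs_in: float, factor: int, passband_edge: float, n_taps: int
) -> np.ndarray:
    """Linear-phase Hamming-window low-pass for decimation by ``factor``.

    ``passband_edge`` marks the end of the flat band; the -6 dB cutoff is
    placed half a transition band above it, so the stopband floor (>= 40 dB
    for a Hamming window) starts one full transition band (~3.3 * fs_in /
    n_taps) past the edge.  Taps are normalized to exact unit DC gain.
    Raises if the stopband cannot start by the output Nyquist.
    """
    fs_out = fs_in / factor
    if passband_edge >= fs_out / 2:
        raise ValueError("passband_edge must be below the output Nyquist")
    if n_taps < 9:
        raise ValueError("n_taps too small for a meaningful design")
    transition = 3.3 * fs_in / n_taps
    if passband_edge + transition > fs_out / 2:
        raise ValueError(
            f"design infeasible: {n_taps} taps give a ~{transition:.1f} Hz "
            f"transition band, stopband cannot start by {fs_out / 2:.1f} Hz"
        )
    cutoff = passband_edge + transition / 2.0
    taps = signal.firwin(n_taps, cutoff, window="hamming", fs=fs_in)
    return taps / taps.sum()  # exact unit DC gain


@dataclass
class DecimationStage:
    """One filter-then-downsample stage with streaming state.

    ``phase`` tracks the downsampling grid across blocks: output samples are
    the filtered samples at absolute indices ``factor-1, 2*factor-1, ...``
    (the last sample of each group, keeping end-time alignment).
    """

    factor: int
    fir_taps: np.ndarray
    fs_in: float
    n_channels: int = 1
    zi: np.ndarray | None = None
    phase: int = 0  # samples consumed modulo factor

    def __post_init__(self) -> None:
        self.fir_taps = np.asarray(self.fir_taps, dtype=np.float64)
        if not np.all(np.isfinite(self.fir_taps)):
            raise ValueError("taps must be finite")
        if abs(self.fir_taps.sum() - 1.0) > 1e-6:
            raise ValueError("taps must have unit DC gain")
        if self.zi is None:
            self.zi = np.zeros((len(self.fir_taps) - 1, self.n_channels))

    @property
    def fs_out(self) -> float:
        return self.fs_in / self.factor


def decimate(block: np.ndarray, stage: DecimationStage) -> tuple[np.ndarray, DecimationStage]:
    """Low-pass filter the block and keep every ``factor``-th sample."""
    block = np.atleast_2d(np.asarray(block, dtype=np.float64))
    if block.size == 0:
        return block.reshape(0, stage.n_channels), stage
    if block.shape[1] != stage.n_channels:
        raise ValueError("channel count mismatch")
    filtered, zf = signal.lfilter(
        stage.fir_taps, [1.0], block, axis=0, zi=stage.zi
    )
    n = block.shape[0]
    # absolute indices stage.phase .. stage.phase+n-1; keep those with
    # (index % factor) == factor-1
    first = (stage.factor - 1 - stage.phase) % stage.factor
    out = filtered[first::stage.factor]
    new_stage = DecimationStage(
        stage.factor,
        stage.fir_taps,
        stage.fs_in,
        stage.n_channels,
        zf,
        (stage.phase + n) % stage.factor,
    )
    return out, new_stage


@dataclass
class PreprocessingChain:
    """Detrend + 5 kHz -> 125 Hz -> 25 Hz decimation with carried state."""

    fs_in: float = 5000.0
    n_channels: int = 1
    pole: float = DEFAULT_POLE
    stage1_taps: int = 351
    stage1_passband: float = 10.0
    stage2_taps: int = 63
    stage2_passband: float = 2.5
    detrend_state: DetrendState = field(init=False)
    stage1: DecimationStage = field(init=False)
    stage2: DecimationStage = field(init=False)

    def __post_init__(self) -> None:
        if self.fs_in != 5000.0 and self.fs_in % 200 != 0:
            raise ValueError("fs_in must be divisible by 200 (two-stage 40x5)")
        self.detrend_state = DetrendState(self.pole, self.n_channels)
        t1 = design_antialias_fir(self.fs_in, 40, self.stage1_passband, self.stage1_taps)
        self.stage1 = DecimationStage(40, t1, self.fs_in, self.n_channels)
        fs_mid = self.fs_in / 40
        t2 = design_antialias_fir(fs_mid, 5, self.stage2_passband, self.stage2_taps)
        self.stage2 = DecimationStage(5, t2, fs_mid, self.n_channels)

    @property
    def fs_out(self) -> float:
        return self.fs_in / 200

    def process(self, block: np.ndarray) -> np.ndarray:
        """Push one block through the chain; returns the 25 Hz samples."""
        out, self.detrend_state = detrend(block, self.detrend_state)
        out, self.stage1 = decimate(out, self.stage1)
        out, self.stage2 = decimate(out, self.stage2)
        return out

    def process_all(self, samples: np.ndarray) -> np.ndarray:
        """Single-shot convenience wrapper (equivalent to any blocking)."""
        return self.process(samples)
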