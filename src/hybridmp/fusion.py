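"""Decision fusion of the per-modality prediction streams.

All modalities emit one binary prediction per 40 ms (indexed by segment end
time).  A detected P300 at stimulus time t opens a movement-expectation gate
over [t + 1 s, t + 5 s] (inclusive endpoints on the grid; overlapping gates
are unioned).  The eight system outputs are the two single modalities and
their Boolean combinations, optionally AND-gated by the P300:

    MRCP, EMG, MoE = EMG | MRCP, MaE = EMG & MRCP,
    PaM = gate & MRCP, PaE = gate & EMG,
    PaMoE = gate & (MRCP | EMG), PaMaE = gate & MRCP & EMG.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PredictionStream", "FusionMode", "FUSION_MODES", "gate_p300", "combine"]

GRID_S = 0.040

FUSION_MODES = ("MRCP", "EMG", "MoE", "MaE", "PaM", "PaE", "PaMoE", "PaMaE")

#: which inputs each mode needs
_NEEDS_GATE = {"PaM", "PaE", "PaMoE", "PaMaE"}


@dataclass
class PredictionStream:
    grid_times: np.ndarray  # strictly increasing, 40 ms spacing
    values: np.ndarray      # binary
    modality: str

    def __post_init__(self) -> None:
        self.grid_times = np.asarray(self.grid_times, dtype=np.float64)
        self.values = np.asarray(self.values).astype(np.uint8)
        if self.grid_times.shape != self.values.shape:
            raise ValueError("times/values length mismatch")
        if len(self.grid_times) > 1:
            dt = np.diff(self.grid_times)
            if not np.allclose(dt, GRID_S, atol=1e-6):
                raise ValueError("grid spacing must be 40 ms")
        if np.any((self.values != 0) & (self.values != 1)):
            raise ValueError("values must be binary")


class FusionMode(str):
    """Validated fusion-mode name."""

    def __new__(cls, mode: str):
        if mode not in FUSION_MODES:
            raise ValueError(f"unknown fusion mode {mode!r}; one of {FUSION_MODES}")
        return super().__new__(cls, mode)


def gate_p300(
    detection_times: np.ndarray,
    grid_times: np.ndarray,
    open_after: float = 1.0,
    close_after: float = 5.0,
) -> PredictionStream:
    """Rasterize the union of [t + 1 s, t + 5 s] windows onto the grid."""
    grid_times = np.asarray(grid_times, dtype=np.float64)
    mask = np.zeros(len(grid_times), dtype=np.uint8)
    for t in np.atleast_1d(np.asarray(detection_times, dtype=np.float64)):
        sel = (grid_times >= t + open_after - 1e-9) & (
            grid_times <= t + close_after + 1e-9
        )
        mask[sel] = 1
    return PredictionStream(grid_times, mask, "p300_gate")


def _check_aligned(*streams: PredictionStream) -> None:
    ref = streams[0].grid_times
    for s in streams[1:]:
        if s.grid_times.shape != ref.shape or not np.allclose(
            s.grid_times, ref, atol=1e-6
        ):
            raise ValueError("prediction streams are not on the same grid")


def combine(
    p_emg: PredictionStream | None,
    p_mrcp: PredictionStream | None,
    p_gate: PredictionStream | None,
    mode: str,
) -> PredictionStream:
    """Pointwise Boolean fusion; single-modality modes pass through."""
    mode = FusionMode(mode)
    present = [s for s in (p_emg, p_mrcp, p_gate) if s is not None]
    if not present:
        raise ValueError("no input streams")
    _check_aligned(*present)
    grid = present[0].grid_times

    def need(s: PredictionStream | None, name: str) -> np.ndarray:
        if s is None:
            raise ValueError(f"mode {mode} requires the {name} stream")
        return s.values.astype(bool)

    if mode == "EMG":
        out = need(p_emg, "EMG")
    elif mode == "MRCP":
        out = need(p_mrcp, "MRCP")
    elif mode == "MoE":
        out = need(p_emg, "EMG") | need(p_mrcp, "MRCP")
    elif mode == "MaE":
        out = need(p_emg, "EMG") & need(p_mrcp, "MRCP")
    else:
        gate = need(p_gate, "P300 gate")
        if mode == "PaM":
            out = gate & need(p_mrcp, "MRCP")
        elif mode == "PaE":
            out = gate & need(p_emg, "EMG")
        elif mode == "PaMoE":
            out = gate & (need(p_mrcp, "MRCP") | need(p_emg, "EMG"))
        else:  # PaMaE
            out = gate & need(p_mrcp, "MRCP") & need(p_emg, "EMG")
    return PredictionStream(grid, out.astype(np.uint8), str(mode))
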