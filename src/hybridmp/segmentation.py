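"""Segment streams and training labels.

Three segment streams feed the three detection branches, all sharing a 40 ms
decision grid indexed by segment *end* time:

* ``emg_raw`` -- contiguous non-overlapping 40 ms windows of raw 5 kHz EMG
  (200 samples x channels);
* ``mrcp``    -- 200 ms sliding windows of the 25 Hz decimated EEG
  (5 samples, hop 1 sample = 40 ms, adjacent windows overlap by 160 ms);
* ``p300``    -- 1000 ms stimulus-locked windows (25 samples) starting at the
  first 25 Hz sample at/after each Standard/Target marker.

Training labels for the movement branches follow the session's temporal
layout around each movement onset: segments ending within +/-120 ms of an
onset are *movement* examples, segments ending inside the movement or within
200 ms after its end are *excluded*, everything else is *rest*.  Interval
endpoints are inclusive on the 40 ms grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Segment",
    "LabelingPolicy",
    "segment_raw",
    "assemble_mrcp_segments",
    "assemble_p300_segments",
    "assign_training_labels",
    "grid_index",
]

GRID_S = 0.040

LABELS = ("movement", "rest", "target", "standard", "excluded", "unknown")


def grid_index(t: float) -> int:
    """Nearest 40 ms grid index for a time in seconds."""
    return int(round(t / GRID_S))


@dataclass
class Segment:
    data: np.ndarray      # (n_samples, n_channels)
    end_time: float       # seconds
    stream: str           # {"emg_raw", "mrcp", "p300"}
    label: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.label is not None and self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")


@dataclass(frozen=True)
class LabelingPolicy:
    """Windows of the segment-based labeling scheme, in ms relative to each
    movement onset (segment end times, inclusive endpoints)."""

    train_movement_window: tuple[float, float] = (-120.0, 120.0)
    obligatory_premovement_ends: tuple[float, ...] = (-80.0, -40.0)
    unknown_interval: tuple[float, float] = (-1000.0, -120.0)
    post_tolerance: float = 200.0  # ms after movement end still excluded
    max_exceptions: int = 1


def segment_raw(samples: np.ndarray, fs: float, window_ms: float = 40.0) -> list[Segment]:
    """Cut a raw recording into contiguous non-overlapping 40 ms segments."""
    samples = np.asarray(samples, dtype=np.float64)
    n_win = int(round(window_ms * 1e-3 * fs))
    n_seg = samples.shape[0] // n_win
    return [
        Segment(
            samples[k * n_win : (k + 1) * n_win],
            end_time=(k + 1) * n_win / fs,
            stream="emg_raw",
        )
        for k in range(n_seg)
    ]


def assemble_mrcp_segments(decimated: np.ndarray, fs_out: float = 25.0,
                           window_samples: int = 5) -> list[Segment]:
    """Sliding 200 ms windows (5 samples at 25 Hz), hop one sample.

    The 25 Hz sample with index n carries end time ``(n + 1) / fs_out``
    (end of the 40 ms raw block it summarizes), so adjacent segments are
    40 ms apart and overlap by 160 ms.
    """
    decimated = np.atleast_2d(np.asarray(decimated, dtype=np.float64))
    n = decimated.shape[0]
    out = []
    for i in range(n - window_samples + 1):
        out.append(
            Segment(
                decimated[i : i + window_samples],
                end_time=(i + window_samples) / fs_out,
                stream="mrcp",
            )
        )
    return out


def assemble_p300_segments(
    decimated: np.ndarray,
    markers,
    fs_out: float = 25.0,
    window_samples: int = 25,
) -> list[Segment]:
    """One 1000 ms (25-sample) window per Standard/Target marker.

    Windows start at the first 25 Hz sample at/after the marker (causal
    alignment, jitter <= one grid step); markers too close to the stream end
    are skipped with a warning.
    """
    import warnings

    decimated = np.atleast_2d(np.asarray(decimated, dtype=np.float64))
    n = decimated.shape[0]
    out = []
    for m in markers:
        if m.kind not in ("standard", "target"):
            continue
        start = int(np.ceil(m.time * fs_out - 1e-9))
        if start + window_samples > n:
            warnings.warn(
                f"marker at {m.time:.3f} s too close to stream end; skipped",
                stacklevel=2,
            )
            continue
        out.append(
            Segment(
                decimated[start : start + window_samples],
                end_time=(start + window_samples) / fs_out,
                stream="p300",
                label=m.kind,
            )
        )
    return out


def _movement_intervals(markers) -> list[tuple[float, float]]:
    """Pair movement_onset/movement_end markers in temporal order."""
    onsets = [m.time for m in markers if m.kind == "movement_onset"]
    ends = [m.time for m in markers if m.kind == "movement_end"]
    if len(onsets) != len(ends):
        raise ValueError("unpaired movement_onset/movement_end markers")
    pairs = list(zip(onsets, ends))
    for (o, e) in pairs:
        if e <= o:
            raise ValueError("movement_end precedes its onset")
    for (_, e0), (o1, _) in zip(pairs, pairs[1:]):
        if o1 <= e0:
            raise ValueError("overlapping movement intervals (paradigm violation)")
    return pairs


def label_grid(end_indices: np.ndarray, markers, policy: LabelingPolicy) -> np.ndarray:
    """Static training labels per grid point: 'movement'/'rest'/'excluded'.

    ``end_indices`` are 40 ms grid indices of segment end times.  Onsets are
    snapped to the nearest grid point (generator jitter <= 20 ms).  Training
    window [-120, +120] ms -> movement; (onset, end + 200 ms] -> excluded
    (movement beats exclusion where the windows overlap); else rest.
    """
    end_indices = np.asarray(end_indices)
    labels = np.full(len(end_indices), "rest", dtype=object)
    lo = grid_index(policy.train_movement_window[0] * 1e-3)
    hi = grid_index(policy.train_movement_window[1] * 1e-3)
    tol = int(np.ceil(policy.post_tolerance * 1e-3 / GRID_S - 1e-9))
    for onset, end in _movement_intervals(markers):
        oi = grid_index(onset)
        ei = int(np.ceil(end / GRID_S - 1e-9))
        rel = end_indices - oi
        labels[(rel >= 0) & (end_indices <= ei + tol)] = "excluded"
        labels[(rel >= lo) & (rel <= hi)] = "movement"
    return labels


def assign_training_labels(segments: list[Segment], markers,
                           policy: LabelingPolicy | None = None) -> list[Segment]:
    """Label movement-branch segments in place (movement/rest/excluded)."""
    policy = policy or LabelingPolicy()
    idx = np.array([grid_index(s.end_time) for s in segments])
    labels = label_grid(idx, markers, policy)
    for s, lab in zip(segments, labels):
        s.label = str(lab)
    return segments
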