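"""Segment-based performance evaluation and prediction-time statistics.

The true class of each 40 ms segment is assigned *dynamically* from its
temporal relation to the movement onsets and, in the pre-movement "unknown"
phase, from the predictions themselves:

* segments ending at -80 or -40 ms relative to an onset are expected to
  predict the movement (obligatory pre-movement phase);
* segments ending in [-1 s, -120 ms] belong to the movement class iff they
  are part of a backward-extending consecutive run of movement predictions
  anchored at -120 ms, tolerating at most one interruption (the tolerated
  gap itself keeps the rest label: it is not a movement-class *prediction*);
* segments ending between the onset and the movement end + 200 ms are
  excluded from the counts;
* everything else is rest.

Metrics follow the usual confusion-matrix definitions: balanced accuracy
BA = (TPR + TNR)/2, FNR = FN/(TP+FN), FPR = FP/(TN+FP), precision =
TP/(TP+FP).  The prediction time of a movement is the earliest segment end
in its movement-labeled run (including the obligatory block) that predicts
the movement, in seconds before the onset; movements with no such prediction
contribute to FN but not to the time statistics.  Quartiles are nearest-rank
on the per-movement times, ordered so that Qt75 <= Qt50 <= Qt25 (Qt75 is the
time exceeded by 75% of movements).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fusion import PredictionStream
from .segmentation import GRID_S, LabelingPolicy, _movement_intervals, grid_index

__all__ = [
    "ConfusionCounts",
    "EvalResult",
    "balanced_accuracy",
    "error_rates",
    "evaluate_stream",
    "prediction_time",
    "evaluate_binary",
]


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def balanced_accuracy(counts: ConfusionCounts) -> float:
    """(TPR + TNR) / 2; raises if either class is empty."""
    if counts.tp + counts.fn == 0 or counts.tn + counts.fp == 0:
        raise ValueError("balanced accuracy undefined with an empty class")
    tpr = counts.tp / (counts.tp + counts.fn)
    tnr = counts.tn / (counts.tn + counts.fp)
    return 0.5 * (tpr + tnr)


def error_rates(counts: ConfusionCounts) -> tuple[float, float, float | None]:
    """(FNR, FPR, precision); precision is None when TP + FP = 0."""
    if counts.tp + counts.fn == 0 or counts.tn + counts.fp == 0:
        raise ValueError("error rates undefined with an empty class")
    fnr = counts.fn / (counts.tp + counts.fn)
    fpr = counts.fp / (counts.tn + counts.fp)
    precision = (
        counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp > 0 else None
    )
    return fnr, fpr, precision


def _nearest_rank(sorted_vals: np.ndarray, q: float) -> float:
    """Nearest-rank quantile (q in (0, 1]) of an ascending array."""
    n = len(sorted_vals)
    rank = max(int(np.ceil(q * n)), 1)
    return float(sorted_vals[rank - 1])


@dataclass
class EvalResult:
    counts: ConfusionCounts
    ba: float
    fnr: float
    fpr: float
    precision: float | None
    prediction_times: np.ndarray = field(default_factory=lambda: np.array([]))
    mu_t: float | None = None
    qt75: float | None = None
    qt50: float | None = None
    qt25: float | None = None

    def as_dict(self) -> dict:
        return {
            "tp": self.counts.tp,
            "tn": self.counts.tn,
            "fp": self.counts.fp,
            "fn": self.counts.fn,
            "ba": self.ba,
            "fnr": self.fnr,
            "fpr": self.fpr,
            "precision": self.precision,
            "mu_t": self.mu_t,
            "qt75": self.qt75,
            "qt50": self.qt50,
            "qt25": self.qt25,
            "prediction_times": list(map(float, self.prediction_times)),
        }


def _dynamic_labels(
    grid_idx: np.ndarray,
    values: np.ndarray,
    markers,
    policy: LabelingPolicy,
) -> tuple[np.ndarray, list[list[int]]]:
    """Per-grid-point dynamic labels 'movement'/'rest'/'excluded' and, per
    movement, the grid positions labeled movement (for prediction times)."""
    labels = np.full(len(grid_idx), "rest", dtype=object)
    pos_of = {g: i for i, g in enumerate(grid_idx)}
    per_movement: list[list[int]] = []

    oblig = [grid_index(ms * 1e-3) for ms in policy.obligatory_premovement_ends]
    unk_lo = grid_index(policy.unknown_interval[0] * 1e-3)
    unk_hi = grid_index(policy.unknown_interval[1] * 1e-3)
    tol = int(np.ceil(policy.post_tolerance * 1e-3 / GRID_S - 1e-9))

    for onset, end in _movement_intervals(markers):
        oi = grid_index(onset)
        ei = int(np.ceil(end / GRID_S - 1e-9))
        move_positions: list[int] = []

        # post-movement phase: onset .. end + tolerance, excluded
        for g in range(oi, ei + tol + 1):
            i = pos_of.get(g)
            if i is not None:
                labels[i] = "excluded"

        # obligatory pre-movement block
        for r in oblig:
            i = pos_of.get(oi + r)
            if i is not None:
                labels[i] = "movement"
                move_positions.append(oi + r)

        # pre-movement unknown phase: backward run anchored at -120 ms
        exceptions = 0
        for r in range(unk_hi, unk_lo - 1, -1):
            i = pos_of.get(oi + r)
            if i is None:
                break
            if values[i]:
                labels[i] = "movement"
                move_positions.append(oi + r)
            elif exceptions < policy.max_exceptions:
                exceptions += 1  # tolerated gap keeps its rest label
            else:
                break
        per_movement.append(move_positions)
    return labels, per_movement


def evaluate_stream(
    predictions: PredictionStream,
    markers,
    policy: LabelingPolicy | None = None,
) -> EvalResult:
    """Score a 40 ms prediction stream with the dynamic segment scheme."""
    policy = policy or LabelingPolicy()
    grid_idx = np.array([grid_index(t) for t in predictions.grid_times])
    if len(grid_idx) > 1 and np.any(np.diff(grid_idx) != 1):
        raise ValueError("predictions are not on a contiguous 40 ms grid")
    values = predictions.values.astype(bool)

    labels, per_movement = _dynamic_labels(grid_idx, values, markers, policy)

    counted = labels != "excluded"
    is_move = labels == "movement"
    tp = int(np.count_nonzero(values & is_move & counted))
    fn = int(np.count_nonzero(~values & is_move & counted))
    fp = int(np.count_nonzero(values & ~is_move & counted))
    tn = int(np.count_nonzero(~values & ~is_move & counted))
    counts = ConfusionCounts(tp, tn, fp, fn)

    pos_of = {g: i for i, g in enumerate(grid_idx)}
    onsets = [o for o, _ in _movement_intervals(markers)]
    times = []
    for onset, move_positions in zip(onsets, per_movement):
        t = prediction_time_from_positions(
            onset, move_positions, values, pos_of
        )
        if t is not None:
            times.append(t)
    times = np.array(sorted(times))

    result = EvalResult(
        counts=counts,
        ba=balanced_accuracy(counts),
        fnr=error_rates(counts)[0],
        fpr=error_rates(counts)[1],
        precision=error_rates(counts)[2],
        prediction_times=times,
    )
    if len(times):
        result.mu_t = float(times.mean())
        result.qt75 = _nearest_rank(times, 0.25)  # exceeded by 75% of movements
        result.qt50 = _nearest_rank(times, 0.50)
        result.qt25 = _nearest_rank(times, 0.75)
    return result


def prediction_time_from_positions(onset, move_positions, values, pos_of):
    """Earliest predicted segment end in the movement-labeled run, in
    seconds before onset; None if no positive among them."""
    oi = grid_index(onset)
    hits = [
        g
        for g in move_positions
        if pos_of.get(g) is not None and values[pos_of[g]]
    ]
    if not hits:
        return None
    return (oi - min(hits)) * GRID_S


def prediction_time(
    predictions: PredictionStream,
    onset: float,
    policy: LabelingPolicy | None = None,
    movement_end: float | None = None,
) -> float | None:
    """Prediction time of a single movement (convenience wrapper)."""
    policy = policy or LabelingPolicy()
    grid_idx = np.array([grid_index(t) for t in predictions.grid_times])
    values = predictions.values.astype(bool)
    end = movement_end if movement_end is not None else onset + 1.0

    from .synthetic import EventMarker

    markers = [
        EventMarker(onset, "movement_onset"),
        EventMarker(end, "movement_end"),
    ]
    _, per_movement = _dynamic_labels(grid_idx, values, markers, policy)
    pos_of = {g: i for i, g in enumerate(grid_idx)}
    return prediction_time_from_positions(onset, per_movement[0], values, pos_of)


def evaluate_binary(y_true: np.ndarray, y_pred: np.ndarray) -> EvalResult:
    """Epoch-wise evaluation (used for the P300 target/standard task)."""
    y_true = np.asarray(y_true).astype(bool)
    y_pred = np.asarray(y_pred).astype(bool)
    counts = ConfusionCounts(
        tp=int(np.count_nonzero(y_pred & y_true)),
        tn=int(np.count_nonzero(~y_pred & ~y_true)),
        fp=int(np.count_nonzero(y_pred & ~y_true)),
        fn=int(np.count_nonzero(~y_pred & y_true)),
    )
    fnr, fpr, precision = error_rates(counts)
    return EvalResult(counts, balanced_accuracy(counts), fnr, fpr, precision)
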