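"""End-to-end session processing.

Protocol: two runs train the data-dependent stages (EMG grid search, xDAWN
spatial filters, feature standardization, PA-1 classifiers with inner CV),
the held-out run is streamed through preprocessing -> segmentation ->
detection -> fusion -> evaluation.  Training never sees test-run data.  The
same inference path can be re-run with a fixed-point quantization scheme for
the float-vs-fixed parity comparison; training always stays floating point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import classification as clf
from . import emg as emg_mod
from .evaluation import EvalResult, evaluate_binary, evaluate_stream
from .features import (
    StandardizationModel,
    fit_standardization,
    flatten_mrcp,
    local_straight_line_features,
    slope_projection,
    standardize,
)
from .fusion import FUSION_MODES, PredictionStream, combine, gate_p300
from .preprocessing import PreprocessingChain
from .quantization import QuantizationScheme
from .segmentation import GRID_S, LabelingPolicy, label_grid
from .spatial import SpatialFilterModel, apply_spatial_filter, fit_xdawn
from .synthetic import Recording

__all__ = [
    "SessionConfig",
    "TrainedModels",
    "SessionPredictions",
    "SessionResult",
    "preprocess_eeg",
    "train_session",
    "predict_session",
    "evaluate_session",
    "run_session",
    "cross_validate_runs",
    "compare_quantized",
]

MRCP_WINDOW = 5    # 200 ms at 25 Hz
P300_WINDOW = 25   # 1000 ms at 25 Hz


@dataclass
class SessionConfig:
    seed: int = 0
    fs: float = 5000.0
    n_components: int = 4
    emg_grid: emg_mod.EMGGrid = field(default_factory=emg_mod.EMGGrid)
    policy: LabelingPolicy = field(default_factory=LabelingPolicy)
    c_grid: tuple = clf.C_GRID
    pa1_epochs: int = 3
    fusion_modes: tuple = FUSION_MODES


@dataclass
class TrainedModels:
    emg_vf: emg_mod.VarianceFilterParams
    emg_at: emg_mod.AdaptiveThresholdParams
    emg_setup: emg_mod.ChannelSetup
    emg_train_ba: float
    mrcp_filter: SpatialFilterModel
    mrcp_std: StandardizationModel
    mrcp_clf: clf.PA1Model
    p300_filter: SpatialFilterModel
    p300_std: StandardizationModel
    p300_clf: clf.PA1Model


@dataclass
class SessionPredictions:
    emg: PredictionStream
    mrcp: PredictionStream
    gate: PredictionStream
    p300_true: np.ndarray       # per stimulus epoch, 1 = Target
    p300_pred: np.ndarray
    p300_times: np.ndarray      # stimulus marker times


@dataclass
class SessionResult:
    models: TrainedModels
    predictions: SessionPredictions
    per_mode: dict              # mode -> EvalResult
    p300: EvalResult


# ---------------------------------------------------------------------------
# shared inference pieces (float or quantized)


def preprocess_eeg(
    recording: Recording, quant: QuantizationScheme | None = None
) -> np.ndarray:
    """Detrend + decimate a raw EEG recording to the 25 Hz stream."""
    if quant is not None:
        return _preprocess_eeg_quantized(recording, quant)
    chain = PreprocessingChain(
        fs_in=recording.fs, n_channels=recording.samples.shape[1]
    )
    return chain.process_all(recording.samples)


def _mrcp_stream_features(
    decimated: np.ndarray,
    model: SpatialFilterModel,
    std: StandardizationModel | None,
    quant: QuantizationScheme | None,
) -> tuple[np.ndarray, np.ndarray]:
    """(end_times, feature matrix) for every sliding 200 ms window."""
    w = model.weights
    if quant is not None:
        w = quant.q_coeff(w)
    filtered = decimated @ w
    if quant is not None:
        filtered = quant.q_signal(filtered)
    n = filtered.shape[0]
    if n < MRCP_WINDOW:
        return np.array([]), np.empty((0, w.shape[1] * MRCP_WINDOW))
    from numpy.lib.stride_tricks import sliding_window_view

    # (n-4, components, 5): [i, c, s] = filtered[i+s, c] -> channel-major flat
    wins = sliding_window_view(filtered, MRCP_WINDOW, axis=0)
    feats = wins.reshape(wins.shape[0], -1)
    end_times = (np.arange(n - MRCP_WINDOW + 1) + MRCP_WINDOW) / 25.0
    if std is not None:
        feats = standardize(feats, std)
        if quant is not None:
            feats = quant.q_signal(feats)
    return end_times, feats


def _p300_epoch_features(
    decimated: np.ndarray,
    markers,
    model: SpatialFilterModel,
    std: StandardizationModel | None,
    quant: QuantizationScheme | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(stimulus times, is_target, feature matrix) per stimulus epoch."""
    w = model.weights
    q = slope_projection(P300_WINDOW)
    if quant is not None:
        w = quant.q_coeff(w)
        q = quant.q_coeff(q)
    n = decimated.shape[0]
    times, is_target, feats = [], [], []
    for m in markers:
        if m.kind not in ("standard", "target"):
            continue
        start = int(np.ceil(m.time * 25.0 - 1e-9))
        if start + P300_WINDOW > n:
            continue
        seg = decimated[start : start + P300_WINDOW] @ w
        if quant is not None:
            seg = quant.q_signal(seg)
        f = (q @ seg).T.reshape(-1)
        times.append(m.time)
        is_target.append(1 if m.kind == "target" else 0)
        feats.append(f)
    if not feats:
        d = model.n_components * q.shape[0]
        return np.array([]), np.array([], dtype=int), np.empty((0, d))
    feats = np.asarray(feats)
    if std is not None:
        feats = standardize(feats, std)
        if quant is not None:
            feats = quant.q_signal(feats)
    return np.asarray(times), np.asarray(is_target), feats


def _classify_batch(
    model: clf.PA1Model, feats: np.ndarray, quant: QuantizationScheme | None
) -> np.ndarray:
    if len(feats) == 0:
        return np.array([], dtype=np.uint8)
    if quant is None:
        preds, _ = clf.classify(model, feats)
        return preds
    w = quant.q_coeff(model.w)
    off = quant.q_coeff(model.decision_offset)
    scores = np.hstack([feats, np.ones((feats.shape[0], 1))]) @ w
    scores = quant.q_accum(scores)
    return (scores - off > 0).astype(np.uint8)


def _emg_stream(
    recording: Recording,
    models: "TrainedModels",
    quant: QuantizationScheme | None,
) -> PredictionStream:
    x = recording.samples
    if quant is not None:
        x = quant.q_signal(x)
    vf, at, setup = models.emg_vf, models.emg_at, models.emg_setup
    dec = emg_mod._decision_indices(x.shape[0], vf.fs)
    n_ch = x.shape[1]
    v_dec = np.empty((n_ch, len(dec)))
    t_dec = np.empty((n_ch, len(dec)))
    for c in range(n_ch):
        v = emg_mod.running_variance(x[:, c], vf)
        if quant is not None:
            v = quant.q_accum(np.nan_to_num(v, nan=0.0))
            v[: vf.n_samples - 1] = np.nan  # keep warm-up undefined
        t = emg_mod.adaptive_threshold(v, at, vf.fs)
        if quant is not None:
            valid = ~np.isnan(t)
            t[valid] = quant.q_accum(t[valid])
        v_dec[c] = v[dec]
        t_dec[c] = t[dec]
    idx = np.asarray(setup.channels)
    with np.errstate(invalid="ignore"):
        above = v_dec[idx] > t_dec[idx]
    preds = (above.sum(axis=0) >= setup.n_cot).astype(np.uint8)
    end_times = (dec + 1) / vf.fs
    return PredictionStream(end_times, preds, "emg")


def _align(streams: list[PredictionStream]) -> list[PredictionStream]:
    """Crop all streams to their common 40 ms grid span."""
    starts = [int(round(s.grid_times[0] / GRID_S)) for s in streams]
    ends = [int(round(s.grid_times[-1] / GRID_S)) for s in streams]
    lo, hi = max(starts), min(ends)
    if hi < lo:
        raise ValueError("streams have no common grid span")
    out = []
    for s, s0 in zip(streams, starts):
        a = lo - s0
        b = a + (hi - lo) + 1
        out.append(PredictionStream(s.grid_times[a:b], s.values[a:b], s.modality))
    return out


# ---------------------------------------------------------------------------
# training


def train_session(
    train_runs: list[tuple[Recording, Recording]],
    config: SessionConfig | None = None,
) -> TrainedModels:
    """Fit all data-dependent stages on (eeg, emg) training runs."""
    config = config or SessionConfig()
    if not train_runs:
        raise ValueError("no training runs")
    policy = config.policy

    # --- EMG: adaptive-threshold branch needs only the parameter search
    def eval_ba(end_times, preds, markers):
        stream = PredictionStream(end_times, preds, "emg")
        return evaluate_stream(stream, markers, policy).ba

    emg_recs = [emg for _, emg in train_runs]
    vf, at, setup, train_ba = emg_mod.grid_search_emg(
        emg_recs, config.emg_grid, eval_ba, fs=config.fs
    )

    # --- shared EEG preprocessing per training run
    decimated = [preprocess_eeg(eeg) for eeg, _ in train_runs]

    # --- MRCP branch
    mrcp_epochs, mrcp_labels = [], []
    for (eeg, _), dec in zip(train_runs, decimated):
        n = dec.shape[0]
        ends = np.arange(MRCP_WINDOW, n + 1)  # grid indices of window ends
        labels = label_grid(ends, eeg.markers, policy)
        for i, lab in enumerate(labels):
            if lab == "excluded":
                continue
            mrcp_epochs.append(dec[i : i + MRCP_WINDOW])
            mrcp_labels.append("movement" if lab == "movement" else "rest")
    mrcp_filter = fit_xdawn(
        mrcp_epochs, mrcp_labels, "movement", config.n_components
    )
    mrcp_feats = np.asarray(
        [flatten_mrcp(apply_spatial_filter(e, mrcp_filter)) for e in mrcp_epochs]
    )
    mrcp_std = fit_standardization(mrcp_feats)
    mrcp_y = np.where(np.asarray(mrcp_labels) == "movement", 1, -1)
    mrcp_clf = clf.fit_classifier(
        standardize(mrcp_feats, mrcp_std),
        mrcp_y,
        grid=config.c_grid,
        seed=config.seed,
        epochs=config.pa1_epochs,
    )

    # --- P300 branch
    p300_epochs, p300_labels = [], []
    for (eeg, _), dec in zip(train_runs, decimated):
        n = dec.shape[0]
        for m in eeg.markers:
            if m.kind not in ("standard", "target"):
                continue
            start = int(np.ceil(m.time * 25.0 - 1e-9))
            if start + P300_WINDOW > n:
                continue
            p300_epochs.append(dec[start : start + P300_WINDOW])
            p300_labels.append(m.kind)
    p300_filter = fit_xdawn(
        p300_epochs, p300_labels, "target", config.n_components
    )
    p300_feats = np.asarray(
        [
            local_straight_line_features(apply_spatial_filter(e, p300_filter))
            for e in p300_epochs
        ]
    )
    p300_std = fit_standardization(p300_feats)
    p300_y = np.where(np.asarray(p300_labels) == "target", 1, -1)
    p300_clf = clf.fit_classifier(
        standardize(p300_feats, p300_std),
        p300_y,
        grid=config.c_grid,
        seed=config.seed,
        epochs=config.pa1_epochs,
    )

    return TrainedModels(
        emg_vf=vf,
        emg_at=at,
        emg_setup=setup,
        emg_train_ba=train_ba,
        mrcp_filter=mrcp_filter,
        mrcp_std=mrcp_std,
        mrcp_clf=mrcp_clf,
        p300_filter=p300_filter,
        p300_std=p300_std,
        p300_clf=p300_clf,
    )


# ---------------------------------------------------------------------------
# inference + evaluation


def predict_session(
    test_eeg: Recording,
    test_emg: Recording,
    models: TrainedModels,
    quant: QuantizationScheme | None = None,
) -> SessionPredictions:
    """Run the full inference chain on one held-out run."""
    emg_stream = _emg_stream(test_emg, models, quant)

    dec = preprocess_eeg(test_eeg, quant=quant)

    mrcp_times, mrcp_feats = _mrcp_stream_features(
        dec, models.mrcp_filter, models.mrcp_std, quant
    )
    mrcp_preds = _classify_batch(models.mrcp_clf, mrcp_feats, quant)
    mrcp_stream = PredictionStream(mrcp_times, mrcp_preds, "mrcp")

    p300_times, p300_true, p300_feats = _p300_epoch_features(
        dec, test_eeg.markers, models.p300_filter, models.p300_std, quant
    )
    p300_pred = _classify_batch(models.p300_clf, p300_feats, quant)
    detections = p300_times[p300_pred.astype(bool)] if len(p300_times) else []

    emg_stream, mrcp_stream = _align([emg_stream, mrcp_stream])
    gate = gate_p300(detections, emg_stream.grid_times)

    if quant is not None:
        quant.warn_if_saturating()
    return SessionPredictions(
        emg=emg_stream,
        mrcp=mrcp_stream,
        gate=gate,
        p300_true=p300_true,
        p300_pred=p300_pred,
        p300_times=p300_times,
    )


def _preprocess_eeg_quantized(
    recording: Recording, quant: QuantizationScheme
) -> np.ndarray:
    """Quantized datapath: input, taps and every stage output snapped.

    The FIRs are applied directly (quantized taps no longer satisfy the
    float stages' exact unit-DC-gain contract, by design).
    """
    from scipy.signal import lfilter

    from .preprocessing import detrend

    chain = PreprocessingChain(
        fs_in=recording.fs, n_channels=recording.samples.shape[1]
    )
    t1 = quant.q_coeff(chain.stage1.fir_taps)
    t2 = quant.q_coeff(chain.stage2.fir_taps)
    x = quant.q_signal(recording.samples)
    out, _ = detrend(x, chain.detrend_state)
    out = quant.q_signal(out)
    out = lfilter(t1, [1.0], out, axis=0)[39::40]
    out = quant.q_signal(out)
    out = lfilter(t2, [1.0], out, axis=0)[4::5]
    return quant.q_signal(out)


def evaluate_session(
    predictions: SessionPredictions,
    markers,
    config: SessionConfig | None = None,
) -> tuple[dict, EvalResult]:
    """Score every fusion mode plus the P300 epoch task."""
    config = config or SessionConfig()
    per_mode = {}
    for mode in config.fusion_modes:
        fused = combine(predictions.emg, predictions.mrcp, predictions.gate, mode)
        per_mode[mode] = evaluate_stream(fused, markers, config.policy)
    p300_eval = evaluate_binary(predictions.p300_true, predictions.p300_pred)
    return per_mode, p300_eval


def run_session(
    train_runs: list[tuple[Recording, Recording]],
    test_run: tuple[Recording, Recording],
    config: SessionConfig | None = None,
    quant: QuantizationScheme | None = None,
    models: TrainedModels | None = None,
) -> SessionResult:
    """Train on the training runs, evaluate on the held-out run."""
    config = config or SessionConfig()
    if models is None:
        models = train_session(train_runs, config)
    test_eeg, test_emg = test_run
    preds = predict_session(test_eeg, test_emg, models, quant)
    per_mode, p300_eval = evaluate_session(preds, test_eeg.markers, config)
    return SessionResult(models, preds, per_mode, p300_eval)


def cross_validate_runs(
    runs: list[tuple[Recording, Recording]],
    config: SessionConfig | None = None,
) -> list[SessionResult]:
    """Offline protocol: every run serves once as the held-out evaluation
    run, the remaining runs train (all train/test assignments)."""
    results = []
    for i in range(len(runs)):
        train = [r for j, r in enumerate(runs) if j != i]
        results.append(run_session(train, runs[i], config))
    return results


def compare_quantized(
    result_float: SessionResult,
    test_run: tuple[Recording, Recording],
    config: SessionConfig | None = None,
    quant: QuantizationScheme | None = None,
) -> dict:
    """Re-run inference in fixed point and report parity with the float
    pipeline: per-modality decision agreement and per-mode BA difference."""
    config = config or SessionConfig()
    quant = quant or QuantizationScheme()
    test_eeg, test_emg = test_run
    preds_q = predict_session(test_eeg, test_emg, result_float.models, quant)
    per_mode_q, p300_q = evaluate_session(preds_q, test_eeg.markers, config)

    pf = result_float.predictions
    agreement = {}
    for name, a, b in (
        ("emg", pf.emg, preds_q.emg),
        ("mrcp", pf.mrcp, preds_q.mrcp),
        ("gate", pf.gate, preds_q.gate),
    ):
        agreement[name] = float(np.mean(a.values == b.values))
    fused_agreement = {}
    delta_ba = {}
    for mode in config.fusion_modes:
        ff = combine(pf.emg, pf.mrcp, pf.gate, mode)
        fq = combine(preds_q.emg, preds_q.mrcp, preds_q.gate, mode)
        fused_agreement[mode] = float(np.mean(ff.values == fq.values))
        delta_ba[mode] = per_mode_q[mode].ba - result_float.per_mode[mode].ba
    return {
        "agreement": agreement,
        "fused_agreement": fused_agreement,
        "delta_ba": delta_ba,
        "delta_ba_p300": p300_q.ba - result_float.p300.ba,
        "per_mode_quantized": per_mode_q,
        "saturation_fraction": quant.saturation_fraction,
    }
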