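"""Synthetic oddball / self-paced-movement sessions.

Emulates the experimental paradigm the rest of the package is built for: a
stream of visual Standard/Target stimuli (ISI 1 s +/- 100 ms), where each
Target instructs the subject to perform a reaching movement after a delay of
at least 2 s, and a run ends after a fixed number of correct movements.
Multichannel EEG and EMG are synthesized at 5 kHz by planting stylized
event-related templates in background noise:

* a P300 -- positive parietal deflection peaking ~350 ms after each Target;
* an MRCP -- slow central negativity ramping up and ending at movement onset;
* an EMG burst -- amplitude-modulated noise on the active-arm channels,
  beginning slightly *before* the movement-onset marker (muscle activity
  precedes the mechanically registered onset by an electromechanical delay).

EEG background noise is Gaussian shaped to a 1/f^beta spectrum, EMG baseline
noise is white.  Templates are scaled per channel by fixed topography vectors
(central channels for the MRCP, parietal for the P300, right-arm channels
1-4 for EMG).  Everything is deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ParadigmConfig",
    "TemplateConfig",
    "EventMarker",
    "Recording",
    "make_templates",
    "generate_session",
]

DEFAULT_FS = 5000.0

#: marker kinds understood throughout the package
MARKER_KINDS = ("standard", "target", "movement_onset", "movement_end")


@dataclass(frozen=True)
class ParadigmConfig:
    """Timing structure of one run of the oddball/movement paradigm."""

    n_movements: int = 40
    isi_mean: float = 1.0            # s
    isi_jitter: float = 0.1          # s, uniform half-width
    min_target_to_move: float = 2.0  # s, imposed wait after a Target
    target_probability: float = 0.2  # fraction of stimuli that are Targets
    run_duration_cap: float = 900.0  # s, hard stop
    move_delay_jitter: float = 0.5   # s, extra uniform delay past the minimum
    movement_duration: float = 1.0   # s, onset -> end

    def validate(self) -> None:
        if self.isi_mean <= 0:
            raise ValueError("isi_mean must be > 0")
        if not (0.0 < self.target_probability < 1.0):
            raise ValueError("target_probability must be in (0, 1)")
        if self.min_target_to_move < 0:
            raise ValueError("min_target_to_move must be >= 0")
        if self.isi_jitter < 0 or self.isi_jitter >= self.isi_mean:
            raise ValueError("isi_jitter must be in [0, isi_mean)")
        if self.min_target_to_move > self.run_duration_cap:
            raise ValueError(
                "impossible timing: min_target_to_move exceeds run_duration_cap"
            )


@dataclass(frozen=True)
class TemplateConfig:
    """Amplitudes, durations and noise levels of the planted waveforms.

    Amplitudes are in microvolts.  ``emg_lead`` is the electromechanical
    lead of the EMG burst over the movement-onset marker.
    """

    mrcp_amplitude: float = 8.0       # uV at onset
    mrcp_ramp_duration: float = 1.5   # s before onset
    p300_amplitude: float = 10.0      # uV at peak
    p300_latency: float = 0.35        # s post-Target
    p300_width: float = 0.12          # s, Gaussian sigma of the bump
    emg_burst_amplitude: float = 40.0  # uV (std of burst noise)
    emg_burst_duration: float = 1.0   # s
    emg_lead: float = 0.15            # s the burst precedes the onset marker
    noise_sd: float = 5.0             # uV
    noise_spectral_exponent: float = 1.0  # EEG noise ~ 1/f^beta

    def validate(self) -> None:
        for name in (
            "mrcp_amplitude", "mrcp_ramp_duration", "p300_amplitude",
            "p300_latency", "p300_width", "emg_burst_amplitude",
            "emg_burst_duration", "emg_lead", "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class EventMarker:
    time: float  # seconds from recording start
    kind: str    # one of MARKER_KINDS

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("marker time must be >= 0")
        if self.kind not in MARKER_KINDS:
            raise ValueError(f"unknown marker kind {self.kind!r}")


@dataclass
class Recording:
    """A raw multichannel session: samples in uV, fs in Hz, sorted markers."""

    samples: np.ndarray            # (n_time, n_channels)
    fs: float
    channel_names: list[str]
    markers: list[EventMarker] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be (n_time, n_channels)")
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        if len(self.channel_names) != self.samples.shape[1]:
            raise ValueError("channel_names length mismatch")
        self.markers = sorted(self.markers, key=lambda m: m.time)
        dur = self.samples.shape[0] / self.fs
        for m in self.markers:
            if m.time >= dur:
                raise ValueError(f"marker at {m.time} s outside recording ({dur} s)")

    @property
    def duration(self) -> float:
        return self.samples.shape[0] / self.fs

    def marker_times(self, kind: str) -> np.ndarray:
        return np.array([m.time for m in self.markers if m.kind == kind])


# ---------------------------------------------------------------------------
# templates


def make_templates(
    templates: TemplateConfig, fs: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (mrcp, p300, emg_envelope) single-channel waveforms at ``fs``.

    The MRCP waveform is a monotonically increasing-magnitude negativity
    spanning ``mrcp_ramp_duration`` and ending (at its most negative value)
    at movement onset.  The P300 waveform is a positive Gaussian bump peaking
    at ``p300_latency``.  The EMG envelope is a smoothed rectangular gate of
    ``emg_burst_duration`` used to modulate burst noise.
    """
    if fs <= 0:
        raise ValueError("fs must be > 0")
    templates.validate()

    n_mrcp = max(int(round(templates.mrcp_ramp_duration * fs)), 1)
    # quadratic ramp: slow build-up, steepest just before onset
    t = np.arange(1, n_mrcp + 1) / n_mrcp
    mrcp = -templates.mrcp_amplitude * t**2

    n_p300 = max(int(round(2 * templates.p300_latency * fs)), 1)
    tt = np.arange(n_p300) / fs
    width = max(templates.p300_width, 1.0 / fs)
    p300 = templates.p300_amplitude * np.exp(
        -0.5 * ((tt - templates.p300_latency) / width) ** 2
    )

    n_emg = max(int(round(templates.emg_burst_duration * fs)), 1)
    env = np.ones(n_emg)
    ramp = min(max(int(round(0.02 * fs)), 1), n_emg // 2)
    if ramp > 0:
        edge = np.linspace(0.0, 1.0, ramp)
        env[:ramp] = edge
        env[-ramp:] = edge[::-1]
    if templates.emg_burst_amplitude == 0:
        env = np.zeros(n_emg)

    return mrcp, p300, env


def _colored_noise(rng: np.random.Generator, n: int, beta: float) -> np.ndarray:
    """Unit-variance Gaussian noise with a 1/f^beta amplitude spectrum."""
    white = rng.standard_normal(n)
    if beta == 0:
        return white
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-beta / 2.0)
    shaping[0] = 0.0  # no DC blow-up
    out = np.fft.irfft(spec * shaping, n=n)
    sd = out.std()
    return out / sd if sd > 0 else out


def _default_topographies(n_eeg: int, n_emg: int):
    """Fixed per-channel template loadings (MRCP central, P300 parietal,
    EMG on the right-arm channels 1-4)."""
    half = max(n_eeg // 2, 1)
    mrcp_topo = np.zeros(n_eeg)
    p300_topo = np.zeros(n_eeg)
    front = np.linspace(1.0, 0.6, half)
    mrcp_topo[:half] = front
    p300_topo[half:] = np.linspace(1.0, 0.6, n_eeg - half) if n_eeg > half else 0.0
    emg_topo = np.zeros(n_emg)
    active = min(n_emg, 4)
    emg_topo[:active] = np.linspace(1.0, 0.6, active)
    return mrcp_topo, p300_topo, emg_topo


def _eeg_channel_names(n: int) -> list[str]:
    return [f"EEG{i + 1:03d}" for i in range(n)]


def _emg_channel_names(n: int) -> list[str]:
    return [f"EMG{i + 1}" for i in range(n)]


# ---------------------------------------------------------------------------
# session generation


def _draw_marker_schedule(
    paradigm: ParadigmConfig, rng: np.random.Generator
) -> list[EventMarker]:
    """Draw the stimulus/movement marker stream for one run."""
    markers: list[EventMarker] = []
    t = 1.0  # first stimulus after a short lead-in
    n_moves = 0
    pending_until = -np.inf  # suppress Targets while a movement is pending
    while n_moves < paradigm.n_movements:
        if t > paradigm.run_duration_cap:
            raise RuntimeError(
                "run_duration_cap reached before the requested movement count"
            )
        is_target = (
            rng.random() < paradigm.target_probability and t >= pending_until
        )
        if is_target:
            markers.append(EventMarker(t, "target"))
            delay = paradigm.min_target_to_move + rng.uniform(
                0.0, paradigm.move_delay_jitter
            )
            onset = t + delay
            end = onset + paradigm.movement_duration
            markers.append(EventMarker(onset, "movement_onset"))
            markers.append(EventMarker(end, "movement_end"))
            n_moves += 1
            pending_until = end + 1.0
        else:
            markers.append(EventMarker(t, "standard"))
        t += rng.uniform(
            paradigm.isi_mean - paradigm.isi_jitter,
            paradigm.isi_mean + paradigm.isi_jitter,
        )
    return sorted(markers, key=lambda m: m.time)


def _add_at(sig: np.ndarray, start_idx: int, wave: np.ndarray) -> None:
    """Add ``wave`` into ``sig`` starting at ``start_idx``, clipping edges."""
    n = sig.shape[0]
    a = max(start_idx, 0)
    b = min(start_idx + len(wave), n)
    if b <= a:
        return
    sig[a:b] += wave[a - start_idx : b - start_idx]


def generate_session(
    paradigm: ParadigmConfig,
    templates: TemplateConfig,
    n_eeg_channels: int = 8,
    n_emg_channels: int = 4,
    seed: int = 0,
    fs: float = DEFAULT_FS,
    mrcp_topography: np.ndarray | None = None,
    p300_topography: np.ndarray | None = None,
    emg_topography: np.ndarray | None = None,
) -> tuple[Recording, Recording]:
    """Generate one run; returns ``(eeg, emg)`` Recordings sharing markers."""
    paradigm.validate()
    templates.validate()
    rng = np.random.default_rng(seed)

    markers = _draw_marker_schedule(paradigm, rng)
    duration = min(markers[-1].time + 2.0, paradigm.run_duration_cap)
    n = int(round(duration * fs))

    mrcp_topo, p300_topo, emg_topo = _default_topographies(
        n_eeg_channels, n_emg_channels
    )
    if mrcp_topography is not None:
        mrcp_topo = np.asarray(mrcp_topography, dtype=float)
    if p300_topography is not None:
        p300_topo = np.asarray(p300_topography, dtype=float)
    if emg_topography is not None:
        emg_topo = np.asarray(emg_topography, dtype=float)

    mrcp_w, p300_w, emg_env = make_templates(templates, fs)

    # single-channel signal tracks, scaled per channel by the topographies
    mrcp_track = np.zeros(n)
    p300_track = np.zeros(n)
    onsets = [m.time for m in markers if m.kind == "movement_onset"]
    targets = [m.time for m in markers if m.kind == "target"]
    for t0 in targets:
        _add_at(p300_track, int(round(t0 * fs)), p300_w)
    n_rebound = int(round(0.5 * fs))
    rebound = (
        -templates.mrcp_amplitude * (1.0 - np.arange(1, n_rebound + 1) / n_rebound)
    )
    for t0 in onsets:
        i0 = int(round(t0 * fs))
        _add_at(mrcp_track, i0 - len(mrcp_w), mrcp_w)
        # return to baseline after onset (in-movement, excluded from scoring)
        _add_at(mrcp_track, i0, rebound)

    eeg = np.empty((n, n_eeg_channels))
    for c in range(n_eeg_channels):
        noise = (
            templates.noise_sd
            * _colored_noise(rng, n, templates.noise_spectral_exponent)
            if templates.noise_sd > 0
            else np.zeros(n)
        )
        eeg[:, c] = noise + mrcp_topo[c] * mrcp_track + p300_topo[c] * p300_track

    emg = np.empty((n, n_emg_channels))
    for c in range(n_emg_channels):
        base = (
            templates.noise_sd * rng.standard_normal(n)
            if templates.noise_sd > 0
            else np.zeros(n)
        )
        emg[:, c] = base
        if emg_topo[c] > 0 and templates.emg_burst_amplitude > 0:
            for t0 in onsets:
                i0 = int(round((t0 - templates.emg_lead) * fs))
                burst = (
                    templates.emg_burst_amplitude
                    * emg_env
                    * rng.standard_normal(len(emg_env))
                )
                _add_at(emg[:, c], i0, emg_topo[c] * burst)

    eeg_rec = Recording(eeg, fs, _eeg_channel_names(n_eeg_channels), list(markers))
    emg_rec = Recording(emg, fs, _emg_channel_names(n_emg_channels), list(markers))
    return eeg_rec, emg_rec


def generate_runs(
    n_runs: int,
    paradigm: ParadigmConfig,
    templates: TemplateConfig,
    n_eeg_channels: int = 8,
    n_emg_channels: int = 4,
    seed: int = 0,
) -> list[tuple[Recording, Recording]]:
    """Generate ``n_runs`` independent runs with per-run derived seeds."""
    ss = np.random.SeedSequence(seed)
    run_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_runs)]
    return [
        generate_session(
            paradigm, templates, n_eeg_channels, n_emg_channels, seed=s
        )
        for s in run_seeds
    ]
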