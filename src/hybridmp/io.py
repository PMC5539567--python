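"""File formats: BrainVision Core triples, columnar TSV, YAML configs.

The BrainVision Core Data Format stores a recording as three companion
files: an INI-style header (.vhdr) naming the data and marker files, a
marker file (.vmrk) with 1-based sample positions, and the raw binary data
(.eeg).  Only the subset this package writes is read back: binary
IEEE_FLOAT_32, multiplexed orientation, units of microvolts.  The TSV dialect
is one column per channel plus a ``<base>_markers.tsv`` sidecar with columns
``time_s`` and ``kind``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .synthetic import EventMarker, Recording

__all__ = [
    "write_brainvision",
    "read_brainvision",
    "write_tsv",
    "read_tsv",
    "load_config",
    "DEFAULT_MARKER_MAP",
]

#: .vmrk marker description <-> package marker kind (identity by default)
DEFAULT_MARKER_MAP = {k: k for k in ("standard", "target", "movement_onset", "movement_end")}


def write_brainvision(recording: Recording, base_path) -> Path:
    """Write ``base.vhdr`` / ``base.vmrk`` / ``base.eeg``; returns the header path."""
    base = Path(base_path)
    base.parent.mkdir(parents=True, exist_ok=True)
    stem = base.name
    vhdr = base.with_suffix(".vhdr")
    vmrk = base.with_suffix(".vmrk")
    eeg = base.with_suffix(".eeg")

    n_ch = recording.samples.shape[1]
    sampling_interval_us = 1e6 / recording.fs
    ch_lines = "\n".join(
        f"Ch{i + 1}={name},,1,µV" for i, name in enumerate(recording.channel_names)
    )
    vhdr.write_text(
        "Brain Vision Data Exchange Header File Version 1.0\n"
        "; Written by hybridmp\n\n"
        "[Common Infos]\n"
        "Codepage=UTF-8\n"
        f"DataFile={stem}.eeg\n"
        f"MarkerFile={stem}.vmrk\n"
        "DataFormat=BINARY\n"
        "DataOrientation=MULTIPLEXED\n"
        f"NumberOfChannels={n_ch}\n"
        f"SamplingInterval={sampling_interval_us:g}\n\n"
        "[Binary Infos]\n"
        "BinaryFormat=IEEE_FLOAT_32\n\n"
        "[Channel Infos]\n"
        f"{ch_lines}\n",
        encoding="utf-8",
    )

    lines = [
        "Brain Vision Data Exchange Marker File, Version 1.0\n",
        "[Common Infos]\n",
        "Codepage=UTF-8\n",
        f"DataFile={stem}.eeg\n\n",
        "[Marker Infos]\n",
        "Mk1=New Segment,,1,1,0,0\n",
    ]
    for i, m in enumerate(recording.markers, start=2):
        pos = int(round(m.time * recording.fs)) + 1  # 1-based sample position
        lines.append(f"Mk{i}=Stimulus,{m.kind},{pos},1,0\n")
    vmrk.write_text("".join(lines), encoding="utf-8")

    recording.samples.astype("<f4").tofile(eeg)
    return vhdr


def _parse_ini(text: str) -> dict[str, dict[str, str]]:
    sections: dict[str, dict[str, str]] = {}
    current: dict[str, str] | None = None
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith(";"):
            continue
        if line.startswith("[") and line.endswith("]"):
            current = sections.setdefault(line[1:-1], {})
        elif "=" in line and current is not None:
            key, _, val = line.partition("=")
            current[key.strip()] = val.strip()
    return sections


def read_brainvision(path, marker_map: dict[str, str] | None = None) -> Recording:
    """Read a .vhdr triple written by :func:`write_brainvision`.

    ``marker_map`` translates .vmrk marker descriptions to package marker
    kinds; unmapped descriptions are skipped.
    """
    marker_map = marker_map or DEFAULT_MARKER_MAP
    vhdr = Path(path)
    if not vhdr.exists():
        raise FileNotFoundError(f"header file not found: {vhdr}")
    hdr = _parse_ini(vhdr.read_text(encoding="utf-8"))
    common = hdr.get("Common Infos", {})
    binary = hdr.get("Binary Infos", {})

    if common.get("DataFormat", "BINARY") != "BINARY":
        raise ValueError(f"unsupported DataFormat in {vhdr}")
    if common.get("DataOrientation", "MULTIPLEXED") != "MULTIPLEXED":
        raise ValueError(f"unsupported DataOrientation in {vhdr}")
    if binary.get("BinaryFormat") != "IEEE_FLOAT_32":
        raise ValueError(
            f"unsupported BinaryFormat {binary.get('BinaryFormat')!r} in {vhdr}"
        )

    n_ch = int(common["NumberOfChannels"])
    fs = 1e6 / float(common["SamplingInterval"])
    names = []
    for i in range(n_ch):
        entry = hdr.get("Channel Infos", {}).get(f"Ch{i + 1}", f"CH{i + 1},,1")
        names.append(entry.split(",")[0])

    eeg_path = vhdr.parent / common.get("DataFile", vhdr.with_suffix(".eeg").name)
    if not eeg_path.exists():
        raise FileNotFoundError(f"data file not found: {eeg_path}")
    raw = np.fromfile(eeg_path, dtype="<f4")
    if raw.size % n_ch != 0:
        raise ValueError(
            f"truncated data file {eeg_path}: {raw.size} values not divisible "
            f"by {n_ch} channels"
        )
    samples = raw.reshape(-1, n_ch).astype(np.float64)

    markers: list[EventMarker] = []
    vmrk_path = vhdr.parent / common.get("MarkerFile", vhdr.with_suffix(".vmrk").name)
    if vmrk_path.exists():
        mrk = _parse_ini(vmrk_path.read_text(encoding="utf-8"))
        for key in sorted(
            mrk.get("Marker Infos", {}),
            key=lambda k: int(k[2:]),
        ):
            fields = mrk["Marker Infos"][key].split(",")
            if len(fields) < 3:
                continue
            mtype, desc, pos = fields[0], fields[1], fields[2]
            if mtype == "New Segment":
                continue
            kind = marker_map.get(desc)
            if kind is None:
                continue
            markers.append(EventMarker((int(pos) - 1) / fs, kind))
    else:
        raise FileNotFoundError(f"marker file not found: {vmrk_path}")

    return Recording(samples, fs, names, markers)


def write_tsv(recording: Recording, path) -> Path:
    """Write samples as TSV (one column per channel) plus a marker sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = "\t".join(recording.channel_names)
    np.savetxt(
        path,
        recording.samples,
        delimiter="\t",
        header=header,
        comments="",
        fmt="%.9g",
    )
    sidecar = path.with_name(path.stem + "_markers.tsv")
    with open(sidecar, "w", encoding="utf-8") as fh:
        fh.write("time_s\tkind\n")
        for m in recording.markers:
            fh.write(f"{m.time:.6f}\t{m.kind}\n")
    return path


def read_tsv(path, fs: float) -> Recording:
    """Read a TSV written by :func:`write_tsv` (fs is not stored in TSV)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"TSV file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        names = fh.readline().strip().split("\t")
    samples = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    markers = []
    sidecar = path.with_name(path.stem + "_markers.tsv")
    if sidecar.exists():
        with open(sidecar, encoding="utf-8") as fh:
            fh.readline()
            for line in fh:
                t, kind = line.strip().split("\t")
                markers.append(EventMarker(float(t), kind))
    return Recording(samples, fs, names, markers)


def write_predictions_tsv(stream, path) -> Path:
    """Prediction stream as TSV: segment_end_s, prediction."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("segment_end_s\tprediction\n")
        for t, v in zip(stream.grid_times, stream.values):
            fh.write(f"{t:.3f}\t{int(v)}\n")
    return path


def read_predictions_tsv(path, modality: str = "fused"):
    from .fusion import PredictionStream

    path = Path(path)
    data = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    return PredictionStream(data[:, 0], data[:, 1].astype(np.uint8), modality)


def load_config(path) -> dict:
    """Load a YAML key-value configuration file."""
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg
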