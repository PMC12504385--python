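"""Data model and on-disk container for synchronized EEG/fNIRS recordings.

A recording is one subject/session pair: a 30-channel EEG stream, two
36-channel fNIRS streams (oxy- and deoxyhemoglobin concentration changes),
and the event markers describing the task paradigm (instruction / task /
rest phases with class labels).

On disk a recording is a directory — one ``.npy`` float64 array per stream
plus a ``meta.json`` sidecar carrying rates, channel names, events and
provenance — inspectable and language-portable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

EEG = "EEG"
FNIRS_HBO = "FNIRS_HBO"
FNIRS_HBR = "FNIRS_HBR"
_MODALITY_TAGS = (EEG, FNIRS_HBO, FNIRS_HBR)

PARADIGM_CLASSES = {
    "nback": ["0back", "2back", "3back"],
    "wg": ["WG", "BL"],
}

PHASES = ("instruction", "task", "rest")


@dataclass
class ModalityStream:
    """One modality's dense [channels x samples] array plus its metadata."""

    data: np.ndarray
    sampling_rate: float
    channel_names: list[str]
    modality_tag: str
    units: str

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("stream data must be 2-D [channels x samples]")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.modality_tag not in _MODALITY_TAGS:
            raise ValueError(f"unknown modality_tag {self.modality_tag!r}")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.modality_tag}: {self.data.shape[0]} rows but "
                f"{len(self.channel_names)} channel names")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.sampling_rate

    def validate_finite(self) -> None:
        bad = ~np.isfinite(self.data)
        if bad.any():
            ch = int(np.argwhere(bad)[0, 0])
            raise ValueError(
                f"non-finite sample in {self.modality_tag} channel "
                f"{self.channel_names[ch]!r}")


@dataclass
class EventMarker:
    """Half-open interval [onset, onset + duration) in seconds from start."""

    onset_s: float
    duration_s: float
    label: str
    phase: str

    def __post_init__(self):
        if self.onset_s < 0:
            raise ValueError("onset_s must be >= 0")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class Recording:
    subject_id: str
    paradigm: str
    eeg: ModalityStream
    fnirs_hbo: ModalityStream
    fnirs_hbr: ModalityStream
    events: list[EventMarker]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.paradigm not in PARADIGM_CLASSES:
            raise ValueError(f"unknown paradigm {self.paradigm!r}")
        allowed = set(PARADIGM_CLASSES[self.paradigm]) | {"instruction", "rest"}
        for ev in self.events:
            if ev.phase == "task" and ev.label not in PARADIGM_CLASSES[self.paradigm]:
                raise ValueError(
                    f"task label {ev.label!r} invalid for paradigm {self.paradigm!r}")
        del allowed
        end = self.events_end_s
        for st in self.streams():
            if st.duration_s < end - 1e-9:
                raise ValueError(
                    f"{st.modality_tag} stream ({st.duration_s:.2f}s) ends before "
                    f"the last event ({end:.2f}s)")

    def streams(self) -> tuple[ModalityStream, ModalityStream, ModalityStream]:
        return (self.eeg, self.fnirs_hbo, self.fnirs_hbr)

    @property
    def events_end_s(self) -> float:
        return max((ev.offset_s for ev in self.events), default=0.0)

    def task_events(self) -> list[EventMarker]:
        return [ev for ev in self.events if ev.phase == "task"]


@dataclass
class BimodalWindow:
    """One classifier sample: time-locked EEG and fNIRS patches."""

    eeg_patch: np.ndarray       # [n_eeg_ch x n_eeg_samples]
    fnirs_patch: np.ndarray     # [n_fnirs_ch x n_fnirs_samples], HbO ; HbR stacked
    label: int
    subject_id: str
    trial_id: int
    window_start_s: float


@dataclass
class WindowSet:
    windows: list[BimodalWindow]
    class_names: list[str]
    window_spec: tuple[float, float]    # (window_len_s, step_s)
    normalization_tag: str = "none"

    def __post_init__(self):
        for w in self.windows:
            if not 0 <= w.label < len(self.class_names):
                raise ValueError(f"label index {w.label} out of range")
        shapes = {(w.eeg_patch.shape, w.fnirs_patch.shape) for w in self.windows}
        if len(shapes) > 1:
            raise ValueError(f"inhomogeneous window shapes: {shapes}")

    def __len__(self) -> int:
        return len(self.windows)

    def labels(self) -> np.ndarray:
        return np.array([w.label for w in self.windows], dtype=np.int64)

    def trial_ids(self) -> np.ndarray:
        return np.array([w.trial_id for w in self.windows], dtype=np.int64)

    def subset(self, idx) -> "WindowSet":
        return WindowSet([self.windows[i] for i in np.asarray(idx, dtype=int)],
                         self.class_names, self.window_spec, self.normalization_tag)

    def stacked(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(eeg [N,C,T], fnirs [N,C,T], labels [N]) as float32 batches."""
        eeg = np.stack([w.eeg_patch for w in self.windows]).astype(np.float32)
        fnirs = np.stack([w.fnirs_patch for w in self.windows]).astype(np.float32)
        return eeg, fnirs, self.labels()


_STREAM_FILES = {"eeg": EEG, "fnirs_hbo": FNIRS_HBO, "fnirs_hbr": FNIRS_HBR}


def save_recording(rec: Recording, path) -> Path:
    """Write ``rec`` to a directory container; rejects non-finite samples."""
    for st in rec.streams():
        st.validate_finite()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": 1,
        "subject_id": rec.subject_id,
        "paradigm": rec.paradigm,
        "provenance": rec.provenance,
        "events": [asdict(ev) for ev in rec.events],
        "streams": {},
    }
    for fname, attr in (("eeg", "eeg"), ("fnirs_hbo", "fnirs_hbo"),
                        ("fnirs_hbr", "fnirs_hbr")):
        st: ModalityStream = getattr(rec, attr)
        np.save(path / f"{fname}.npy", st.data.astype(np.float64))
        meta["streams"][fname] = {
            "sampling_rate": st.sampling_rate,
            "channel_names": st.channel_names,
            "modality_tag": st.modality_tag,
            "units": st.units,
            "n_channels": st.n_channels,
            "n_samples": int(st.data.shape[1]),
        }
    (path / "meta.json").write_text(json.dumps(meta, indent=2))
    return path


def load_recording(path) -> Recording:
    """Load and validate a container written by :func:`save_recording`."""
    path = Path(path)
    sidecar = path / "meta.json"
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    if meta.get("paradigm") not in PARADIGM_CLASSES:
        raise ValueError(f"unknown paradigm tag {meta.get('paradigm')!r}")
    streams = {}
    for fname in _STREAM_FILES:
        arr = np.load(path / f"{fname}.npy")
        sm = meta["streams"][fname]
        if arr.shape != (sm["n_channels"], sm["n_samples"]):
            raise ValueError(
                f"{fname}: sidecar declares shape "
                f"({sm['n_channels']}, {sm['n_samples']}), array has {arr.shape}")
        streams[fname] = ModalityStream(
            data=arr, sampling_rate=sm["sampling_rate"],
            channel_names=sm["channel_names"], modality_tag=sm["modality_tag"],
            units=sm["units"])
        streams[fname].validate_finite()
    events = [EventMarker(**ev) for ev in meta["events"]]
    return Recording(subject_id=meta["subject_id"], paradigm=meta["paradigm"],
                     eeg=streams["eeg"], fnirs_hbo=streams["fnirs_hbo"],
                     fnirs_hbr=streams["fnirs_hbr"], events=events,
                     provenance=meta.get("provenance", {}))


def save_window_set(ws: WindowSet, path) -> Path:
    """One .npz per window set: stacked patches + labels + bookkeeping."""
    path = Path(path)
    eeg = np.stack([w.eeg_patch for w in ws.windows])
    fnirs = np.stack([w.fnirs_patch for w in ws.windows])
    meta = {
        "class_names": ws.class_names,
        "window_spec": list(ws.window_spec),
        "normalization_tag": ws.normalization_tag,
        "subject_ids": [w.subject_id for w in ws.windows],
    }
    np.savez(path, eeg=eeg, fnirs=fnirs, labels=ws.labels(),
             trial_ids=ws.trial_ids(),
             window_starts=np.array([w.window_start_s for w in ws.windows]),
             meta=np.array(json.dumps(meta)))
    return path


def load_window_set(path) -> WindowSet:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        windows = [
            BimodalWindow(eeg_patch=z["eeg"][i], fnirs_patch=z["fnirs"][i],
                          label=int(z["labels"][i]),
                          subject_id=meta["subject_ids"][i],
                          trial_id=int(z["trial_ids"][i]),
                          window_start_s=float(z["window_starts"][i]))
            for i in range(z["labels"].shape[0])
        ]
    return WindowSet(windows, meta["class_names"], tuple(meta["window_spec"]),
                     meta["normalization_tag"])


def check_alignment(rec: Recording) -> dict:
    """Report-only synchrony check between the two modalities.

    Drift is the absolute duration difference between the EEG stream and the
    fNIRS streams; it is flagged when it exceeds one fNIRS sample period.
    """
    durations = {st.modality_tag: st.duration_s for st in rec.streams()}
    fnirs_dur = min(rec.fnirs_hbo.duration_s, rec.fnirs_hbr.duration_s)
    drift = abs(rec.eeg.duration_s - fnirs_dur)
    period = 1.0 / rec.fnirs_hbo.sampling_rate
    event_span = rec.events_end_s
    covered = all(st.duration_s >= event_span - 1e-9 for st in rec.streams())
    return {
        "stream_durations_s": durations,
        "event_span_s": event_span,
        "drift_s": drift,
        "fnirs_sample_period_s": period,
        "drift_flag": drift > period,
        "events_covered": covered,
        "passed": covered and drift <= period,
    }
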