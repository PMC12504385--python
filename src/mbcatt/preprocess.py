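"""Signal conditioning and epoching.

Pipeline order is fixed: bandpass filter -> resample -> segment trials ->
slide windows -> normalize.  Only the task period of each trial block is
retained (instruction and rest samples are discarded); windows never
straddle a trial boundary because segmentation happens first.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .signal_store import (BimodalWindow, ModalityStream, Recording, WindowSet,
                           PARADIGM_CLASSES)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry; defaults: 5 s windows advanced by 1 s."""

    window_len_s: float = 5.0
    step_s: float = 1.0

    def __post_init__(self):
        if not 0 < self.step_s <= self.window_len_s:
            raise ValueError("need 0 < step_s <= window_len_s")


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth bandpass; defaults to the 1-40 Hz EEG band, zero phase."""

    low_hz: float = 1.0
    high_hz: float = 40.0
    order: int = 4
    zero_phase: bool = True

    def validate_for_rate(self, fs: float) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError("need 0 < low_hz < high_hz")
        if self.high_hz >= fs / 2:
            raise ValueError(
                f"high edge {self.high_hz} Hz >= Nyquist of a {fs} Hz stream")


def bandpass(stream: ModalityStream, spec: FilterSpec = FilterSpec()) -> ModalityStream:
    """Zero-phase Butterworth bandpass; preserves shape and sampling rate."""
    spec.validate_for_rate(stream.sampling_rate)
    sos = sps.butter(spec.order, [spec.low_hz, spec.high_hz],
                     btype="bandpass", fs=stream.sampling_rate, output="sos")
    if spec.zero_phase:
        out = sps.sosfiltfilt(sos, stream.data, axis=1)
    else:
        out = sps.sosfilt(sos, stream.data, axis=1)
    return replace(stream, data=out)


def resample(stream: ModalityStream, target_hz: float) -> ModalityStream:
    """Polyphase anti-aliased downsampling; handles non-integer ratios
    (e.g. 10.4 -> 10 Hz) through a rational approximation."""
    fs = stream.sampling_rate
    if target_hz > fs:
        raise ValueError("upsampling is not supported")
    if math.isclose(target_hz, fs):
        return stream
    frac = Fraction(target_hz / fs).limit_denominator(1000)
    out = sps.resample_poly(stream.data, frac.numerator, frac.denominator, axis=1)
    want = round(stream.data.shape[1] * target_hz / fs)
    out = out[:, :want]
    if out.shape[1] < want:  # pad by edge value in the rare off-by-one case
        out = np.pad(out, ((0, 0), (0, want - out.shape[1])), mode="edge")
    return replace(stream, data=out, sampling_rate=target_hz)


@dataclass
class TrialEpoch:
    """The task-period slice of one trial block, both modalities."""

    eeg: np.ndarray          # [n_eeg_ch x n_samples]
    fnirs: np.ndarray        # [2*n_fnirs_ch x n_samples], HbO stacked on HbR
    label: str
    trial_id: int
    onset_s: float
    duration_s: float
    eeg_rate: float
    fnirs_rate: float


def segment_trials(rec: Recording) -> list[TrialEpoch]:
    """One epoch per task-phase marker, spanning [onset, onset+duration).

    Trials whose task period extends past any stream end are dropped with a
    warning rather than truncated.
    """
    epochs: list[TrialEpoch] = []
    eeg_fs = rec.eeg.sampling_rate
    f_fs = rec.fnirs_hbo.sampling_rate
    for trial_id, ev in enumerate(rec.task_events()):
        e0 = round(ev.onset_s * eeg_fs)
        e1 = round(ev.offset_s * eeg_fs)
        f0 = round(ev.onset_s * f_fs)
        f1 = round(ev.offset_s * f_fs)
        if e1 > rec.eeg.data.shape[1] or f1 > rec.fnirs_hbo.data.shape[1]:
            log.warning("trial %d (%s @ %.1fs) extends past stream end; dropped",
                        trial_id, ev.label, ev.onset_s)
            continue
        fnirs = np.vstack([rec.fnirs_hbo.data[:, f0:f1],
                           rec.fnirs_hbr.data[:, f0:f1]])
        epochs.append(TrialEpoch(
            eeg=rec.eeg.data[:, e0:e1], fnirs=fnirs, label=ev.label,
            trial_id=trial_id, onset_s=ev.onset_s, duration_s=ev.duration_s,
            eeg_rate=eeg_fs, fnirs_rate=f_fs))
    return epochs


def window_count(duration_s: float, spec: WindowSpec) -> int:
    """floor((T - window) / step) + 1, zero when the epoch is too short."""
    if duration_s < spec.window_len_s:
        return 0
    # guard float jitter: 40.0 - 5.0 must give exactly 35 steps of 1.0
    return int(math.floor((duration_s - spec.window_len_s) / spec.step_s + 1e-9)) + 1


def slide_windows(epoch: TrialEpoch, spec: WindowSpec, label_index: int,
                  subject_id: str) -> list[BimodalWindow]:
    """Cut time-locked fixed-length windows from one trial epoch.

    EEG and fNIRS patches always cover the same absolute time interval;
    start times are onset + k * step for k = 0 .. count-1.
    """
    n = window_count(epoch.duration_s, spec)
    n_eeg = round(spec.window_len_s * epoch.eeg_rate)
    n_f = round(spec.window_len_s * epoch.fnirs_rate)
    out = []
    for k in range(n):
        t = k * spec.step_s
        e0 = round(t * epoch.eeg_rate)
        f0 = round(t * epoch.fnirs_rate)
        out.append(BimodalWindow(
            eeg_patch=epoch.eeg[:, e0:e0 + n_eeg],
            fnirs_patch=epoch.fnirs[:, f0:f0 + n_f],
            label=label_index, subject_id=subject_id, trial_id=epoch.trial_id,
            window_start_s=epoch.onset_s + t))
    return out


NORMALIZE_MODES = ("none", "zscore_per_channel")


def normalize_window(w: BimodalWindow, mode: str = "zscore_per_channel") -> BimodalWindow:
    """Per-channel z-scoring of both patches (sd floored at 1e-8)."""
    if mode not in NORMALIZE_MODES:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if mode == "none":
        return w

    def _z(a):
        mu = a.mean(axis=1, keepdims=True)
        sd = a.std(axis=1, keepdims=True)
        z = (a - mu) / np.maximum(sd, 1e-8)
        # constant channels: the floor would amplify mean round-off
        z[np.broadcast_to(sd < 1e-8, z.shape)] = 0.0
        return z

    return BimodalWindow(eeg_patch=_z(w.eeg_patch), fnirs_patch=_z(w.fnirs_patch),
                         label=w.label, subject_id=w.subject_id,
                         trial_id=w.trial_id, window_start_s=w.window_start_s)


def build_window_set(rec: Recording, spec: WindowSpec = WindowSpec(),
                     normalize: str = "none") -> WindowSet:
    """Full segmentation of one recording into a labeled WindowSet.

    No per-window normalization is applied by default: slow hemodynamic
    class information lives partly in the window mean, which per-channel
    z-scoring would remove.  ``zscore_per_channel`` remains available for
    data whose scale varies across sessions.
    """
    class_names = PARADIGM_CLASSES[rec.paradigm]
    windows = []
    for epoch in segment_trials(rec):
        li = class_names.index(epoch.label)
        for w in slide_windows(epoch, spec, li, rec.subject_id):
            windows.append(normalize_window(w, normalize))
    return WindowSet(windows=windows, class_names=class_names,
                     window_spec=(spec.window_len_s, spec.step_s),
                     normalization_tag=normalize)


def merge_window_sets(sets: list[WindowSet]) -> WindowSet:
    """Pool windows across recordings (classes and spec must agree)."""
    if not sets:
        raise ValueError("no window sets to merge")
    first = sets[0]
    for ws in sets[1:]:
        if ws.class_names != first.class_names or ws.window_spec != first.window_spec:
            raise ValueError("window sets are not compatible")
    windows = [w for ws in sets for w in ws.windows]
    return WindowSet(windows, first.class_names, first.window_spec,
                     first.normalization_tag)


def preprocess_recording(rec: Recording, band: FilterSpec = FilterSpec(),
                         eeg_rate: float = 200.0, fnirs_rate: float = 10.0) -> Recording:
    """Canonical conditioning path: bandpass the EEG, then bring both
    modalities to their target rates.  Steps already recorded as done in the
    provenance metadata are skipped, so generator output and raw recordings
    share one code path."""
    prov = dict(rec.provenance)
    eeg = rec.eeg
    if not prov.get("eeg_filtered", False):
        eeg = bandpass(eeg, band)
        prov["eeg_filtered"] = True
    if eeg.sampling_rate > eeg_rate:
        eeg = resample(eeg, eeg_rate)
    hbo, hbr = rec.fnirs_hbo, rec.fnirs_hbr
    if hbo.sampling_rate > fnirs_rate:
        hbo = resample(hbo, fnirs_rate)
        hbr = resample(hbr, fnirs_rate)
    return Recording(subject_id=rec.subject_id, paradigm=rec.paradigm,
                     eeg=eeg, fnirs_hbo=hbo, fnirs_hbr=hbr,
                     events=rec.events, provenance=prov)
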