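"""Synthetic paired EEG/fNIRS generator for the n-back and word-generation
paradigms.

The generator's contract is statistical, not physiological realism: it
produces recordings whose event schedule matches the paradigm timing
exactly, whose EEG carries a class-dependent band-limited oscillation on a
subset of channels over 1/f (pink) background noise, and whose fNIRS
carries a canonical double-gamma hemodynamic response to each task block
with class-dependent amplitude over slow drift and white noise.  Class
separability is controlled by ``eeg_snr`` / ``fnirs_snr`` and can be split
across modalities (``complementarity='split'``) so that neither modality
alone can separate all classes — the regime where cross-modal fusion
matters.

Everything is deterministic given (seed, subject index): each subject's
generator is ``np.random.default_rng([seed, subject_idx])``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .signal_store import (EventMarker, ModalityStream, Recording,
                           EEG, FNIRS_HBO, FNIRS_HBR, PARADIGM_CLASSES)

# paradigm block timing, seconds
NBACK_INSTRUCTION_S = 2.0
NBACK_TASK_S = 40.0
NBACK_REST_S = 20.0
WG_PROMPT_S = 2.0
WG_TASK_S = 10.0
WG_REST_RANGE_S = (13.0, 15.0)

# class-dependent signal levels (dimensionless multipliers of the SNR knobs)
EEG_LEVELS = {
    ("nback", "none"): {"0back": 0.4, "2back": 1.0, "3back": 1.6},
    # split: the band oscillation separates 0back from {2back, 3back} only
    ("nback", "split"): {"0back": 0.3, "2back": 1.5, "3back": 1.5},
    ("wg", "none"): {"WG": 0.1, "BL": 1.0},    # alpha suppression during WG
    ("wg", "split"): {"WG": 0.1, "BL": 1.0},
}
FNIRS_LEVELS = {
    ("nback", "none"): {"0back": 0.5, "2back": 1.0, "3back": 1.5},
    # split: the hemodynamic amplitude separates 3back from {0back, 2back} only
    ("nback", "split"): {"0back": 1.0, "2back": 1.0, "3back": 2.2},
    ("wg", "none"): {"WG": 1.5, "BL": 0.3},
    ("wg", "split"): {"WG": 1.5, "BL": 0.3},
}
EEG_BANDS_HZ = {"nback": (4.0, 7.0), "wg": (8.0, 12.0)}   # theta / alpha

N_ACTIVE_EEG_CH = 10     # channels carrying the class oscillation
N_ACTIVE_FNIRS_CH = 18   # channels carrying the task response
HBR_SCALE = -0.4         # HbR is anticorrelated with HbO
DRIFT_SD = 0.5           # slow physiological drift, fNIRS nuisance part
TAIL_PAD_S = 2.0         # recording continues past the last event


@dataclass(frozen=True)
class HRFSpec:
    """Double-gamma hemodynamic response: ~6 s peak, ~16 s undershoot at a
    sixth of the peak amplitude, 2 s lag behind the neural envelope."""

    peak_time_s: float = 6.0
    undershoot_time_s: float = 16.0
    undershoot_ratio: float = 1.0 / 6.0
    lag_s: float = 2.0

    def __post_init__(self):
        if not self.peak_time_s < self.undershoot_time_s:
            raise ValueError("peak must precede undershoot")

    def kernel(self, fs: float, length_s: float = 30.0) -> np.ndarray:
        """Impulse response sampled at fs, peak normalized to 1."""
        from scipy.stats import gamma
        t = np.arange(0, length_s, 1.0 / fs)
        h = (gamma.pdf(t, a=self.peak_time_s, scale=1.0)
             - self.undershoot_ratio * gamma.pdf(t, a=self.undershoot_time_s, scale=1.0))
        peak = h.max()
        if peak <= 0:
            raise ValueError("degenerate HRF: non-positive peak")
        return h / peak


@dataclass(frozen=True)
class SynthConfig:
    paradigm: str = "nback"
    n_subjects: int = 1
    trials_per_class: int = 2
    eeg_rate: float = 200.0
    fnirs_rate: float = 10.0
    n_eeg_ch: int = 30
    n_fnirs_ch: int = 36
    eeg_snr: float = 1.0          # band-power of class signal / pink-noise power
    fnirs_snr: float = 1.5        # HRF response amplitude / (drift+noise) sd
    complementarity: str = "none"  # 'none' | 'split'
    channel_corr: float = 0.3     # inter-channel pink-noise correlation
    seed: int = 0
    hrf: HRFSpec = HRFSpec()

    def __post_init__(self):
        if self.paradigm not in PARADIGM_CLASSES:
            raise ValueError(f"unknown paradigm {self.paradigm!r}")
        if self.complementarity not in ("none", "split"):
            raise ValueError(f"unknown complementarity {self.complementarity!r}")
        for fld in ("n_subjects", "trials_per_class", "eeg_rate", "fnirs_rate",
                    "n_eeg_ch", "n_fnirs_ch"):
            if getattr(self, fld) <= 0:
                raise ValueError(f"{fld} must be positive")
        if not 0 <= self.channel_corr < 1:
            raise ValueError("channel_corr must be in [0, 1)")

    @property
    def class_names(self) -> list[str]:
        return PARADIGM_CLASSES[self.paradigm]

    def eeg_levels(self) -> dict[str, float]:
        return EEG_LEVELS[(self.paradigm, self.complementarity)]

    def fnirs_levels(self) -> dict[str, float]:
        return FNIRS_LEVELS[(self.paradigm, self.complementarity)]


def _schedule(cfg: SynthConfig, rng: np.random.Generator):
    """Shuffled trial order and the exact paradigm event list."""
    classes = np.repeat(cfg.class_names, cfg.trials_per_class)
    rng.shuffle(classes)
    events, t = [], 0.0
    if cfg.paradigm == "nback":
        instr, task = NBACK_INSTRUCTION_S, NBACK_TASK_S
    else:
        instr, task = WG_PROMPT_S, WG_TASK_S
    for label in classes:
        events.append(EventMarker(t, instr, label, "instruction"))
        t += instr
        events.append(EventMarker(t, task, label, "task"))
        t += task
        rest = (NBACK_REST_S if cfg.paradigm == "nback"
                else rng.uniform(*WG_REST_RANGE_S))
        events.append(EventMarker(t, rest, label, "rest"))
        t += rest
    return events, t + TAIL_PAD_S


def _pink_noise(rng: np.random.Generator, n_ch: int, n: int) -> np.ndarray:
    """Unit-variance 1/f noise per channel via spectral shaping."""
    n_freq = n // 2 + 1
    f = np.arange(n_freq, dtype=float)
    f[0] = 1.0  # no DC boost
    shape = 1.0 / np.sqrt(f)
    spec = (rng.standard_normal((n_ch, n_freq))
            + 1j * rng.standard_normal((n_ch, n_freq))) * shape
    x = np.fft.irfft(spec, n=n, axis=1)
    x /= x.std(axis=1, keepdims=True)
    return x


def _correlated_pink(rng, n_ch, n, rho):
    common = _pink_noise(rng, 1, n)
    indep = _pink_noise(rng, n_ch, n)
    return np.sqrt(rho) * common + np.sqrt(1.0 - rho) * indep


def _eeg_signal(cfg: SynthConfig, rng, events, total_s) -> np.ndarray:
    n = round(total_s * cfg.eeg_rate)
    x = _correlated_pink(rng, cfg.n_eeg_ch, n, cfg.channel_corr)
    levels = cfg.eeg_levels()
    lo, hi = EEG_BANDS_HZ[cfg.paradigm]
    t_axis = np.arange(n) / cfg.eeg_rate
    for ev in events:
        if ev.phase != "task":
            continue
        # sinusoid of band power eeg_snr * level relative to unit noise power
        amp = np.sqrt(2.0 * cfg.eeg_snr * levels[ev.label])
        i0, i1 = round(ev.onset_s * cfg.eeg_rate), round(ev.offset_s * cfg.eeg_rate)
        freqs = rng.uniform(lo, hi, size=N_ACTIVE_EEG_CH)
        phases = rng.uniform(0, 2 * np.pi, size=N_ACTIVE_EEG_CH)
        seg_t = t_axis[i0:i1]
        osc = amp * np.sin(2 * np.pi * freqs[:, None] * seg_t + phases[:, None])
        x[:N_ACTIVE_EEG_CH, i0:i1] += osc
    return x


def _fnirs_signals(cfg: SynthConfig, rng, events, total_s):
    n = round(total_s * cfg.fnirs_rate)
    levels = cfg.fnirs_levels()
    # lagged neural envelope convolved with the canonical HRF
    env = np.zeros(n)
    for ev in events:
        if ev.phase != "task":
            continue
        i0 = round((ev.onset_s + cfg.hrf.lag_s) * cfg.fnirs_rate)
        i1 = round((ev.offset_s + cfg.hrf.lag_s) * cfg.fnirs_rate)
        env[i0:min(i1, n)] = levels[ev.label]
    response = np.convolve(env, cfg.hrf.kernel(cfg.fnirs_rate))[:n]

    gains = np.zeros(cfg.n_fnirs_ch)
    n_act = min(N_ACTIVE_FNIRS_CH, cfg.n_fnirs_ch)
    gains[:n_act] = rng.uniform(0.7, 1.3, size=n_act)

    t_axis = np.arange(n) / cfg.fnirs_rate
    drift = np.zeros((cfg.n_fnirs_ch, n))
    for _ in range(3):
        f = rng.uniform(0.005, 0.03)
        ph = rng.uniform(0, 2 * np.pi, size=cfg.n_fnirs_ch)
        drift += np.sin(2 * np.pi * f * t_axis + ph[:, None])
    drift *= DRIFT_SD / np.sqrt(3.0 / 2.0)  # three unit sinusoids -> sd DRIFT_SD
    white_sd = np.sqrt(max(1.0 - DRIFT_SD ** 2, 0.0))

    hbo = (cfg.fnirs_snr * gains[:, None] * response
           + drift + white_sd * rng.standard_normal((cfg.n_fnirs_ch, n)))
    hbr = HBR_SCALE * hbo + 0.5 * rng.standard_normal((cfg.n_fnirs_ch, n))
    return hbo, hbr


def generate_subject(cfg: SynthConfig, subject_idx: int = 0) -> Recording:
    """One subject's full synthetic recording, deterministic in
    (cfg.seed, subject_idx)."""
    rng = np.random.default_rng([cfg.seed, subject_idx])
    events, total_s = _schedule(cfg, rng)
    eeg = _eeg_signal(cfg, rng, events, total_s)
    hbo, hbr = _fnirs_signals(cfg, rng, events, total_s)
    sid = f"S{subject_idx + 1:02d}"
    prov = {"generator": "synthgen", "seed": cfg.seed, "subject_idx": subject_idx,
            "config": _config_dict(cfg), "eeg_filtered": True}
    return Recording(
        subject_id=sid, paradigm=cfg.paradigm,
        eeg=ModalityStream(eeg, cfg.eeg_rate,
                           [f"EEG{i + 1:02d}" for i in range(cfg.n_eeg_ch)],
                           EEG, "uV"),
        fnirs_hbo=ModalityStream(hbo, cfg.fnirs_rate,
                                 [f"HBO{i + 1:02d}" for i in range(cfg.n_fnirs_ch)],
                                 FNIRS_HBO, "delta-concentration a.u."),
        fnirs_hbr=ModalityStream(hbr, cfg.fnirs_rate,
                                 [f"HBR{i + 1:02d}" for i in range(cfg.n_fnirs_ch)],
                                 FNIRS_HBR, "delta-concentration a.u."),
        events=events, provenance=prov)


def _config_dict(cfg: SynthConfig) -> dict:
    d = asdict(cfg)
    return d


def generate_dataset(cfg: SynthConfig):
    """All subjects plus a manifest recording the exact configuration and the
    per-subject seed derivation rule."""
    recs = [generate_subject(cfg, i) for i in range(cfg.n_subjects)]
    manifest = {
        "config": _config_dict(cfg),
        "seed_rule": "default_rng([seed, subject_idx])",
        "subject_ids": [r.subject_id for r in recs],
    }
    return recs, manifest
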