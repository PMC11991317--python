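"""Synthetic multimodal emotion-recording generator.

Emulates the structure of DEAP- and DREAMER-style datasets — per-trial
stimulus + resting-baseline segments at 128 Hz, multi-channel EEG plus EOG or
ECG peripherals, and continuous affect ratings — with a controllable
class-separability knob so the whole pipeline is testable without the
controlled-access downloads.

Statistical model, per trial:

* a latent binary class (low/high) is drawn per affect dimension, balanced
  across trials; the class of ``signal_dimension`` (default valence) drives
  the physiological effect;
* EEG channels are sums of band-limited sinusoids (delta 0.5-4, theta 4-8,
  alpha 8-13, beta 13-30 Hz; random frequency and phase per channel/trial)
  plus Gaussian background noise. For the high class the alpha amplitude is
  scaled by (1 + effect_size) on the first ceil(n_eeg/4) channels and the
  beta amplitude on the remaining channels, giving both a localized and a
  distributed class signature;
* EOG channels are a slow drift plus randomly timed 0.3-s biphasic blink
  pulses whose rate differs between classes by (1 + effect_size); ECG
  channels are a periodic 0.08-s triangular QRS train at 60-100 bpm whose
  rate differs by the same factor;
* baseline segments contain noise and baseline-amplitude oscillations only
  (no class effect);
* the continuous rating for each dimension is uniform on (threshold, max]
  for the high class and on [min, threshold] for the low class, so
  binarization at the standard threshold recovers the latent class exactly.

Identical (config, seed) pairs produce bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .layouts import DEAP_EEG_CHANNELS, DREAMER_EEG_CHANNELS

BANDS = {"delta": (0.5, 4.0), "theta": (4.0, 8.0),
         "alpha": (8.0, 13.0), "beta": (13.0, 30.0)}
BAND_AMPLITUDES = {"delta": 1.0, "theta": 0.8, "alpha": 1.0, "beta": 0.6}

BLINK_DURATION_S = 0.3
BLINK_RATE_HZ = 0.3          # low-class blink rate; ~18 blinks/min
BLINK_AMPLITUDE = 3.0
QRS_DURATION_S = 0.08
QRS_AMPLITUDE = 2.0
HEART_RATE_BPM = (60.0, 100.0)

_THRESHOLDS = {(1, 9): 5.0, (1, 5): 3.0}


@dataclass(frozen=True)
class SyntheticConfig:
    n_subjects: int = 1
    n_trials: int = 40
    trial_s: float | tuple = 60.0          # scalar, or (lo, hi) range per trial
    baseline_s: float = 3.0
    fs: float = 128.0
    n_eeg: int = 32
    n_periph: int = 2
    periph_kind: str = "EOG"               # "EOG" or "ECG"
    rating_scale: tuple = (1, 9)
    effect_size: float = 1.0
    noise_sd: float = 1.0
    dimensions: tuple = ("valence", "arousal", "dominance", "liking")
    signal_dimension: str = "valence"
    seed: int = 0

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        lo = self.trial_s[0] if isinstance(self.trial_s, tuple) else self.trial_s
        if lo < 1:
            raise ValueError("trial_s must be >= 1 s")
        if self.baseline_s < 0 or self.n_eeg < 1 or self.effect_size < 0:
            raise ValueError("invalid config: need baseline_s >= 0, n_eeg >= 1, "
                             "effect_size >= 0")
        if self.periph_kind not in ("EOG", "ECG"):
            raise ValueError(f"periph_kind must be 'EOG' or 'ECG', got "
                             f"{self.periph_kind!r}")
        if tuple(self.rating_scale) not in _THRESHOLDS:
            raise ValueError("rating_scale must be (1, 9) or (1, 5)")
        if self.signal_dimension not in self.dimensions:
            raise ValueError(f"signal_dimension {self.signal_dimension!r} not in "
                             f"dimensions {self.dimensions}")

    @property
    def threshold(self) -> float:
        """Standard binarization threshold for the declared rating scale."""
        return _THRESHOLDS[tuple(self.rating_scale)]


@dataclass
class TrialRecording:
    """One trial: stimulus signal, resting baseline, and continuous ratings."""

    subject_id: str
    trial_id: str
    signal: np.ndarray           # [n_channels, n_samples]
    baseline: np.ndarray         # [n_channels, baseline_samples]
    fs: float
    channel_names: list
    channel_roles: list          # per channel: "EEG" or "peripheral"
    ratings: dict                # affect dimension -> score

    @property
    def eeg_indices(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.channel_roles) == "EEG")

    @property
    def periph_indices(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.channel_roles) == "peripheral")


def preset_deap_like(**overrides) -> SyntheticConfig:
    """32 EEG + 2 EOG channels, 40 trials x 60 s, 3-s baseline, ratings 1-9."""
    base = dict(n_trials=40, trial_s=60.0, baseline_s=3.0, fs=128.0,
                n_eeg=32, n_periph=2, periph_kind="EOG", rating_scale=(1, 9),
                dimensions=("valence", "arousal", "dominance", "liking"))
    base.update(overrides)
    return SyntheticConfig(**base)


def preset_dreamer_like(**overrides) -> SyntheticConfig:
    """14 EEG + 2 ECG channels, 18 trials of variable length, ratings 1-5."""
    base = dict(n_trials=18, trial_s=(60.0, 240.0), baseline_s=3.0, fs=128.0,
                n_eeg=14, n_periph=2, periph_kind="ECG", rating_scale=(1, 5),
                dimensions=("valence", "arousal", "dominance"))
    base.update(overrides)
    return SyntheticConfig(**base)


def preset_reduced_study(effect_size: float = 1.0, seed: int = 0,
                         **overrides) -> SyntheticConfig:
    """Reduced study conditions for parameter-recovery experiments.

    One subject, 20 trials x 20 s at 128 Hz -> 400 one-second windows,
    ~200 per class, with 14 EEG + 2 EOG channels. Small enough for the
    reduced model to train in minutes, large enough for stable held-out
    accuracy estimates.
    """
    base = dict(n_subjects=1, n_trials=20, trial_s=20.0, baseline_s=3.0,
                fs=128.0, n_eeg=14, n_periph=2, periph_kind="EOG",
                rating_scale=(1, 9), dimensions=("valence", "arousal"),
                effect_size=effect_size, seed=seed)
    base.update(overrides)
    return SyntheticConfig(**base)


def default_channel_names(cfg: SyntheticConfig) -> tuple[list, list]:
    if cfg.n_eeg == 32:
        eeg = list(DEAP_EEG_CHANNELS)
    elif cfg.n_eeg == 14:
        eeg = list(DREAMER_EEG_CHANNELS)
    else:
        eeg = [f"EEG{i + 1}" for i in range(cfg.n_eeg)]
    periph = [f"{cfg.periph_kind}{i + 1}" for i in range(cfg.n_periph)]
    return eeg, periph


# ------------------------------------------------------------------ internals
def _balanced_classes(rng: np.random.Generator, n: int) -> np.ndarray:
    cls = np.zeros(n, dtype=int)
    cls[: n // 2] = 1
    if n % 2:
        cls[n // 2] = rng.integers(0, 2)
    return rng.permutation(cls)

def _eeg_block(rng, cfg, n_ch, t, boost=None):
    """Sum of band-limited sinusoids + Gaussian noise; boost: [n_ch, n_bands] or None."""
    out = rng.normal(0.0, cfg.noise_sd, size=(n_ch, t.size))
    names = list(BANDS)
    freqs = np.empty((n_ch, len(names)))
    for j, b in enumerate(names):
        lo, hi = BANDS[b]
        freqs[:, j] = rng.uniform(lo, min(hi, cfg.fs / 2), size=n_ch)
    phases = rng.uniform(0, 2 * np.pi, size=(n_ch, len(names)))
    amps = np.array([BAND_AMPLITUDES[b] for b in names])[None, :].repeat(n_ch, 0)
    if boost is not None:
        amps = amps * boost
    out += (amps[:, :, None]
            * np.sin(2 * np.pi * freqs[:, :, None] * t + phases[:, :, None])).sum(axis=1)
    return out


def _blink_template(fs: float) -> np.ndarray:
    n = max(int(round(BLINK_DURATION_S * fs)), 2)
    t = np.linspace(0, 1, n)
    # biphasic: one full sine period under a Hann window
    return BLINK_AMPLITUDE * np.sin(2 * np.pi * t) * np.hanning(n)


def _qrs_template(fs: float) -> np.ndarray:
    n = max(int(round(QRS_DURATION_S * fs)), 3)
    half = n // 2
    up = np.linspace(0, 1, half, endpoint=False)
    down = np.linspace(1, 0, n - half)
    return QRS_AMPLITUDE * np.concatenate([up, down])


def _add_pulses(sig: np.ndarray, template: np.ndarray, starts: np.ndarray):
    n = sig.size
    for s in starts:
        s = int(s)
        if s >= n:
            continue
        seg = template[: n - s]
        sig[s:s + seg.size] += seg


def _eog_block(rng, cfg, n_ch, t, rate_hz):
    out = rng.normal(0.0, 0.3 * cfg.noise_sd, size=(n_ch, t.size))
    template = _blink_template(cfg.fs)
    dur = t.size / cfg.fs
    for c in range(n_ch):
        f = rng.uniform(0.05, 0.3)
        out[c] += 0.5 * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        n_blinks = rng.poisson(rate_hz * dur)
        starts = rng.uniform(0, max(dur - BLINK_DURATION_S, 0), size=n_blinks) * cfg.fs
        _add_pulses(out[c], template, np.sort(starts))
    return out


def _ecg_block(rng, cfg, n_ch, t, rate_factor):
    out = rng.normal(0.0, 0.1 * cfg.noise_sd, size=(n_ch, t.size))
    template = _qrs_template(cfg.fs)
    dur = t.size / cfg.fs
    bpm = rng.uniform(*HEART_RATE_BPM) * rate_factor
    period = 60.0 / bpm
    for c in range(n_ch):
        jitter = rng.normal(0, 0.01, size=int(dur / period) + 2)
        beats = (np.arange(jitter.size) * period + rng.uniform(0, period) + jitter)
        beats = beats[beats < dur]
        out[c] += 0.2 * np.sin(2 * np.pi * 0.25 * t + rng.uniform(0, 2 * np.pi))
        _add_pulses(out[c], template, beats * cfg.fs)
    return out


# ----------------------------------------------------------------- generation
def generate_dataset(cfg: SyntheticConfig) -> list[TrialRecording]:
    """Generate all trials for all subjects; deterministic in (cfg, cfg.seed)."""
    rng = np.random.default_rng(cfg.seed)
    eeg_names, periph_names = default_channel_names(cfg)
    names = eeg_names + periph_names
    roles = ["EEG"] * cfg.n_eeg + ["peripheral"] * cfg.n_periph
    n_boost = -(-cfg.n_eeg // 4)              # ceil(n_eeg / 4)
    band_idx = {b: j for j, b in enumerate(BANDS)}
    lo, hi = cfg.rating_scale
    thr = cfg.threshold

    trials = []
    for s in range(cfg.n_subjects):
        classes = {d: _balanced_classes(rng, cfg.n_trials) for d in cfg.dimensions}
        for j in range(cfg.n_trials):
            if isinstance(cfg.trial_s, tuple):
                trial_s = rng.uniform(*cfg.trial_s)
            else:
                trial_s = float(cfg.trial_s)
            n_samp = int(round(trial_s * cfg.fs))
            n_base = int(round(cfg.baseline_s * cfg.fs))
            t_stim = np.arange(n_samp) / cfg.fs
            t_base = np.arange(n_base) / cfg.fs
            cls = int(classes[cfg.signal_dimension][j])

            # class-conditional EEG band boost
            boost = np.ones((cfg.n_eeg, len(BANDS)))
            if cls == 1:
                gain = 1.0 + cfg.effect_size
                boost[:n_boost, band_idx["alpha"]] = gain
                boost[n_boost:, band_idx["beta"]] = gain
            eeg_stim = _eeg_block(rng, cfg, cfg.n_eeg, t_stim, boost)
            eeg_base = _eeg_block(rng, cfg, cfg.n_eeg, t_base, None)

            rate_factor = (1.0 + cfg.effect_size) if cls == 1 else 1.0
            if cfg.n_periph > 0 and cfg.periph_kind == "EOG":
                per_stim = _eog_block(rng, cfg, cfg.n_periph, t_stim,
                                      BLINK_RATE_HZ * rate_factor)
                per_base = _eog_block(rng, cfg, cfg.n_periph, t_base, BLINK_RATE_HZ)
            elif cfg.n_periph > 0:
                per_stim = _ecg_block(rng, cfg, cfg.n_periph, t_stim, rate_factor)
                per_base = _ecg_block(rng, cfg, cfg.n_periph, t_base, 1.0)
            else:
                per_stim = np.zeros((0, n_samp))
                per_base = np.zeros((0, n_base))

            ratings = {}
            for d in cfg.dimensions:
                c = int(classes[d][j])
                if c == 1:
                    # open at the threshold so strict binarization is exact
                    r = thr + (hi - thr) * rng.uniform(np.finfo(float).eps, 1.0)
                else:
                    r = lo + (thr - lo) * rng.uniform(0.0, 1.0)
                ratings[d] = float(r)

            trials.append(TrialRecording(
                subject_id=f"subject_{s}", trial_id=f"trial_{j}",
                signal=np.vstack([eeg_stim, per_stim]),
                baseline=np.vstack([eeg_base, per_base]),
                fs=cfg.fs, channel_names=list(names), channel_roles=list(roles),
                ratings=ratings))
    return trials


# -------------------------------------------------------------- serialization
def save_hdf5(trials: Sequence[TrialRecording], path) -> None:
    """Layout: /<subject>/<trial>/{signal, baseline, rating_values} + attrs."""
    import h5py

    with h5py.File(path, "w") as f:
        for tr in trials:
            g = f.require_group(tr.subject_id).create_group(tr.trial_id)
            g.create_dataset("signal", data=tr.signal)
            g.create_dataset("baseline", data=tr.baseline)
            dims = sorted(tr.ratings)
            g.create_dataset("rating_values", data=[tr.ratings[d] for d in dims])
            g.attrs["rating_dimensions"] = dims
            g.attrs["fs"] = tr.fs
            g.attrs["channel_names"] = tr.channel_names
            g.attrs["channel_roles"] = tr.channel_roles


def load_hdf5(path) -> list[TrialRecording]:
    import h5py

    trials = []
    with h5py.File(path, "r") as f:
        for sid in sorted(f, key=_natural_key):
            for tid in sorted(f[sid], key=_natural_key):
                g = f[sid][tid]
                dims = [d for d in g.attrs["rating_dimensions"]]
                vals = np.asarray(g["rating_values"])
                trials.append(TrialRecording(
                    subject_id=sid, trial_id=tid,
                    signal=np.asarray(g["signal"]),
                    baseline=np.asarray(g["baseline"]),
                    fs=float(g.attrs["fs"]),
                    channel_names=[str(c) for c in g.attrs["channel_names"]],
                    channel_roles=[str(r) for r in g.attrs["channel_roles"]],
                    ratings={d: float(v) for d, v in zip(dims, vals)}))
    return trials


def save_npz(trials: Sequence[TrialRecording], path) -> None:
    arrays = {}
    for i, tr in enumerate(trials):
        arrays[f"{i}/signal"] = tr.signal
        arrays[f"{i}/baseline"] = tr.baseline
        dims = sorted(tr.ratings)
        arrays[f"{i}/rating_values"] = np.array([tr.ratings[d] for d in dims])
        arrays[f"{i}/meta"] = np.array([
            tr.subject_id, tr.trial_id, str(tr.fs),
            ",".join(tr.channel_names), ",".join(tr.channel_roles),
            ",".join(dims)])
    np.savez(path, **arrays)


def load_npz(path) -> list[TrialRecording]:
    trials = []
    with np.load(path, allow_pickle=False) as data:
        n = len([k for k in data.files if k.endswith("/meta")])
        for i in range(n):
            sid, tid, fs, names, roles, dims = (str(x) for x in data[f"{i}/meta"])
            dims = dims.split(",")
            vals = data[f"{i}/rating_values"]
            trials.append(TrialRecording(
                subject_id=sid, trial_id=tid,
                signal=data[f"{i}/signal"], baseline=data[f"{i}/baseline"],
                fs=float(fs), channel_names=names.split(","),
                channel_roles=roles.split(","),
                ratings={d: float(v) for d, v in zip(dims, vals)}))
    return trials


def _natural_key(s: str):
    head, _, tail = s.rpartition("_")
    return (head, int(tail)) if tail.isdigit() else (s, -1)
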