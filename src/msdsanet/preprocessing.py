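"""Raw recordings -> model-ready windows.

Stages: per-trial baseline correction, 1-s sliding-window segmentation,
strict-threshold label binarization, mapping of EEG channels onto the 2-D
electrode grid, and SNR-controlled Gaussian noise injection for robustness
experiments. Coordinates are 0-based and windows are half-open.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .layouts import DEAP_PLACEMENT, DREAMER_PLACEMENT
from .synthetic import TrialRecording


@dataclass
class ElectrodeLayout:
    """Injective channel-name -> (row, col) placement on a grid_h x grid_w plane."""

    grid_h: int
    grid_w: int
    placement: dict

    def __post_init__(self):
        cells = list(self.placement.values())
        for name, (r, c) in self.placement.items():
            if not (0 <= r < self.grid_h and 0 <= c < self.grid_w):
                raise ValueError(f"channel {name!r} placed out of bounds at {(r, c)}")
        if len(set(map(tuple, cells))) != len(cells):
            raise ValueError("placement is not injective: two electrodes share a cell")

    @classmethod
    def deap_10_20(cls) -> "ElectrodeLayout":
        return cls(9, 9, dict(DEAP_PLACEMENT))

    @classmethod
    def dreamer_10_20(cls) -> "ElectrodeLayout":
        return cls(9, 9, dict(DREAMER_PLACEMENT))

    @classmethod
    def generic(cls, channel_names, grid_h: int = 9, grid_w: int = 9):
        """Row-major fallback placement for channel sets without 10-20 names."""
        if len(channel_names) > grid_h * grid_w:
            raise ValueError("more channels than grid cells")
        return cls(grid_h, grid_w,
                   {ch: (i // grid_w, i % grid_w) for i, ch in enumerate(channel_names)})

    @classmethod
    def for_channels(cls, channel_names) -> "ElectrodeLayout":
        """Pick the standard 10-20 layout covering these names, else row-major."""
        names = set(channel_names)
        for layout in (cls.deap_10_20(), cls.dreamer_10_20()):
            if names <= set(layout.placement):
                return layout
        return cls.generic(list(channel_names))

    @classmethod
    def from_json(cls, path) -> "ElectrodeLayout":
        with open(path) as fh:
            d = json.load(fh)
        return cls(int(d["grid_h"]), int(d["grid_w"]),
                   {k: tuple(v) for k, v in d["placement"].items()})

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"grid_h": self.grid_h, "grid_w": self.grid_w,
                       "placement": {k: list(v) for k, v in self.placement.items()}},
                      fh, indent=1)


@dataclass
class Sample:
    """One 1-s window of one trial, in the three forms the model consumes."""

    eeg: np.ndarray                  # [C, T]
    grid: np.ndarray | None          # [H, W, T]
    periph: np.ndarray               # [P, T]
    label: int | None                # 0 = low, 1 = high
    affect_dimension: str | None
    subject_id: str = ""
    trial_id: str = ""
    window_index: int = 0
    rating: float | None = None


# ------------------------------------------------------------------ operations
def subtract_baseline(trial: TrialRecording, strict: bool = False) -> TrialRecording:
    """Subtract, per channel, the mean of the baseline's 1-s segment means.

    The baseline is cut into as many full 1-s segments as it contains; the
    per-channel mean of the segment means is removed from every stimulus
    sample. A missing baseline leaves the trial unchanged (an error instead
    if strict=True).
    """
    fs = int(round(trial.fs))
    n_seg = trial.baseline.shape[1] // fs
    if n_seg < 1:
        if strict:
            raise ValueError(
                f"baseline has {trial.baseline.shape[1]} samples, shorter than one "
                f"1-s segment at fs={trial.fs}")
        if trial.baseline.shape[1] > 0:
            warnings.warn("baseline shorter than 1 s; skipping baseline correction")
        return TrialRecording(
            trial.subject_id, trial.trial_id, trial.signal.copy(),
            trial.baseline.copy(), trial.fs, list(trial.channel_names),
            list(trial.channel_roles), dict(trial.ratings))
    segs = trial.baseline[:, : n_seg * fs].reshape(trial.baseline.shape[0], n_seg, fs)
    ref = segs.mean(axis=2).mean(axis=1)      # mean of 1-s segment means
    return TrialRecording(
        trial.subject_id, trial.trial_id, trial.signal - ref[:, None],
        trial.baseline.copy(), trial.fs, list(trial.channel_names),
        list(trial.channel_roles), dict(trial.ratings))


def window_starts(n_samples: int, fs: float, window_s: float = 1.0,
                  stride_s: float = 1.0) -> list[int]:
    """0-based start indices of half-open windows [k*stride*fs, ... + window*fs)."""
    if window_s <= 0 or stride_s <= 0:
        raise ValueError("window_s and stride_s must be positive")
    wlen = int(round(window_s * fs))
    step = int(round(stride_s * fs))
    if n_samples < wlen:
        return []
    return list(range(0, n_samples - wlen + 1, step))


def segment_trial(trial: TrialRecording, window_s: float = 1.0,
                  stride_s: float = 1.0) -> list[Sample]:
    """Cut the stimulus signal into unlabeled, ungridded windows."""
    eeg_idx = trial.eeg_indices
    per_idx = trial.periph_indices
    wlen = int(round(window_s * trial.fs))
    out = []
    for k, s in enumerate(window_starts(trial.signal.shape[1], trial.fs,
                                        window_s, stride_s)):
        sl = trial.signal[:, s:s + wlen]
        out.append(Sample(eeg=sl[eeg_idx], grid=None, periph=sl[per_idx],
                          label=None, affect_dimension=None,
                          subject_id=trial.subject_id, trial_id=trial.trial_id,
                          window_index=k))
    return out


def binarize_label(score: float, threshold: float, scale: tuple | None = None) -> int:
    """1 iff score > threshold (strict), else 0."""
    if scale is not None and not (scale[0] <= score <= scale[1]):
        raise ValueError(f"score {score} outside declared scale {scale}")
    return int(score > threshold)


def map_to_grid(eeg: np.ndarray, layout: ElectrodeLayout,
                channel_names) -> np.ndarray:
    """[C, T] channel matrix -> [H, W, T] spatial tensor; unplaced cells are zero."""
    eeg = np.asarray(eeg)
    if eeg.shape[0] != len(channel_names):
        raise ValueError(f"{eeg.shape[0]} rows but {len(channel_names)} channel names")
    grid = np.zeros((layout.grid_h, layout.grid_w, eeg.shape[1]))
    for i, name in enumerate(channel_names):
        if name not in layout.placement:
            raise KeyError(f"channel {name!r} has no cell in the electrode layout")
        r, c = layout.placement[name]
        grid[r, c, :] = eeg[i]
    return grid


def add_gaussian_noise(signal: np.ndarray, snr_db: float,
                       seed=None) -> np.ndarray:
    """Additive zero-mean Gaussian noise at a target per-channel SNR.

    Noise variance per channel is P / 10^(snr_db/10) where P is that
    channel's mean square. snr_db = +inf is the no-noise mode (returns a
    copy). Rows of an [C, T] matrix are treated as channels; a 1-D input is
    one channel.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size == 0:
        raise ValueError("empty signal")
    if np.isnan(snr_db) or snr_db == -np.inf:
        raise ValueError(f"snr_db must be finite or +inf, got {snr_db}")
    if snr_db == np.inf:
        return signal.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    power = np.mean(signal ** 2, axis=-1, keepdims=True)
    sigma = np.sqrt(power / 10.0 ** (snr_db / 10.0))
    return signal + rng.normal(size=signal.shape) * sigma


def inject_noise(trial: TrialRecording, snr_db: float, seed=None,
                 include_peripheral: bool = False) -> TrialRecording:
    """Noise-injected copy of a trial; EEG channels only unless told otherwise."""
    sig = trial.signal.copy()
    idx = (np.arange(sig.shape[0]) if include_peripheral else trial.eeg_indices)
    sig[idx] = add_gaussian_noise(sig[idx], snr_db, seed=seed)
    return TrialRecording(trial.subject_id, trial.trial_id, sig,
                          trial.baseline.copy(), trial.fs,
                          list(trial.channel_names), list(trial.channel_roles),
                          dict(trial.ratings))


# -------------------------------------------------------------------- pipeline
def preprocess_trials(trials, dimension: str, threshold: float,
                      layout: ElectrodeLayout | None = None,
                      window_s: float = 1.0, stride_s: float = 1.0,
                      scale: tuple | None = None,
                      baseline_correction: bool = True) -> list[Sample]:
    """Full pipeline: baseline correction -> segmentation -> label + grid.

    Every window inherits the binarized rating of its parent trial on the
    requested affect dimension.
    """
    samples = []
    for trial in trials:
        if layout is None:
            eeg_names = [n for n, r in zip(trial.channel_names, trial.channel_roles)
                         if r == "EEG"]
            layout = ElectrodeLayout.for_channels(eeg_names)
        if dimension not in trial.ratings:
            raise KeyError(f"trial {trial.trial_id} has no rating for {dimension!r}")
        corrected = subtract_baseline(trial) if baseline_correction else trial
        label = binarize_label(trial.ratings[dimension], threshold, scale)
        eeg_names = [n for n, r in zip(trial.channel_names, trial.channel_roles)
                     if r == "EEG"]
        for s in segment_trial(corrected, window_s, stride_s):
            s.grid = map_to_grid(s.eeg, layout, eeg_names)
            s.label = label
            s.affect_dimension = dimension
            s.rating = float(trial.ratings[dimension])
            samples.append(s)
    return samples


def stack_samples(samples) -> dict:
    """Stack a list of Samples into batched arrays for the network.

    The "trial" entry keeps each window's parent-trial identity so split
    construction can group windows by trial.
    """
    return {
        "eeg": np.stack([s.eeg for s in samples]),
        "grid": np.stack([s.grid for s in samples]),
        "periph": np.stack([s.periph for s in samples]),
        "label": np.array([s.label for s in samples], dtype=int),
        "trial": np.array([f"{s.subject_id}/{s.trial_id}" for s in samples]),
    }


# ------------------------------------------------------------------- container
def save_samples(samples, path) -> None:
    """Windowed-sample container: /samples/{eeg, grid, periph, label, meta}."""
    import h5py

    arrs = stack_samples(samples)
    with h5py.File(path, "w") as f:
        g = f.create_group("samples")
        for key in ("eeg", "grid", "periph"):
            g.create_dataset(key, data=arrs[key])
        g.create_dataset("label", data=arrs["label"])
        meta = np.array([[s.subject_id, s.trial_id, str(s.window_index),
                          s.affect_dimension or ""] for s in samples], dtype="S64")
        g.create_dataset("meta", data=meta)


def load_samples(path) -> list[Sample]:
    import h5py

    out = []
    with h5py.File(path, "r") as f:
        g = f["samples"]
        eeg, grid, periph = (np.asarray(g[k]) for k in ("eeg", "grid", "periph"))
        labels = np.asarray(g["label"])
        meta = np.asarray(g["meta"]).astype(str)
        for i in range(eeg.shape[0]):
            sid, tid, widx, dim = meta[i]
            out.append(Sample(eeg=eeg[i], grid=grid[i], periph=periph[i],
                              label=int(labels[i]), affect_dimension=dim or None,
                              subject_id=sid, trial_id=tid, window_index=int(widx)))
    return out
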