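"""Optional adapters for the public DEAP and DREAMER release formats.

These functions convert the released per-subject files into
:class:`~msdsanet.synthetic.TrialRecording` lists consumable by
``preprocess_trials``. They require the controlled-access downloads and are
therefore not exercised by the test suite; the synthetic container formats
are the supported interchange.
"""

from __future__ import annotations

import numpy as np

from .layouts import DEAP_EEG_CHANNELS, DREAMER_EEG_CHANNELS
from .synthetic import TrialRecording

DEAP_FS = 128.0
DEAP_BASELINE_S = 3.0
# released label-column order
DEAP_DIMENSIONS = ("valence", "arousal", "dominance", "liking")
DREAMER_DIMENSIONS = ("valence", "arousal", "dominance")


def load_deap_subject(path, subject_id: str = "",
                      n_periph: int = 2) -> list[TrialRecording]:
    """Load one preprocessed DEAP per-subject file (s01.dat ... s32.dat).

    The released pickle holds ``data`` [40 trials x 40 channels x 8064
    samples] — channels 0–31 are EEG in the standard DEAP order, 32–33 the
    horizontal/vertical EOG — and ``labels`` [40 x 4] continuous ratings.
    Each trial's first 3 s are the pre-stimulus baseline; the remaining 60 s
    are the stimulus signal. Only the first ``n_periph`` peripheral channels
    (the EOG pair by default) are kept.
    """
    import pickle

    with open(path, "rb") as fh:
        blob = pickle.load(fh, encoding="latin1")
    data = np.asarray(blob["data"], dtype=float)
    labels = np.asarray(blob["labels"], dtype=float)
    if data.shape[1] < 32 + n_periph:
        raise ValueError(f"expected >= {32 + n_periph} channels, got {data.shape[1]}")
    n_base = int(DEAP_BASELINE_S * DEAP_FS)
    names = list(DEAP_EEG_CHANNELS) + [f"EOG{i + 1}" for i in range(n_periph)]
    roles = ["EEG"] * 32 + ["peripheral"] * n_periph
    keep = list(range(32)) + list(range(32, 32 + n_periph))
    trials = []
    for j in range(data.shape[0]):
        sig = data[j, keep]
        trials.append(TrialRecording(
            subject_id=subject_id or "deap_subject", trial_id=f"trial_{j}",
            signal=sig[:, n_base:], baseline=sig[:, :n_base], fs=DEAP_FS,
            channel_names=list(names), channel_roles=list(roles),
            ratings=dict(zip(DEAP_DIMENSIONS, labels[j]))))
    return trials


def load_dreamer_mat(path, subject_index: int = 0) -> list[TrialRecording]:
    """Load one participant from the released DREAMER.mat bundle.

    EEG (14 channels at 128 Hz) and ECG (2 channels at 256 Hz in the
    release; kept at their native rate is not supported here — the ECG is
    decimated by 2 to align with the EEG clock). Per trial, the last 3 s
    of the baseline recording become the baseline segment.
    """
    from scipy.io import loadmat

    mat = loadmat(path, squeeze_me=True, struct_as_record=False)
    subj = mat["DREAMER"].Data[subject_index]
    scores = {d: np.atleast_1d(getattr(subj, f"Score{d.capitalize()}"))
              for d in DREAMER_DIMENSIONS}
    names = list(DREAMER_EEG_CHANNELS) + ["ECG1", "ECG2"]
    roles = ["EEG"] * 14 + ["peripheral"] * 2
    n_trials = len(np.atleast_1d(subj.EEG.stimuli))
    n_base = int(3 * 128)
    trials = []
    for j in range(n_trials):
        eeg_stim = np.asarray(subj.EEG.stimuli[j], dtype=float).T
        eeg_base = np.asarray(subj.EEG.baseline[j], dtype=float).T
        ecg_stim = np.asarray(subj.ECG.stimuli[j], dtype=float).T[:, ::2]
        ecg_base = np.asarray(subj.ECG.baseline[j], dtype=float).T[:, ::2]
        n_stim = min(eeg_stim.shape[1], ecg_stim.shape[1])
        nb = min(eeg_base.shape[1], ecg_base.shape[1], n_base)
        trials.append(TrialRecording(
            subject_id=f"dreamer_subject_{subject_index}", trial_id=f"trial_{j}",
            signal=np.vstack([eeg_stim[:, :n_stim], ecg_stim[:, :n_stim]]),
            baseline=np.vstack([eeg_base[:, -nb:], ecg_base[:, -nb:]]),
            fs=128.0, channel_names=list(names), channel_roles=list(roles),
            ratings={d: float(scores[d][j]) for d in DREAMER_DIMENSIONS}))
    return trials
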