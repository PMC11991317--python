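import numpy as np
import pytest

from msdsanet.evaluation import TrainingConfig
from msdsanet.model import ModelConfig
from msdsanet.preprocessing import preprocess_trials, stack_samples
from msdsanet.synthetic import SyntheticConfig, generate_dataset, \
    preset_reduced_study


@pytest.fixture(scope="session")
def study_trials():
    """Separable synthetic set (effect size 1), reduced study conditions."""
    return generate_dataset(preset_reduced_study(effect_size=1.0, seed=0))


@pytest.fixture(scope="session")
def study_arrays(study_trials):
    return stack_samples(preprocess_trials(study_trials, "valence", 5.0))


@pytest.fixture(scope="session")
def null_arrays():
    """Null set (effect size 0): classes carry no signal."""
    trials = generate_dataset(preset_reduced_study(effect_size=0.0, seed=0))
    return stack_samples(preprocess_trials(trials, "valence", 5.0))


@pytest.fixture(scope="session")
def tiny_trials():
    """8 trials x 5 s, 4 EEG + 1 EOG: 40 windows for fast training tests."""
    cfg = SyntheticConfig(n_subjects=1, n_trials=8, trial_s=5.0, baseline_s=3.0,
                          fs=128.0, n_eeg=4, n_periph=1, periph_kind="EOG",
                          rating_scale=(1, 9), dimensions=("valence",),
                          effect_size=1.5, seed=11)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def tiny_arrays(tiny_trials):
    return stack_samples(preprocess_trials(tiny_trials, "valence", 5.0))


@pytest.fixture()
def tiny_model_cfg():
    """Minimal widths that still exercise every block."""
    return ModelConfig(n_eeg=4, n_periph=1, window_samples=128,
                       f0=4, f_ms=2, temporal_filters=2, cross_channel_filters=2,
                       eeg_conv_filters=(2, 2), dsanet_filters=(2, 2),
                       lstm_long=8, lstm_short=4, f_e=2, cbam_reduction=2,
                       dropout=0.25, seed=5)


@pytest.fixture()
def tiny_hyper():
    return TrainingConfig.reduced(epochs=1, batch_size=16, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
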