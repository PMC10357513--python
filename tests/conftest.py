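import numpy as np
import pytest

from haptic_eeg.pipeline import extract_subject_features
from haptic_eeg.preprocess import preprocess_recording
from haptic_eeg.simulate import scaled_config, generate_experiment


@pytest.fixture(scope="session")
def experiment():
    """Small two-subject synthetic experiment shared across test modules."""
    cfg = scaled_config(n_subjects=2, clip_duration_s=16.0, fs=200.0, seed=7)
    recordings, annotations, manifest = generate_experiment(cfg)
    return cfg, recordings, annotations, manifest


@pytest.fixture(scope="session")
def segments0(experiment):
    """Preprocessed condition segments for subject 0 (ICA off for speed)."""
    cfg, recordings, annotations, _ = experiment
    anns = [a for a in annotations if a.subject == 0]
    return preprocess_recording(recordings[0], anns, fs_out=200.0, run_ica=False)


@pytest.fixture(scope="session")
def feats0(segments0):
    """Feature tensors for subject 0, keyed by (pattern, condition)."""
    return extract_subject_features(segments0)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
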