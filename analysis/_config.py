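"""Shared run configuration for the numbered analysis drivers.

One seeded run directory under scratch/ holds the heavy intermediates
(recordings, segments); each driver executes one pipeline stage against it
and copies its human-readable tables into results/.
"""

from pathlib import Path

from haptic_eeg.pipeline import RunConfig
from haptic_eeg.simulate import scaled_config

REPO = Path(__file__).resolve().parent.parent
RUN_DIR = REPO / "scratch" / "analysis_run"
RESULTS = REPO / "results"


def run_config() -> RunConfig:
    """Four synthetic subjects, 20-s clips at 500 Hz (resampled to 200 Hz)."""
    return RunConfig(
        generator=scaled_config(n_subjects=4, clip_duration_s=20.0,
                                rest_s=1.0, fs=500.0, seed=0),
        out_dir=RUN_DIR,
        fs_out=200.0,
        run_ica=True,
        seed=2026,
    )
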