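#!/usr/bin/env python
"""Preprocess the synthetic recordings into condition segments.

Chain per subject: resample 500 -> 200 Hz, 50 Hz notch, 1-50 Hz bandpass,
seeded ICA rejection of frontal (EOG-like) components, common-average
re-reference with FCz recovery, then a split of every clip into its
non-haptic first half and haptic second half, each with the 5-s pre-clip
baseline attached.
"""

from _config import RUN_DIR, run_config
from haptic_eeg.pipeline import load_segments, stage_preprocess

cfg = run_config()
seg_dir = stage_preprocess(cfg, RUN_DIR)

files = sorted(seg_dir.glob("subject*.npz"))
segs = load_segments(files[0])
print(f"preprocessed {len(files)} subjects -> {seg_dir}")
print(f"subject 0: {len(segs)} segments "
      f"({len(segs) // 2} sessions x 2 conditions), "
      f"{segs[0].samples.shape[0]} channels (incl. recovered FCz) at "
      f"{segs[0].fs:.0f} Hz, baseline {segs[0].baseline.shape[1]} samples")
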