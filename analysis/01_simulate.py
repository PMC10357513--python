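#!/usr/bin/env python
"""Generate the synthetic haptic-EEG experiment.

Simulates four subjects, each with 16 annotated sessions (5-s cue + clip
with haptic stimulation in the second half), four emotion classes with
lateralized beta/gamma signatures in temporal/prefrontal channels, and an
8/8 split between the fixed and the adaptive haptic pattern.  Recordings go
to the run directory as BrainVision triplets; the session manifest is copied
into results/.
"""

import shutil

from _config import RESULTS, RUN_DIR, run_config
from haptic_eeg.io import read_manifest
from haptic_eeg.pipeline import stage_simulate

cfg = run_config()
RUN_DIR.mkdir(parents=True, exist_ok=True)
rec_dir = stage_simulate(cfg, RUN_DIR)

manifest = read_manifest(rec_dir / "manifest.csv")
RESULTS.mkdir(exist_ok=True)
shutil.copy(rec_dir / "manifest.csv", RESULTS / "manifest.csv")

print(f"wrote {len(list(rec_dir.glob('*.vhdr')))} recordings to {rec_dir}")
print(f"{manifest.subject.nunique()} subjects x "
      f"{manifest.groupby('subject').size().iloc[0]} sessions; "
      f"pattern split per subject: "
      f"{manifest.groupby(['subject', 'pattern']).size().unstack().iloc[0].to_dict()}")
print(f"manifest copied to {RESULTS / 'manifest.csv'}")
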