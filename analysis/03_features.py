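#!/usr/bin/env python
"""Extract the four feature families and inspect dataset shapes.

Per 1-s non-overlapping window: five-band STFT energy (PSD), differential
entropy of the band-filtered signal (DE), and the DE differences over the
28 hemispheric (DASM) and 22 frontal-posterior (DCAU) electrode pairs.
Writes a dimensions table to results/feature_dimensions.csv.
"""

import pandas as pd

from _config import RESULTS, RUN_DIR, run_config
from haptic_eeg.pipeline import (extract_subject_features, load_segments,
                                 subject_datasets)

cfg = run_config()
segs = load_segments(RUN_DIR / "segments" / "subject00.npz")
feats = extract_subject_features(segs)
datasets = subject_datasets(feats, 0)

rows = [{"feature": d.kind, "band": d.band_selection, "pattern": d.pattern,
         "condition": d.condition, "n_windows": d.X.shape[0],
         "n_features": d.X.shape[1]} for d in datasets]
table = pd.DataFrame(rows)
RESULTS.mkdir(exist_ok=True)
table.to_csv(RESULTS / "feature_dimensions.csv", index=False)

widths = table.drop_duplicates(["feature", "band"]).pivot(
    index="band", columns="feature", values="n_features")
print(f"subject 0: {len(datasets)} classifier datasets "
      f"(4 features x 6 band rows x 2 patterns x 2 conditions)")
print("feature widths per band row:")
print(widths[["PSD", "DE", "DASM", "DCAU"]].to_string())
print(f"wrote {RESULTS / 'feature_dimensions.csv'}")
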