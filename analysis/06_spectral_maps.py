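#!/usr/bin/env python
"""Wavelet time-frequency summaries and baseline-subtracted DE topographies.

Morlet (7-cycle) energy averaged in non-overlapping 5-s windows and over
channels/subjects per (pattern, condition, emotion); plus channel-wise
window-mean DE minus baseline DE per band.  CSV maps land in
results/spectral/; the printed summary reports where the joy-gamma
topography peaks.
"""

import shutil

import numpy as np
import pandas as pd

from _config import RESULTS, RUN_DIR, run_config
from haptic_eeg.montage import PREFRONTAL_CHANNELS, TEMPORAL_CHANNELS
from haptic_eeg.pipeline import stage_spectral

cfg = run_config()
spec_dir = stage_spectral(cfg, RUN_DIR)

out = RESULTS / "spectral"
out.mkdir(parents=True, exist_ok=True)
for f in sorted(spec_dir.glob("*.csv")):
    shutil.copy(f, out / f.name)

topo = pd.read_csv(spec_dir / "topo_haptic1_haptic_joy.csv", index_col=0)
gamma = topo["gamma"]
top3 = gamma.sort_values(ascending=False).head(3)
temporal = gamma.loc[[c for c in TEMPORAL_CHANNELS if c in gamma.index]].mean()
rest = gamma.drop([c for c in (*TEMPORAL_CHANNELS, *PREFRONTAL_CHANNELS)
                   if c in gamma.index]).mean()
print(f"copied {len(list(out.glob('*.csv')))} spectral tables to {out}")
print("joy/haptic gamma topography: top channels "
      + ", ".join(f"{c}={v:.2f}" for c, v in top3.items()))
print(f"temporal-group mean {temporal:.2f} nats vs rest {rest:.2f} nats")
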