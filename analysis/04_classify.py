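#!/usr/bin/env python
"""Per-subject 4-class linear-SVM evaluation over the full factor grid.

For every (subject, feature, band, pattern, condition) cell: 4-fold
cross-validation grouped by session (windows of one session never span the
train/test split), features standardized on training folds only.  Copies
the long-format accuracy grid to results/accuracy.csv.
"""

import shutil

import pandas as pd

from _config import RESULTS, RUN_DIR, run_config
from haptic_eeg.pipeline import stage_classify

cfg = run_config()
acc_path = stage_classify(cfg, RUN_DIR)
shutil.copy(acc_path, RESULTS / "accuracy.csv")

acc = pd.read_csv(acc_path)
de = acc[acc.feature == "DE"].pivot_table(index="band", columns="condition",
                                          values="accuracy")
print(f"evaluated {len(acc)} grid cells "
      f"({acc.subject.nunique()} subjects x 96 cells)")
print("mean DE accuracy (%) across subjects and patterns:")
print(de.round(1).loc[["delta", "theta", "alpha", "beta", "gamma", "total"]]
      .to_string())
print(f"wrote {RESULTS / 'accuracy.csv'}")
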