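#!/usr/bin/env python
"""Haptic vs non-haptic statistics: paired t-tests and growth rates.

Per (feature, band, pattern) cell: a two-sided paired-sample t-test across
subjects at alpha = 0.05 and the across-subject mean relative accuracy
growth (haptic - non-haptic) / non-haptic.  The four report tables are
copied into results/tables/.
"""

import shutil

import pandas as pd

from _config import RESULTS, RUN_DIR, run_config
from haptic_eeg.pipeline import stage_report

cfg = run_config()
report_dir = stage_report(cfg, RUN_DIR)

out = RESULTS / "tables"
out.mkdir(parents=True, exist_ok=True)
for name in ("accuracy_haptic1.csv", "accuracy_haptic2.csv",
             "paired_ttest.csv", "growth_rates.csv", "summary.txt"):
    shutil.copy(report_dir / name, out / name)

stats = pd.read_csv(report_dir / "stats_long.csv")
growth = pd.read_csv(report_dir / "growth_long.csv")
sig = stats[stats.significant]
print(f"{len(sig)}/{len(stats)} cells significant at alpha = {cfg.alpha}")
print("significant cells:",
      ", ".join(f"{r.pattern}/{r.feature}/{r.band} (p={r.p:.4f})"
                for r in sig.itertuples()) or "none")
de_growth = growth[growth.feature == "DE"].pivot(index="band",
                                                 columns="pattern",
                                                 values="growth_pct")
print("DE growth rates (%):")
print(de_growth.round(2).to_string())
print(f"tables copied to {out}")
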