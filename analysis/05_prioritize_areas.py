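"""Derive priority river areas and account for protection.

Cells with EMca > 0.9 are clumped under 8-adjacency, clumps with more
than 10 cells are clipped to the river polygons, and the surviving
priority cells are tallied per region, split inside/outside the
protected-area polygons (which cover ~10% of river cells by
construction).
"""

import pandas as pd

from common import STUDY_DIR, publish, study_config
from riversdm.pipeline import stage_prioritize

cfg = study_config()
stage_prioritize(cfg, STUDY_DIR)

table = pd.read_csv(STUDY_DIR / "priority_table.csv", index_col="region")
pct = pd.read_csv(STUDY_DIR / "percent_unprotected.csv", index_col="region")
log = pd.read_csv(STUDY_DIR / "clump_log.csv")

print("priority areas (km2) by region:")
print(table.round(3).to_string())
if not log.empty:
    print("\nclump clipping events:")
    print(log.to_string(index=False))
print(f"\n{pct.loc['all', 'percent_unprotected']:.1f}% of the priority area "
      "falls outside protected areas")

publish("priority_table.csv", "percent_unprotected.csv", "clump_log.csv")
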