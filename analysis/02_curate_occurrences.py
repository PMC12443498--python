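"""Curate the raw occurrence records into modeling presences.

Applies the metadata filters (uncertainty > 1000 m, pre-1990 dates,
reservoir/dam records), early-life classification (documented evidence,
spawning-river registry, or Strahler order <= 4 with a 500 m pull),
river snapping within 500 m, grid sampling to one presence per cell, and
draws an equal number of pseudoabsences from the remaining river cells.
"""

import pandas as pd

from common import STUDY_DIR, publish, study_config
from riversdm.pipeline import stage_curate

cfg = study_config()
stage_curate(cfg, STUDY_DIR)

audit = pd.read_csv(STUDY_DIR / "curation_audit.csv")
truth = pd.read_csv(STUDY_DIR / "occurrences_truth.csv").fillna("")
presences = pd.read_csv(STUDY_DIR / "presences.csv")

print(f"raw records: {truth.shape[0]}")
for stage in ("filter", "classify", "snap", "grid_sample"):
    rows = audit[audit["stage"] == stage]
    dropped = rows[rows["disposition"] == "dropped"]
    reasons = dropped["reason"].value_counts().to_dict()
    print(f"  {stage}: {len(rows)} in, {len(dropped)} dropped {reasons or ''}")
print(f"modeling presences: {len(presences)} cells "
      f"(+ {len(presences)} pseudoabsences, equal weightage)")

clean = set(truth[truth["truth_reason"] == ""]["record_id"])
snap_kept = set(audit[(audit["stage"] == "snap") & (audit["disposition"] == "kept")]["record_id"])
filter_kept = set(audit[(audit["stage"] == "filter") & (audit["disposition"] == "kept")]["record_id"])
classify_kept = set(audit[(audit["stage"] == "classify") & (audit["disposition"] == "kept")]["record_id"])
survivors = filter_kept & classify_kept & snap_kept
print("survivors match the generator's clean ground truth:", survivors == clean)

publish("curation_audit.csv")
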