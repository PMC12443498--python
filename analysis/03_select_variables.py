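"""Screen the candidate environmental variables for collinearity.

Computes the Pearson correlation matrix over the presence and
pseudoabsence sites and keeps, in ecological priority order (hyd, sgr,
bio10, bio16, hft), every variable with |r| < 0.75 against the already
kept set.  The synthetic stack is constructed with low collinearity, so
all five candidates should pass the gate.
"""

import pandas as pd

from common import STUDY_DIR, publish, study_config
from riversdm.io_utils import read_yaml
from riversdm.pipeline import stage_select_vars

cfg = study_config()
stage_select_vars(cfg, STUDY_DIR)

matrix = pd.read_csv(STUDY_DIR / "correlation_matrix.csv", index_col=0)
kept = read_yaml(STUDY_DIR / "selection.yaml")["kept"]

print("pairwise Pearson r at the modeled sites:")
print(matrix.round(2).to_string())
strongest = matrix.where(lambda m: m < 1).abs().max().max()
print(f"strongest off-diagonal |r| = {strongest:.2f} (threshold {cfg.correlation_threshold})")
print(f"kept for modeling: {', '.join(kept)}")

publish("correlation_matrix.csv")
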