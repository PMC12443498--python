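"""Shared plumbing for the numbered analysis scripts.

All scripts operate on one shared study directory under scratch/ (large
rasters and intermediate artifacts) and copy the small summary tables
they discuss into results/.
"""

from __future__ import annotations

import shutil
from pathlib import Path

from riversdm.config import RunConfig

ROOT = Path(__file__).resolve().parent.parent
STUDY_DIR = ROOT / "scratch" / "study"
RESULTS_DIR = ROOT / "results"


def study_config() -> RunConfig:
    """The default synthetic study: master seed 0, all defaults."""
    return RunConfig(seed=0).validate()


def publish(*names: str) -> None:
    """Copy small text artifacts from the study directory into results/."""
    RESULTS_DIR.mkdir(exist_ok=True)
    for name in names:
        shutil.copy(STUDY_DIR / name, RESULTS_DIR / name)
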