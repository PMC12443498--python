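"""Field habitat assessment: water-quality envelopes and stressor tallies.

Point readings from a handheld multiparameter probe (pH, water
temperature, conductivity, total dissolved solids, dissolved oxygen) are
compared against the species' literature preference envelope with
inclusive bounds.  Observed stressors are tallied per site across five
categories: solid wastes, effluents, activities and facilities,
hydromorphological and ecological degradation, and sanitation.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .errors import AssessmentError

STRESSOR_CATEGORIES = (
    "solid_wastes",
    "effluents",
    "activities_facilities",
    "hydromorph_eco_degradation",
    "sanitation",
)

PARAMETERS = ("ph", "temp_c", "conductivity_us", "tds_mg_l", "do_mg_l")


@dataclass
class WaterQualityReading:
    site: str
    ph: float
    temp_c: float
    conductivity_us: float
    tds_mg_l: float
    do_mg_l: float
    timestamp: str | None = None

    def __post_init__(self):
        for name in PARAMETERS:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise AssessmentError(f"site {self.site}: non-finite {name}")
            if v < 0:
                raise AssessmentError(f"site {self.site}: negative {name}")
        if self.ph > 14:
            raise AssessmentError(f"site {self.site}: pH above 14")


@dataclass
class PreferenceEnvelope:
    """Preferred (lo, hi) bounds per parameter, each with a source tag.

    Defaults: temperature 13-30 degC and dissolved oxygen 6.4-11 mg/L in
    breeding grounds, both from the species literature; pH 7.0-9.0 is an
    assumption encoding the species' alkaline preference (tagged as such);
    conductivity and TDS have no numeric literature bounds and stay
    unassessed unless the user supplies them.
    """

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "temp_c": (13.0, 30.0),
            "do_mg_l": (6.4, 11.0),
            "ph": (7.0, 9.0),
        }
    )
    source_tags: dict[str, str] = field(
        default_factory=lambda: {
            "temp_c": "literature",
            "do_mg_l": "literature (breeding grounds)",
            "ph": "assumption: alkaline preference",
        }
    )

    def __post_init__(self):
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise AssessmentError(f"envelope for {name} has lo >= hi")


@dataclass
class StressorObservation:
    site: str
    category: str
    component: str

    def __post_init__(self):
        if self.category not in STRESSOR_CATEGORIES:
            raise AssessmentError(
                f"unknown stressor category {self.category!r} at site {self.site!r} "
                f"(component {self.component!r})"
            )
        if not self.component:
            raise AssessmentError(f"empty stressor component at site {self.site!r}")


def check_water_quality(
    reading: WaterQualityReading,
    envelope: PreferenceEnvelope | None = None,
) -> dict[str, str]:
    """Status per parameter: below / within / above the preference bounds
    (inclusive at both ends), or unassessed when no bounds exist."""
    envelope = envelope or PreferenceEnvelope()
    if not envelope.bounds:
        raise AssessmentError("envelope defines no parameter bounds")
    status = {}
    for name in PARAMETERS:
        v = getattr(reading, name)
        if name not in envelope.bounds:
            status[name] = "unassessed"
            continue
        lo, hi = envelope.bounds[name]
        status[name] = "below" if v < lo else ("above" if v > hi else "within")
    return status


def assess_readings(
    readings: list[WaterQualityReading],
    envelope: PreferenceEnvelope | None = None,
) -> pd.DataFrame:
    """Status table, one row per reading, one column per parameter."""
    rows = [
        {"site": r.site, **check_water_quality(r, envelope)} for r in readings
    ]
    return pd.DataFrame(rows).set_index("site")


def tally_stressors(
    observations: list[StressorObservation],
) -> tuple[pd.DataFrame, list[str]]:
    """Contingency table of counts (sites x all five categories) and the
    modal category overall; ties are all listed."""
    sites = sorted({o.site for o in observations})
    table = pd.DataFrame(0, index=sites, columns=list(STRESSOR_CATEGORIES))
    for o in observations:
        table.loc[o.site, o.category] += 1
    counts = Counter(o.category for o in observations)
    if not counts:
        return table, []
    top = max(counts.values())
    modal = [c for c in STRESSOR_CATEGORIES if counts.get(c, 0) == top]
    return table, modal
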