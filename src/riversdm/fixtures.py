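"""Small constructed fixtures with known outcomes.

The toy occurrence table here is built record by record with its expected
disposition under the default curation thresholds (uncertainty > 1000 m,
event year < 1990, reservoir/dam waterbody), so filter behaviour can be
checked against exact counts.
"""

from __future__ import annotations

import datetime as _dt

from .curation import OccurrenceRecord


def toy_occurrence_table() -> tuple[list[OccurrenceRecord], dict[str, int]]:
    """Twenty records with known violations.

    Returns (records, expected) where expected maps each primary drop
    reason to its count plus a "kept" count.  Multi-violation records are
    counted once under their primary reason (uncertainty before date
    before waterbody).
    """

    def rec(i, unc, year, wb, evidence="none"):
        return OccurrenceRecord(
            record_id=i,
            lon=10.0 + i,
            lat=10.0,
            event_date=_dt.date(year, 6, 15) if year else None,
            coord_uncertainty_m=unc,
            waterbody_class=wb,
            life_stage_evidence=evidence,
            source_id=f"S{i:02d}",
        )

    records = [
        # clean keepers (10): includes both boundary and missing-metadata cases
        rec(0, 500.0, 2005, "river"),
        rec(1, 1000.0, 1995, "river"),      # exactly at threshold: kept
        rec(2, None, 2010, "river"),        # missing uncertainty: kept
        rec(3, 250.0, None, "river"),       # missing date: kept
        rec(4, None, None, "river"),        # both missing: kept
        rec(5, 999.9, 1990, "river"),       # year boundary: kept
        rec(6, 40.0, 2021, "lake"),         # lake is not a reservoir: kept
        rec(7, 80.0, 2018, "unknown"),
        rec(8, 15.0, 1993, "river"),
        rec(9, 700.0, 2000, "river"),
        # uncertainty violations (4)
        rec(10, 1500.0, 2005, "river"),
        rec(11, 1000.1, 2005, "river"),
        rec(12, 4000.0, None, "river"),
        rec(13, 2500.0, 1980, "reservoir"),  # multi-violation: primary=uncertainty
        # date violations (3)
        rec(14, None, 1989, "river"),
        rec(15, 300.0, 1975, "river"),
        rec(16, 900.0, 1989, "dam"),         # date checked before waterbody
        # waterbody violations (3)
        rec(17, 200.0, 2015, "reservoir"),
        rec(18, None, 2012, "dam"),
        rec(19, 100.0, None, "reservoir"),
    ]
    expected = {"kept": 10, "uncertainty": 4, "date": 3, "waterbody": 3}
    return records, expected
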