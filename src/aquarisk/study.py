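"""Bundled monitoring study: a five-month POP campaign over three supply wells
and one river.

These per-site mean concentrations (ng/dm^3) are the published campaign
averages for thirteen PCB congeners and four chloroorganic pesticides measured
in a municipal well field; each mean condenses ~20 determinations.  The river
crosses the protected well-field area and is monitored as a reference, but the
population drinks well water only, so the river is excluded from exposure.

The quantification limit was 1 ng/dm^3 for every analyte except
p,p'-dichlorodiphenyldichloroethylene (DDE), for which it was 5 ng/dm^3.
Entries reported as "not detected" are carried as 0-valued below-LOQ records.
"""

from __future__ import annotations

import datetime

from .monitoring import AnalyteClass, ConcentrationRecord

WELL_I = "well_I"
WELL_II = "well_II"
WELL_III = "well_III"
RIVER = "river"

SUPPLY_SITES: tuple[str, ...] = (WELL_I, WELL_II, WELL_III)
ALL_SITES: tuple[str, ...] = SUPPLY_SITES + (RIVER,)

DEFAULT_LOQ = 1.0  # ng/dm^3
DDE_CAS = "72-55-9"
DDE_LOQ = 5.0  # ng/dm^3

#: CAS -> (name, class, mean at well I, well II, well III, river) in ng/dm^3
STUDY_MEANS: dict[str, tuple[str, AnalyteClass, float, float, float, float]] = {
    "37680-65-2": ("PCB18", AnalyteClass.PCB, 2.44, 285.87, 131.33, 44.31),
    "38444-84-7": ("PCB20", AnalyteClass.PCB, 0.78, 15.29, 0.0, 72.74),
    "7012-37-5": ("PCB28", AnalyteClass.PCB, 128.23, 6.27, 241.62, 0.0),
    "41464-39-5": ("PCB44", AnalyteClass.PCB, 167.65, 8.56, 118.66, 485.27),
    "35693-99-3": ("PCB52", AnalyteClass.PCB, 0.0, 0.14, 179.46, 0.0),
    "37680-73-2": ("PCB101", AnalyteClass.PCB, 0.0, 3.44, 8.53, 2.18),
    "31508-00-6": ("PCB118", AnalyteClass.PCB, 6.12, 1.17, 0.0, 0.0),
    "32598-14-4": ("PCB105", AnalyteClass.PCB, 0.03, 7.85, 3.21, 1.46),
    "35065-27-1": ("PCB153", AnalyteClass.PCB, 0.0, 1.67, 7.22, 6.74),
    "35065-28-2": ("PCB138", AnalyteClass.PCB, 7.62, 4.13, 4.02, 8.54),
    "35065-30-6": ("PCB170", AnalyteClass.PCB, 5.43, 8.07, 0.69, 2.13),
    "35065-29-3": ("PCB180", AnalyteClass.PCB, 0.0, 0.11, 0.0, 0.0),
    "35694-08-7": ("PCB194", AnalyteClass.PCB, 0.0, 0.0, 0.24, 7.34),
    "58-89-9": ("gamma-HCH", AnalyteClass.COP, 3.26, 98.17, 65.74, 153.86),
    DDE_CAS: ("DDE", AnalyteClass.COP, 6.21, 4.84, 0.0, 0.02),
    "72-54-8": ("DDD", AnalyteClass.COP, 10.48, 2.85, 4.65, 7.48),
    "50-29-3": ("DDT", AnalyteClass.COP, 14.39, 6.65, 3.31, 6.63),
}

#: analyte id -> class, for `aquarisk.monitoring.summarize`
CLASS_BY_ANALYTE: dict[str, AnalyteClass] = {
    cas: entry[1] for cas, entry in STUDY_MEANS.items()
}


def loq_for(analyte_id: str) -> float:
    """Quantification limit (ng/dm^3) for a study analyte."""
    return DDE_LOQ if analyte_id == DDE_CAS else DEFAULT_LOQ


def study_records(sample_date: datetime.date = datetime.date(2010, 6, 1)) -> list[ConcentrationRecord]:
    """The study concentrations as one record per (site, analyte).

    Each record carries the campaign mean directly, so summarising them
    reproduces the published per-site and cross-site averages exactly.
    """
    records = []
    for cas, (name, _cls, *means) in STUDY_MEANS.items():
        loq = loq_for(cas)
        for site, mean in zip(ALL_SITES, means):
            records.append(
                ConcentrationRecord(
                    site_id=site,
                    sample_date=sample_date,
                    analyte_id=cas,
                    value=mean,
                    below_loq=mean < loq,
                    loq=loq,
                    analyte_name=name,
                )
            )
    return records
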