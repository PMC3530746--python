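"""Per-analyte dose-response constants and regulatory screening.

The registry holds, for each analyte, the oral cancer slope factor SF0 in
(mg/(kg*day))^-1, the chronic oral reference dose RfD in mg/(kg*day), the
NOAEL where available, and the EPA weight-of-evidence carcinogen class.
The PCB congener mixture carries a single slope factor (IRIS treats PCB
mixtures by Aroclor-based potency, not per congener), so it is registered
under the synthetic key ``SUM-PCB``.

Screening compares measured concentrations against drinking-water standards:
the US EPA maximum contaminant level for total PCBs, and the EU drinking-water
limits for single pesticides and total pesticides.  A concentration exactly at
the limit is compliant — the limit is the maximum permitted level.
"""

from __future__ import annotations

import enum
import logging
from collections.abc import Iterable
from dataclasses import dataclass

import pandas as pd
import yaml

from .monitoring import NG_TO_MG, AnalyteClass, AnalyteSummary, class_total

logger = logging.getLogger(__name__)

PCB_MIXTURE_ID = "SUM-PCB"


class CarcinogenClass(str, enum.Enum):
    A = "A"
    B2 = "B2"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class PollutantToxicity:
    """Dose-response constants for one analyte.

    ``sf_oral`` is required for the carcinogenic pathway, ``rfd`` for the
    noncancer pathway; either may be absent (``None``) when no value exists.
    """

    analyte_id: str
    cas: str
    name: str
    analyte_class: AnalyteClass
    carcinogen_class: CarcinogenClass = CarcinogenClass.UNCLASSIFIED
    sf_oral: float | None = None  # (mg/(kg*day))^-1
    rfd: float | None = None  # mg/(kg*day)
    noael: float | None = None  # mg/(kg*day)

    def __post_init__(self) -> None:
        for label, v in (("sf_oral", self.sf_oral), ("rfd", self.rfd), ("noael", self.noael)):
            if v is not None and v <= 0:
                raise ValueError(f"{label} must be > 0 when present, got {v}")


class StandardScope(str, enum.Enum):
    PCB_TOTAL = "pcb_total"
    PESTICIDE_SINGLE = "pesticide_single"
    PESTICIDE_TOTAL = "pesticide_total"


@dataclass(frozen=True)
class RegulatoryStandard:
    scope: StandardScope
    limit: float  # mg/dm^3
    authority: str = ""

    def __post_init__(self) -> None:
        if self.limit <= 0:
            raise ValueError(f"limit must be > 0, got {self.limit}")


def default_registry() -> list[PollutantToxicity]:
    """The packaged registry for the study analytes.

    Slope factors and RfDs are the IRIS/RAIS values: total PCBs SF 2.0 and
    RfD 2e-5 (Aroclor 1016 NOAEL 0.007); gamma-HCH SF 1.10 (RAIS; not EPA
    classified) and RfD 3e-4; DDE SF 0.34, RfD 3e-3; DDD SF 0.24, RfD 9e-3;
    DDT SF 0.34, RfD 5e-4, NOAEL 0.05.
    """
    return [
        PollutantToxicity(
            PCB_MIXTURE_ID, PCB_MIXTURE_ID, "Polychlorinated biphenyls (sum)",
            AnalyteClass.PCB, CarcinogenClass.B2, sf_oral=2.0, rfd=2e-5, noael=0.007,
        ),
        PollutantToxicity(
            "58-89-9", "58-89-9", "gamma-HCH", AnalyteClass.COP,
            CarcinogenClass.UNCLASSIFIED, sf_oral=1.10, rfd=3e-4, noael=0.33,
        ),
        PollutantToxicity(
            "72-55-9", "72-55-9", "DDE", AnalyteClass.COP,
            CarcinogenClass.B2, sf_oral=0.34, rfd=3e-3,
        ),
        PollutantToxicity(
            "72-54-8", "72-54-8", "DDD", AnalyteClass.COP,
            CarcinogenClass.B2, sf_oral=0.24, rfd=9e-3,
        ),
        PollutantToxicity(
            "50-29-3", "50-29-3", "DDT", AnalyteClass.COP,
            CarcinogenClass.B2, sf_oral=0.34, rfd=5e-4, noael=0.05,
        ),
    ]


def default_standards() -> list[RegulatoryStandard]:
    """US EPA MCL for total PCBs; EU 98/83/EC pesticide limits (mg/dm^3)."""
    return [
        RegulatoryStandard(StandardScope.PCB_TOTAL, 0.0005, "US EPA MCL"),
        RegulatoryStandard(StandardScope.PESTICIDE_SINGLE, 0.0001, "EU 98/83/EC"),
        RegulatoryStandard(StandardScope.PESTICIDE_TOTAL, 0.0005, "EU 98/83/EC"),
    ]


def load_registry(path) -> list[PollutantToxicity]:
    """Load a registry from YAML: a list of blocks with keys ``id, cas, name,
    class, carcinogen_class, sf_oral, rfd, noael`` (constants optional)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not raw:
        return []
    entries: list[PollutantToxicity] = []
    seen: set[str] = set()
    for block in raw:
        analyte_id = str(block["id"])
        if analyte_id in seen:
            raise ValueError(f"duplicate analyte id {analyte_id!r} in registry {path}")
        seen.add(analyte_id)
        entries.append(
            PollutantToxicity(
                analyte_id=analyte_id,
                cas=str(block.get("cas", analyte_id)),
                name=str(block.get("name", analyte_id)),
                analyte_class=AnalyteClass(block["class"]),
                carcinogen_class=CarcinogenClass(block.get("carcinogen_class", "unclassified")),
                sf_oral=block.get("sf_oral"),
                rfd=block.get("rfd"),
                noael=block.get("noael"),
            )
        )
    return entries


def write_registry(entries: Iterable[PollutantToxicity], path) -> None:
    blocks = [
        {
            "id": e.analyte_id,
            "cas": e.cas,
            "name": e.name,
            "class": e.analyte_class.value,
            "carcinogen_class": e.carcinogen_class.value,
            "sf_oral": e.sf_oral,
            "rfd": e.rfd,
            "noael": e.noael,
        }
        for e in entries
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(blocks, fh, sort_keys=False)


@dataclass(frozen=True)
class ScreeningRow:
    scope: StandardScope
    subject: str  # what was compared (class total or single analyte)
    measured_mg_dm3: float | None
    limit_mg_dm3: float | None
    authority: str
    passed: bool | None  # None = not evaluated

    @property
    def evaluated(self) -> bool:
        return self.passed is not None


@dataclass(frozen=True)
class ScreeningReport:
    rows: tuple[ScreeningRow, ...]

    @property
    def all_pass(self) -> bool:
        return all(r.passed for r in self.rows if r.evaluated)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "scope": r.scope.value,
                    "subject": r.subject,
                    "measured_mg_dm3": r.measured_mg_dm3,
                    "limit_mg_dm3": r.limit_mg_dm3,
                    "authority": r.authority,
                    "status": "not evaluated" if not r.evaluated else ("pass" if r.passed else "FAIL"),
                }
                for r in self.rows
            ]
        )


def screen(
    summaries: Iterable[AnalyteSummary],
    standards: Iterable[RegulatoryStandard] | None = None,
) -> ScreeningReport:
    """Screen exposure-point concentrations against drinking-water standards.

    Concentrations (ng/dm^3) are converted to mg/dm^3; equality with a limit
    counts as compliant.  Scopes without a supplied standard are reported as
    not evaluated, with a warning.
    """
    summaries = list(summaries)
    by_scope = {s.scope: s for s in (standards if standards is not None else default_standards())}
    rows: list[ScreeningRow] = []

    def compare(scope: StandardScope, subject: str, measured_ng: float) -> None:
        std = by_scope.get(scope)
        if std is None:
            logger.warning("no standard supplied for scope %s; not evaluated", scope.value)
            rows.append(ScreeningRow(scope, subject, measured_ng * NG_TO_MG, None, "", None))
            return
        measured = measured_ng * NG_TO_MG
        rows.append(
            ScreeningRow(scope, subject, measured, std.limit, std.authority, measured <= std.limit)
        )

    compare(StandardScope.PCB_TOTAL, "total PCBs", class_total(summaries, AnalyteClass.PCB))
    for s in summaries:
        if s.analyte_class is AnalyteClass.COP:
            compare(StandardScope.PESTICIDE_SINGLE, s.analyte_name or s.analyte_id, s.cross_site_mean)
    compare(StandardScope.PESTICIDE_TOTAL, "total pesticides", class_total(summaries, AnalyteClass.COP))
    return ScreeningReport(tuple(rows))
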