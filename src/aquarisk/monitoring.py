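"""Raw well-monitoring records and their aggregation to exposure-point concentrations.

A monitoring campaign produces one concentration determination per (site, date,
analyte), in ng/dm^3, with a flag for values below the limit of quantification
(LOQ).  Exposure calculations use a single exposure-point concentration per
analyte: the unweighted arithmetic mean over the *supply* sites of the per-site
mean concentrations.  Surface-water reference sites (e.g. a river crossing the
well field) are monitored but excluded from exposure.
"""

from __future__ import annotations

import datetime
import enum
import logging
import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

#: ng/dm^3 -> mg/dm^3
NG_TO_MG = 1e-6

MONITORING_COLUMNS = (
    "site_id",
    "sample_date",
    "analyte_cas",
    "analyte_name",
    "value_ng_dm3",
    "below_loq",
    "loq_ng_dm3",
)


class MonitoringFormatError(ValueError):
    """The monitoring CSV does not match the documented dialect."""


class AnalyteClass(str, enum.Enum):
    """Pollutant family: PCB congeners vs chloroorganic pesticides."""

    PCB = "PCB"
    COP = "COP"


class CensorPolicy(str, enum.Enum):
    """Substitution rule for below-LOQ values when averaging.

    ``as_reported`` keeps the determined value (the campaign convention here:
    sub-LOQ values are retained to show that a compound was detected at very
    low level); ``zero`` and ``half_loq`` are the classical substitutions for
    sensitivity runs.
    """

    AS_REPORTED = "as_reported"
    ZERO = "zero"
    HALF_LOQ = "half_loq"


@dataclass(frozen=True)
class ConcentrationRecord:
    """One analyte determination at one site on one date.

    Parameters
    ----------
    site_id : str
        Sampling site identifier.
    sample_date : datetime.date
        Date the sample was taken.
    analyte_id : str
        CAS registry number (or the synthetic ``SUM-PCB`` key).
    value : float
        Determined concentration, ng/dm^3. Non-negative.
    below_loq : bool
        True when the determination fell below the quantification limit.
    loq : float
        Limit of quantification for this analyte, ng/dm^3.
    analyte_name : str
        Human-readable analyte name (optional, carried through to reports).
    """

    site_id: str
    sample_date: datetime.date
    analyte_id: str
    value: float
    below_loq: bool = False
    loq: float = 1.0
    analyte_name: str = ""

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"concentration must be >= 0, got {self.value}")
        if self.loq <= 0:
            raise ValueError(f"LOQ must be > 0, got {self.loq}")
        if self.below_loq and not self.value < self.loq:
            raise ValueError(
                f"record flagged below LOQ but value {self.value} >= LOQ {self.loq}"
            )


@dataclass(frozen=True)
class AnalyteSummary:
    """Per-analyte exposure-point summary across sites.

    ``cross_site_mean`` is the arithmetic mean of the per-site means over the
    designated supply sites only — the concentration c̄ that enters the dose
    equations.
    """

    analyte_id: str
    analyte_name: str = ""
    analyte_class: AnalyteClass | None = None
    per_site_mean: Mapping[str, float] = field(default_factory=dict)
    cross_site_mean: float = 0.0
    n_samples: Mapping[str, int] = field(default_factory=dict)


def read_monitoring_csv(path) -> list[ConcentrationRecord]:
    """Read monitoring records from the package CSV dialect.

    Expected header: ``site_id,sample_date,analyte_cas,analyte_name,
    value_ng_dm3,below_loq,loq_ng_dm3`` with ISO-8601 dates and 0/1 censoring
    flags.  Raises :class:`MonitoringFormatError` naming any missing column,
    and ``ValueError`` with the offending row number for negative values.
    """
    frame = pd.read_csv(path, dtype={"site_id": str, "analyte_cas": str})
    missing = [c for c in MONITORING_COLUMNS if c not in frame.columns]
    if missing:
        raise MonitoringFormatError(
            f"monitoring file {path} is missing required column(s): {', '.join(missing)}"
        )
    if frame.empty:
        logger.warning("monitoring file %s contains no data rows", path)
        return []
    records: list[ConcentrationRecord] = []
    for idx, row in frame.iterrows():
        rowno = int(idx) + 2  # header is line 1
        value = float(row["value_ng_dm3"])
        if value < 0:
            raise ValueError(f"negative concentration {value} at row {rowno} of {path}")
        try:
            records.append(
                ConcentrationRecord(
                    site_id=str(row["site_id"]),
                    sample_date=datetime.date.fromisoformat(str(row["sample_date"])),
                    analyte_id=str(row["analyte_cas"]),
                    analyte_name=str(row["analyte_name"]),
                    value=value,
                    below_loq=bool(int(row["below_loq"])),
                    loq=float(row["loq_ng_dm3"]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"invalid record at row {rowno} of {path}: {exc}") from exc
    return records


def write_monitoring_csv(records: Iterable[ConcentrationRecord], path) -> None:
    """Write records in the dialect `read_monitoring_csv` expects."""
    rows = [
        {
            "site_id": r.site_id,
            "sample_date": r.sample_date.isoformat(),
            "analyte_cas": r.analyte_id,
            "analyte_name": r.analyte_name,
            "value_ng_dm3": r.value,
            "below_loq": int(r.below_loq),
            "loq_ng_dm3": r.loq,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(MONITORING_COLUMNS)).to_csv(path, index=False)


def _censored_value(record: ConcentrationRecord, policy: CensorPolicy) -> float:
    if not record.below_loq or policy is CensorPolicy.AS_REPORTED:
        return record.value
    if policy is CensorPolicy.ZERO:
        return 0.0
    if policy is CensorPolicy.HALF_LOQ:
        return record.loq / 2.0
    raise ValueError(f"unknown censoring policy {policy!r}")


def summarize(
    records: Iterable[ConcentrationRecord],
    supply_sites: Iterable[str],
    censor_policy: CensorPolicy = CensorPolicy.AS_REPORTED,
    classes: Mapping[str, AnalyteClass] | None = None,
) -> list[AnalyteSummary]:
    """Aggregate records into per-analyte summaries.

    Per-site means are taken after applying ``censor_policy`` to below-LOQ
    values; the cross-site mean averages the per-site means over
    ``supply_sites`` only.  An analyte observed at no supply site gets a
    cross-site mean of 0 with a warning.  ``classes`` maps analyte id to
    :class:`AnalyteClass`; unmapped analytes keep class ``None``.
    """
    supply = set(supply_sites)
    if not supply:
        raise ValueError("supply_sites must be nonempty")
    censor_policy = CensorPolicy(censor_policy)
    classes = dict(classes or {})

    by_analyte: dict[str, list[ConcentrationRecord]] = {}
    for rec in records:
        by_analyte.setdefault(rec.analyte_id, []).append(rec)

    summaries: list[AnalyteSummary] = []
    for analyte_id, recs in by_analyte.items():
        by_site: dict[str, list[float]] = {}
        for rec in recs:
            by_site.setdefault(rec.site_id, []).append(_censored_value(rec, censor_policy))
        # fsum keeps the means exactly permutation-invariant
        per_site_mean = {s: math.fsum(v) / len(v) for s, v in by_site.items()}
        n_samples = {s: len(v) for s, v in by_site.items()}
        supply_means = sorted(m for s, m in per_site_mean.items() if s in supply)
        if supply_means:
            cross = math.fsum(supply_means) / len(supply_means)
        else:
            cross = 0.0
            logger.warning(
                "analyte %s observed at no supply site; cross-site mean set to 0",
                analyte_id,
            )
        summaries.append(
            AnalyteSummary(
                analyte_id=analyte_id,
                analyte_name=recs[0].analyte_name,
                analyte_class=classes.get(analyte_id),
                per_site_mean=per_site_mean,
                cross_site_mean=cross,
                n_samples=n_samples,
            )
        )
    return summaries


def class_total(summaries: Iterable[AnalyteSummary], analyte_class: AnalyteClass | str) -> float:
    """Sum of cross-site means over analytes of one class, ng/dm^3."""
    try:
        cls = AnalyteClass(analyte_class)
    except ValueError:
        valid = ", ".join(c.value for c in AnalyteClass)
        raise ValueError(
            f"unknown analyte class {analyte_class!r}; valid classes: {valid}"
        ) from None
    return sum(s.cross_site_mean for s in summaries if s.analyte_class is cls)


def summary_frame(summaries: Iterable[AnalyteSummary], site_order: Iterable[str] | None = None) -> pd.DataFrame:
    """Tabulate summaries: one row per analyte, one column per site plus the
    cross-site mean — the layout of the campaign concentration tables."""
    summaries = list(summaries)
    if site_order is None:
        sites: list[str] = []
        for s in summaries:
            for site in s.per_site_mean:
                if site not in sites:
                    sites.append(site)
    else:
        sites = list(site_order)
    rows = []
    for s in summaries:
        row: dict[str, object] = {
            "analyte": s.analyte_name or s.analyte_id,
            "cas": s.analyte_id,
            "class": s.analyte_class.value if s.analyte_class else "",
        }
        for site in sites:
            row[site] = s.per_site_mean.get(site)
        row["cross_site_mean"] = s.cross_site_mean
        rows.append(row)
    return pd.DataFrame(rows)
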