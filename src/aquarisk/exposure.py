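"""Ingestion exposure doses for a residential drinking-water scenario.

For a population group with body weight BW (kg), water intake rate IR
(dm^3/day), exposure duration ED (years), exposure frequency EF (days/year)
and fraction ingested FI, the dose from an exposure-point concentration c̄
(ng/dm^3) is

    dose = c̄ * 1e-6 * FI * IR * EF * ED / (BW * AT)   [mg/(kg*day)]

where the averaging time AT (days) distinguishes the two dose measures:

* LADD (lifetime average daily dose, also called CDI) spreads the intake over
  a 70-year lifetime, AT = 25,550 days — the carcinogenic-effects convention.
* ADD (average daily dose) averages over the exposure duration itself,
  AT = ED * 365 days — the noncancer convention.

An alternative averaging convention ("duration-matched") sets the
carcinogenic AT equal to the exposure duration for designated groups, which
is appropriate when concentrations are roughly constant over the assessment
period and yields markedly higher risks for short-duration (child) groups.
"""

from __future__ import annotations

import enum
from collections.abc import Iterable
from dataclasses import dataclass, field

import pandas as pd

from .monitoring import NG_TO_MG, AnalyteClass, AnalyteSummary, class_total
from .toxicity import PCB_MIXTURE_ID

#: 70 years x 365 days/year
LIFETIME_DAYS = 25_550.0


class Convention(str, enum.Enum):
    """Averaging-time convention for the carcinogenic dose."""

    EPA_LIFETIME = "epa_lifetime"
    DURATION_MATCHED = "duration_matched"


@dataclass(frozen=True)
class PopulationGroup:
    """An exposed subpopulation and its intake parameters."""

    label: str
    size: float  # persons
    bw: float  # kg
    ir: float  # dm^3/day
    ed_years: float
    at_cancer_days: float = LIFETIME_DAYS
    at_noncancer_days: float | None = None  # default ED * 365

    def __post_init__(self) -> None:
        if self.size < 0:
            raise ValueError("population size must be >= 0")
        if self.bw <= 0 or self.ed_years <= 0:
            raise ValueError("bw and ed_years must be > 0")
        if self.ir < 0:
            raise ValueError("intake rate must be >= 0")
        if self.at_noncancer_days is None:
            object.__setattr__(self, "at_noncancer_days", self.ed_years * 365.0)
        if self.at_noncancer_days <= 0 or self.at_cancer_days < self.at_noncancer_days:
            raise ValueError("need 0 < at_noncancer_days <= at_cancer_days")


@dataclass(frozen=True)
class ExposureContext:
    """Scenario-wide exposure parameters.

    ``duration_matched_groups`` lists the group labels whose carcinogenic
    averaging time is replaced by their exposure duration under the
    duration-matched convention; an empty set means every group.
    """

    fi: float = 0.65  # fraction ingested, dimensionless
    ef: float = 365.0  # days/year
    convention: Convention = Convention.EPA_LIFETIME
    duration_matched_groups: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "convention", Convention(self.convention))
        object.__setattr__(self, "duration_matched_groups", frozenset(self.duration_matched_groups))
        if not 0.0 <= self.fi <= 1.0:
            raise ValueError("fi must lie in [0, 1]")
        if not 0.0 < self.ef <= 365.0:
            raise ValueError("ef must lie in (0, 365]")

    def at_cancer(self, group: PopulationGroup) -> float:
        """Effective carcinogenic averaging time for ``group`` (days)."""
        if self.convention is Convention.DURATION_MATCHED and (
            not self.duration_matched_groups or group.label in self.duration_matched_groups
        ):
            return group.at_noncancer_days
        return group.at_cancer_days


@dataclass(frozen=True)
class DoseResult:
    """LADD and ADD for one (analyte, group) cell, mg/(kg*day)."""

    analyte_id: str
    analyte_name: str
    group_label: str
    ladd: float
    add: float


def _intake_per_at(c_bar: float, group: PopulationGroup, ctx: ExposureContext, at_days: float) -> float:
    if c_bar < 0:
        raise ValueError("concentration must be >= 0")
    if at_days <= 0 or group.bw <= 0:
        raise ValueError("bw and averaging time must be > 0")
    return (c_bar * NG_TO_MG) * ctx.fi * group.ir * ctx.ef * group.ed_years / (group.bw * at_days)


def compute_ladd(c_bar: float, group: PopulationGroup, ctx: ExposureContext) -> float:
    """Lifetime average daily dose, mg/(kg*day), for concentration ``c_bar``
    in ng/dm^3, using the context's carcinogenic averaging convention."""
    return _intake_per_at(c_bar, group, ctx, ctx.at_cancer(group))


def compute_add(c_bar: float, group: PopulationGroup, ctx: ExposureContext) -> float:
    """Average daily dose, mg/(kg*day): intake averaged over the exposure
    duration itself."""
    return _intake_per_at(c_bar, group, ctx, group.at_noncancer_days)


def dose_table(
    summaries: Iterable[AnalyteSummary],
    groups: Iterable[PopulationGroup],
    ctx: ExposureContext,
) -> list[DoseResult]:
    """One DoseResult per (assessment row, group).

    PCB congeners enter as a single class-total row (keyed ``SUM-PCB``,
    matching the mixture slope factor); pesticides enter individually.
    """
    summaries = list(summaries)
    groups = list(groups)
    if not summaries or not groups:
        raise ValueError("summaries and groups must be nonempty")

    rows: list[tuple[str, str, float]] = []
    pcb_total = class_total(summaries, AnalyteClass.PCB)
    if any(s.analyte_class is AnalyteClass.PCB for s in summaries):
        rows.append((PCB_MIXTURE_ID, "Polychlorinated biphenyls (sum)", pcb_total))
    for s in summaries:
        if s.analyte_class is not AnalyteClass.PCB:
            rows.append((s.analyte_id, s.analyte_name or s.analyte_id, s.cross_site_mean))

    results = []
    for analyte_id, name, c_bar in rows:
        for g in groups:
            results.append(
                DoseResult(
                    analyte_id=analyte_id,
                    analyte_name=name,
                    group_label=g.label,
                    ladd=compute_ladd(c_bar, g, ctx),
                    add=compute_add(c_bar, g, ctx),
                )
            )
    return results


def load_scenario(path) -> tuple[list[PopulationGroup], ExposureContext, list[str]]:
    """Load an exposure scenario from YAML.

    Schema: ``groups`` (list of label/size/bw/ir/ed_years and optional
    at_cancer_days/at_noncancer_days), ``context`` (fi, ef, convention,
    duration_matched_groups) and optional ``supply_sites``.
    """
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    groups = [
        PopulationGroup(
            label=str(g["label"]),
            size=float(g["size"]),
            bw=float(g["bw"]),
            ir=float(g["ir"]),
            ed_years=float(g["ed_years"]),
            at_cancer_days=float(g.get("at_cancer_days", LIFETIME_DAYS)),
            at_noncancer_days=(
                float(g["at_noncancer_days"]) if "at_noncancer_days" in g else None
            ),
        )
        for g in raw.get("groups", [])
    ]
    c = raw.get("context", {})
    ctx = ExposureContext(
        fi=float(c.get("fi", 0.65)),
        ef=float(c.get("ef", 365.0)),
        convention=Convention(c.get("convention", "epa_lifetime")),
        duration_matched_groups=frozenset(c.get("duration_matched_groups", ())),
    )
    return groups, ctx, [str(s) for s in raw.get("supply_sites", [])]


def write_scenario(groups: Iterable[PopulationGroup], ctx: ExposureContext, supply_sites: Iterable[str], path) -> None:
    import yaml

    doc = {
        "groups": [
            {
                "label": g.label,
                "size": g.size,
                "bw": g.bw,
                "ir": g.ir,
                "ed_years": g.ed_years,
                "at_cancer_days": g.at_cancer_days,
                "at_noncancer_days": g.at_noncancer_days,
            }
            for g in groups
        ],
        "context": {
            "fi": ctx.fi,
            "ef": ctx.ef,
            "convention": ctx.convention.value,
            "duration_matched_groups": sorted(ctx.duration_matched_groups),
        },
        "supply_sites": list(supply_sites),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def dose_frame(results: Iterable[DoseResult], which: str = "ladd") -> pd.DataFrame:
    """Pivot dose results to an analyte x group matrix of LADD or ADD."""
    if which not in ("ladd", "add"):
        raise ValueError("which must be 'ladd' or 'add'")
    results = list(results)
    if not results:
        return pd.DataFrame(index=pd.Index([], name="analyte"))
    frame = pd.DataFrame(
        [
            {"analyte": r.analyte_name, "group": r.group_label, which: getattr(r, which)}
            for r in results
        ]
    )
    order = list(dict.fromkeys(r.analyte_name for r in results))
    groups = list(dict.fromkeys(r.group_label for r in results))
    return (
        frame.pivot(index="analyte", columns="group", values=which)
        .reindex(index=order, columns=groups)
        .rename_axis(index="analyte", columns=None)
    )
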