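"""Cancer risk, population burden, and noncancer hazard characterization.

Carcinogenic risk follows the one-hit dose-response model

    ELCR = 1 - exp(-LADD * SF0)

with its linear low-dose form ELCR = LADD * SF0, valid below risk ~0.01.
Risks from multiple carcinogens add (response additivity); the population
burden is the expected number of extra cancer cases, ECC = ELCR * N for a
population of N persons.  Noncancer hazard is the quotient HQ = ADD / RfD and
the per-group hazard index HI = sum of HQs; HI > 1 flags potential harm.

Individual risks are classified against the conventional acceptability bands:
below 1e-6 unconditionally negligible, 1e-6 to 1e-4 the usual acceptable
range, 1e-4 to 1e-3 remediation desirable, and 1e-3 or more requiring
protective measures.

Two slope-factor configurations are shipped.  ``per_analyte`` (the default)
applies each analyte's own registry slope factor.  ``as_published`` applies
the PCB-mixture slope factor 2.0 (mg/(kg*day))^-1 uniformly to all five
assessment rows — the configuration under which the study's published risk
and burden tables reproduce exactly (every published ELCR equals twice its
LADD, including for the pesticides whose registry SFs differ).
"""

from __future__ import annotations

import enum
import logging
import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import pandas as pd

from .exposure import DoseResult, PopulationGroup
from .toxicity import PollutantToxicity

logger = logging.getLogger(__name__)

#: linear/one-hit crossover: below this dose*SF the linear form is used in auto mode
LOW_RISK_LIMIT = 0.01


class DoseResponseModel(str, enum.Enum):
    LINEAR = "linear"
    ONE_HIT = "one_hit"
    AUTO = "auto"


class SFConfig(str, enum.Enum):
    """Named slope-factor configurations (see module docstring)."""

    AS_PUBLISHED = "as_published"
    PER_ANALYTE = "per_analyte"


class RiskLevel(str, enum.Enum):
    NEGLIGIBLE = "negligible"
    ACCEPTABLE_RANGE = "acceptable_range"
    REMEDIATION_DESIRABLE = "remediation_desirable"
    PROTECTIVE_MEASURES_REQUIRED = "protective_measures_required"


#: ordered ELCR bin edges for `classify`
RISK_THRESHOLDS = (1e-6, 1e-4, 1e-3)


def cancer_risk(dose: float, sf: float, model: DoseResponseModel = DoseResponseModel.ONE_HIT) -> float:
    """Excess lifetime cancer risk for a dose in mg/(kg*day) and an oral
    slope factor in (mg/(kg*day))^-1."""
    if dose < 0:
        raise ValueError("dose must be >= 0")
    if sf <= 0:
        raise ValueError("slope factor must be > 0")
    x = dose * sf
    model = DoseResponseModel(model)
    if model is DoseResponseModel.AUTO:
        model = DoseResponseModel.LINEAR if x < LOW_RISK_LIMIT else DoseResponseModel.ONE_HIT
    if model is DoseResponseModel.LINEAR:
        return min(x, 1.0)
    return 1.0 - math.exp(-x)


def cumulative_risk(risks: Iterable[float]) -> float:
    """Total risk from several carcinogens: the arithmetic sum of the
    individual risks (response additivity).  Warns if the sum exceeds 1."""
    risks = list(risks)
    for r in risks:
        if not 0.0 <= r < 1.0:
            raise ValueError(f"individual risks must lie in [0, 1), got {r}")
    total = sum(risks)
    if total > 1.0:
        logger.warning("cumulative risk %.3g exceeds 1; additivity is a low-risk approximation", total)
    return total


def extra_cancer_cases(elcr: float, group: PopulationGroup) -> float:
    """Expected extra cancer cases in the group: ELCR x population size.

    Reported as a real-valued expectation; meaningful for large populations.
    """
    if not 0.0 <= elcr < 1.0:
        raise ValueError("elcr must lie in [0, 1)")
    return elcr * group.size


def hazard_quotient(add: float, rfd: float) -> float:
    """Noncancer hazard quotient ADD / RfD (both in mg/(kg*day))."""
    if rfd <= 0:
        raise ValueError("rfd must be > 0")
    if add < 0:
        raise ValueError("add must be >= 0")
    return add / rfd


def hazard_index(hqs: Iterable[float]) -> float:
    """Hazard index: sum of hazard quotients."""
    hqs = list(hqs)
    for hq in hqs:
        if hq < 0:
            raise ValueError("hazard quotients must be >= 0")
    return sum(hqs)


def classify(elcr: float) -> RiskLevel:
    """Place an individual ELCR in the acceptability bands (lower bound of
    each band inclusive)."""
    if not 0.0 <= elcr < 1.0:
        raise ValueError("elcr must lie in [0, 1)")
    lo, mid, hi = RISK_THRESHOLDS
    if elcr < lo:
        return RiskLevel.NEGLIGIBLE
    if elcr < mid:
        return RiskLevel.ACCEPTABLE_RANGE
    if elcr < hi:
        return RiskLevel.REMEDIATION_DESIRABLE
    return RiskLevel.PROTECTIVE_MEASURES_REQUIRED


def slope_factors(
    registry: Iterable[PollutantToxicity],
    sf_config: SFConfig | str = SFConfig.PER_ANALYTE,
) -> dict[str, float]:
    """Resolve the per-analyte slope factors for a named configuration."""
    sf_config = SFConfig(sf_config)
    entries = [e for e in registry if e.sf_oral is not None]
    if sf_config is SFConfig.AS_PUBLISHED:
        return {e.analyte_id: 2.0 for e in entries}
    return {e.analyte_id: e.sf_oral for e in entries}


@dataclass(frozen=True)
class RiskTable:
    """ELCR per (analyte, group) and the per-group cumulative totals."""

    elcr: pd.DataFrame  # analytes x groups
    elcr_tot: pd.Series  # per group
    model: DoseResponseModel
    sf_config: SFConfig

    def classification(self) -> pd.Series:
        return self.elcr_tot.map(lambda r: classify(r).value)


@dataclass(frozen=True)
class PopulationBurden:
    """Expected extra cancer cases per (analyte, group), per group, overall."""

    ecc: pd.DataFrame  # analytes x groups
    ecc_pop: pd.Series  # per group
    ecc_gen: float  # whole population


@dataclass(frozen=True)
class HazardTable:
    """HQ per (analyte, group) and per-group hazard indices with flags."""

    hq: pd.DataFrame  # analytes x groups
    hi: pd.Series  # per group

    @property
    def exceedances(self) -> pd.Series:
        return self.hi > 1.0


def _pivot(doses: list[DoseResult], values: Mapping[tuple[str, str], float]) -> pd.DataFrame:
    order = list(dict.fromkeys(d.analyte_name for d in doses))
    groups = list(dict.fromkeys(d.group_label for d in doses))
    if not values:
        return pd.DataFrame(index=pd.Index([], name="analyte"), columns=groups, dtype=float)
    frame = pd.DataFrame(
        [
            {"analyte": d.analyte_name, "group": d.group_label, "v": values[(d.analyte_id, d.group_label)]}
            for d in doses
            if (d.analyte_id, d.group_label) in values
        ]
    )
    return (
        frame.pivot(index="analyte", columns="group", values="v")
        .reindex(columns=groups)
        .reindex(index=[a for a in order if a in set(frame["analyte"])])
        .rename_axis(index="analyte", columns=None)
    )


def risk_table(
    doses: Iterable[DoseResult],
    registry: Iterable[PollutantToxicity],
    sf_config: SFConfig | str = SFConfig.PER_ANALYTE,
    model: DoseResponseModel | str = DoseResponseModel.ONE_HIT,
) -> RiskTable:
    """Per-cell ELCR from LADDs, plus cumulative per-group totals.

    Analytes without a slope factor in the resolved configuration are omitted
    with a warning.
    """
    doses = list(doses)
    model = DoseResponseModel(model)
    sfs = slope_factors(registry, sf_config)
    missing = {d.analyte_id for d in doses} - set(sfs)
    if missing:
        logger.warning("no slope factor for %s; omitted from cancer risk", ", ".join(sorted(missing)))
    cells = {
        (d.analyte_id, d.group_label): cancer_risk(d.ladd, sfs[d.analyte_id], model)
        for d in doses
        if d.analyte_id in sfs
    }
    elcr = _pivot(doses, cells)
    elcr_tot = elcr.apply(lambda col: cumulative_risk(col.dropna()))
    return RiskTable(elcr=elcr, elcr_tot=elcr_tot, model=model, sf_config=SFConfig(sf_config))


def population_burden(risks: RiskTable, groups: Iterable[PopulationGroup]) -> PopulationBurden:
    """Convert per-cell risks into expected extra cancer cases."""
    by_label = {g.label: g for g in groups}
    sizes = pd.Series({label: by_label[label].size for label in risks.elcr.columns})
    ecc = risks.elcr * sizes
    ecc_pop = ecc.sum(axis=0)
    return PopulationBurden(ecc=ecc, ecc_pop=ecc_pop, ecc_gen=float(ecc_pop.sum()))


def hazard_table(doses: Iterable[DoseResult], registry: Iterable[PollutantToxicity]) -> HazardTable:
    """Per-cell hazard quotients from ADDs and registry RfDs, plus per-group
    hazard indices.  Analytes without an RfD are skipped with a warning."""
    doses = list(doses)
    rfds = {e.analyte_id: e.rfd for e in registry if e.rfd is not None}
    missing = {d.analyte_id for d in doses} - set(rfds)
    if missing:
        logger.warning("no RfD for %s; omitted from hazard index", ", ".join(sorted(missing)))
    cells = {
        (d.analyte_id, d.group_label): hazard_quotient(d.add, rfds[d.analyte_id])
        for d in doses
        if d.analyte_id in rfds
    }
    hq = _pivot(doses, cells)
    hi = hq.apply(lambda col: hazard_index(col.dropna()))
    return HazardTable(hq=hq, hi=hi)
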