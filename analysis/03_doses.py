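"""Compute the dose matrices for the residential ingestion scenario.

LADD (cancer convention, 70-year averaging) and ADD (noncancer convention,
averaging over the exposure duration) per assessment analyte and population
group.  PCB congeners enter as one class-total row with the mixture slope
factor downstream; pesticides enter individually.  Writes results/ladd.csv
and results/add.csv.
"""

import pathlib

import aquarisk as aq
from aquarisk import study

RESULTS = pathlib.Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    records = aq.read_monitoring_csv(RESULTS / "monitoring_pinned.csv")
    groups, ctx, registry = aq.default_scenario()
    classes = {**study.CLASS_BY_ANALYTE, **{e.analyte_id: e.analyte_class for e in registry}}
    summaries = aq.summarize(records, study.SUPPLY_SITES, classes=classes)
    doses = aq.dose_table(summaries, groups, ctx)
    for which in ("ladd", "add"):
        frame = aq.dose_frame(doses, which)
        frame.to_csv(RESULTS / f"{which}.csv")
        print(f"{which.upper()} [mg/(kg*day)]")
        print(frame.to_string(float_format=lambda v: f"{v:.4g}"), end="\n\n")


if __name__ == "__main__":
    main()
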