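"""Aggregate the campaign to exposure-point concentrations and screen them.

Reads results/monitoring_pinned.csv, computes per-well and cross-well means
per analyte, totals per pollutant class, and screens the concentrations
against the drinking-water standards (US EPA PCB MCL, EU pesticide limits).
Writes results/concentrations.csv and results/screening.csv.
"""

import pathlib

import aquarisk as aq
from aquarisk import study

RESULTS = pathlib.Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    records = aq.read_monitoring_csv(RESULTS / "monitoring_pinned.csv")
    summaries = aq.summarize(records, study.SUPPLY_SITES, classes=study.CLASS_BY_ANALYTE)
    frame = aq.summary_frame(summaries, site_order=study.ALL_SITES)
    frame.to_csv(RESULTS / "concentrations.csv", index=False)

    pcb_total = aq.class_total(summaries, "PCB")
    cop_total = aq.class_total(summaries, "COP")
    print(f"cross-well mean totals: PCBs {pcb_total:.2f} ng/dm3, "
          f"pesticides {cop_total:.2f} ng/dm3")

    report = aq.screen(summaries)
    report.to_frame().to_csv(RESULTS / "screening.csv", index=False)
    print(report.to_frame().to_string(index=False))
    print("all standards met" if report.all_pass else "STANDARD EXCEEDED")


if __name__ == "__main__":
    main()
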