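"""Generate the monitoring campaign used by the downstream analyses.

Writes two campaigns to results/: one with cv = 0, i.e. every determination
pinned to the per-well study means (the deterministic input every later step
consumes), and one with the default log-normal scatter (cv = 0.3) for
sensitivity exploration.
"""

import json
import pathlib

import aquarisk as aq
from aquarisk.synthetic import study_campaign_spec

RESULTS = pathlib.Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    for tag, cv in (("pinned", 0.0), ("noisy", 0.3)):
        spec = study_campaign_spec(cv=cv, n_dates=20, cadence_days=7, seed=SEED)
        records = aq.generate_campaign(spec)
        path = RESULTS / f"monitoring_{tag}.csv"
        aq.write_monitoring_csv(records, path)
        meta = {"seed": SEED, "cv": cv, "n_dates": 20, "cadence_days": 7,
                "n_records": len(records)}
        (RESULTS / f"monitoring_{tag}.meta.json").write_text(json.dumps(meta, indent=2) + "\n")
        print(f"{tag}: wrote {len(records)} records ({len(spec.analytes)} analytes x "
              f"{len(spec.sites)} sites x {spec.n_dates} dates) -> {path.name}")


if __name__ == "__main__":
    main()
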