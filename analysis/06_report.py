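#!/usr/bin/env python
"""Bundle everything into results/report: tables, plots, run metadata."""

import pathlib

import pandas as pd

from analysis_common import COHORT_DIR, load_cohort
from arrestnirs import pipeline
from arrestnirs.detect import latency_table
from arrestnirs.hemodynamics import cohort_table
from arrestnirs.report import build_report

RESULTS = pathlib.Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    sessions = [pipeline.process_recording(rec) for rec in load_cohort()]
    summaries = [s for sess in sessions for s in pipeline.prepost_all(sess)]
    detections = [d for sess in sessions for d in pipeline.detect_all(sess)]
    lat_summary, lat_pairs = latency_table(detections)
    pulse = pd.concat([pipeline.pulse_table(s) for s in sessions], ignore_index=True)

    first = sessions[0]
    traces = {
        "derived_channels": {
            n: first.channels[n] for n in ("MAP", "TSI", "PO2") if n in first.channels
        },
        "pulse_channels": {n: first.channels[n] for n in ("ABP_z", "O2Hb_z")},
    }
    out = build_report(
        RESULTS / "report",
        prepost=cohort_table(summaries),
        latency_summary=lat_summary,
        latency_pairs=lat_pairs,
        pulse=pulse,
        traces=traces,
        metadata={"cohort_dir": str(COHORT_DIR), "n_animals": len(sessions),
                  "preset": "cohort", "seed": 11},
    )
    print(f"report bundle written to {out}")


if __name__ == "__main__":
    main()
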