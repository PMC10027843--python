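"""Report bundle: summary CSVs, trace plots and run metadata.

Everything written here is deterministic given its inputs: CSVs use a fixed
float format, JSON metadata is key-sorted, and figures are rendered with the
non-interactive Agg backend.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["build_report"]

FLOAT_FMT = "%.6g"


def _write_csv(frame: pd.DataFrame, path: pathlib.Path, index: bool = False) -> None:
    frame.to_csv(path, float_format=FLOAT_FMT, index=index)


def _config_hash(metadata: dict) -> str:
    blob = json.dumps(metadata, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def build_report(
    outdir,
    prepost: pd.DataFrame | None = None,
    latency_summary: pd.DataFrame | None = None,
    latency_pairs: pd.DataFrame | None = None,
    pulse: pd.DataFrame | None = None,
    tests=None,
    traces: dict[str, "object"] | None = None,
    metadata: dict | None = None,
) -> pathlib.Path:
    """Write whatever results are present; an empty call yields a valid skeleton.

    ``traces`` maps a figure name to a dict of ``label -> TimeSeries`` drawn
    on a shared axis.  ``tests`` is an iterable of
    :class:`arrestnirs.stats.TestResult`.
    """
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if prepost is not None:
        flat = prepost.copy()
        if isinstance(flat.columns, pd.MultiIndex):
            flat.columns = ["_".join(map(str, c)) for c in flat.columns]
        _write_csv(flat, outdir / "prepost_table.csv", index=True)
    if latency_summary is not None:
        _write_csv(latency_summary, outdir / "latency_summary.csv")
    if latency_pairs is not None:
        _write_csv(latency_pairs, outdir / "latency_pairwise.csv")
    if pulse is not None:
        _write_csv(pulse, outdir / "pulse_table.csv")
    if tests:
        rows = []
        for t in tests:
            row = dataclasses.asdict(t)
            row["df"] = str(row["df"])
            rows.append(row)
        _write_csv(pd.DataFrame(rows), outdir / "test_summaries.csv")

    for name, chans in (traces or {}).items():
        fig, ax = plt.subplots(figsize=(8, 3.5))
        for label, ts in chans.items():
            ax.plot(ts.times, ts.data, lw=0.7, label=label)
        ax.set_xlabel("time (s)")
        ax.legend(loc="best", fontsize=8)
        ax.set_title(name)
        fig.tight_layout()
        fig.savefig(outdir / f"{name}.png", dpi=110)
        plt.close(fig)

    meta = dict(metadata or {})
    meta.setdefault("float_format", FLOAT_FMT)
    meta["config_hash"] = _config_hash(meta)
    with open(outdir / "run_metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=str)
    return outdir
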