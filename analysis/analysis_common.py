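"""Shared helper for the analysis drivers: reload the simulated cohort."""

import pathlib

import yaml

from arrestnirs import synth

COHORT_DIR = pathlib.Path(__file__).resolve().parents[1] / "results" / "cohort"


def load_cohort(cohort_dir: pathlib.Path = COHORT_DIR) -> list[synth.AnimalRecording]:
    """Re-simulate the cohort exactly from its stored configuration."""
    if not (cohort_dir / "cohort_config.yaml").exists():
        raise SystemExit(f"{cohort_dir} missing - run 01_simulate_cohort.py first")
    with open(cohort_dir / "cohort_config.yaml") as fh:
        raw = yaml.safe_load(fh)
    recordings = []
    for animal_id in sorted(raw):
        cfg = dict(raw[animal_id])
        has_map = cfg.pop("has_map", True)
        has_po2 = cfg.pop("has_po2", True)
        cfg["artifact_schedule"] = tuple(
            synth.ArtifactEvent(**ev) for ev in cfg.get("artifact_schedule", [])
        )
        if cfg.get("tachycardia") is not None:
            cfg["tachycardia"] = synth.Tachycardia(**cfg["tachycardia"])
        recordings.append(
            synth.simulate_animal(synth.AnimalConfig(**cfg), has_map=has_map, has_po2=has_po2)
        )
    return recordings
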