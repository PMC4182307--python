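"""Stage orchestration: simulate -> metrics -> onset -> cohort -> power.

Each stage reads/writes the CSV schemas in :mod:`runwheel.io`; all
randomness derives from the single master seed in the run configuration, so
a run is bit-reproducible from its manifest.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from . import cohort as cohort_mod
from . import io as rio
from . import onset as onset_mod
from .power import PowerSpec, min_group_size, power_two_sample_t
from .presets import get_preset
from .sim import cohort_daily_table, cohort_metadata, cohort_weekly_table, simulate_cohort

log = logging.getLogger("runwheel")

STAGES = ("simulate", "metrics", "onset", "cohort", "power")

#: stage -> input tables it needs and the stage that produces them
_NEEDS = {
    "onset": [("daily.csv", "metrics"), ("weekly.csv", "simulate")],
    "cohort": [("onsets.csv", "onset")],
}


class MissingStageError(RuntimeError):
    """An upstream output is missing; the message names the stage to run."""


def _require(outdir: Path, stage: str) -> None:
    for fname, producer in _NEEDS.get(stage, []):
        if not (outdir / fname).exists():
            raise MissingStageError(
                f"stage '{stage}' needs {fname}; run stage '{producer}' first"
            )


def run_pipeline(
    preset: str = "sod1",
    n_animals: int = 15,
    seed: int = 0,
    outdir: str | Path = "runwheel-out",
    stages: tuple[str, ...] = STAGES,
    power_delta: float = 10.0,
    power_sd: float | None = None,
    target_power: float = 0.80,
) -> rio.RunManifest:
    """Run the requested stages in dependency order and write a manifest."""
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise ValueError(f"unknown stages {bad}; valid: {STAGES}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ordered = [s for s in STAGES if s in stages]
    manifest = rio.RunManifest(seed=seed, preset=preset, n_animals=n_animals, stages=ordered)

    if "simulate" in ordered or "metrics" in ordered:
        config = get_preset(preset, n_animals=n_animals, seed=seed)
        tracks = simulate_cohort(config)
        daily = cohort_daily_table(tracks) if config.wheel_access else pd.DataFrame(
            columns=rio.SCHEMAS["daily"])
        weekly = cohort_weekly_table(tracks)
        animals = cohort_metadata(tracks)
        rio.write_table(daily, outdir / "daily.csv", "daily")
        rio.write_table(weekly, outdir / "weekly.csv", "weekly")
        rio.write_table(animals, outdir / "animals.csv", "animals")
        log.info("simulate: %d animals, %d daily records (%d censored)",
                 len(tracks), len(daily),
                 int(daily["censored"].sum()) if len(daily) else 0)

    if "onset" in ordered:
        _require(outdir, "onset")
        daily = rio.load_table(outdir / "daily.csv", "daily")
        weekly = rio.load_table(outdir / "weekly.csv", "weekly")
        onsets = onset_mod.onsets_table(daily, weekly)
        rio.write_table(onsets, outdir / "onsets.csv", "onsets")
        log.info("onset: %d results, %d censored", len(onsets), int(onsets["censored"].sum()))

    if "cohort" in ordered:
        _require(outdir, "cohort")
        onsets = rio.load_table(outdir / "onsets.csv", "onsets")
        summaries = cohort_mod.summaries_table(onsets)
        rio.write_table(summaries, outdir / "summaries.csv", "summaries")
        log.info("cohort: %d study/metric summaries", len(summaries))

    if "power" in ordered:
        sd = 3.93 if power_sd is None else power_sd
        rows = []
        for n in range(2, 21):
            rows.append({"n_per_group": n,
                         "power": power_two_sample_t(PowerSpec(power_delta, sd, n))})
        pd.DataFrame(rows).to_csv(outdir / "power.csv", index=False, float_format="%.4f")
        n_min = min_group_size(power_delta, sd, target_power=target_power)
        (outdir / "power.txt").write_text(
            f"delta={power_delta} sd={sd} alpha=0.05 two-sided: "
            f"min n per group for power {target_power} = {n_min}\n"
        )
        log.info("power: min group size %d (delta=%g, sd=%g)", n_min, power_delta, sd)

    for f in sorted(outdir.glob("*.csv")):
        manifest.outputs[f.name] = rio.file_digest(f)
    manifest.write(outdir / "manifest.json")
    return manifest
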