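"""End-to-end orchestration: simulate/load -> detect -> arrival -> transit -> stats.

A run consumes either simulation configs or recordings, processes every
animal through the identical per-channel chain, matches beats across
sites, fits the per-animal regressions, pools them and writes fixed-name
CSV tables plus a JSON manifest. Given the same configs and seed, output
files are byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .arrival import annotate_channel, beats_to_frame
from .config import SimulationConfig
from .recording import PressureRecording
from .simulate import simulate_experiment
from .stats import CohortResults, analyze_cohort
from .transit import PWV_PLAUSIBLE, build_pairs, pairs_to_frame

__all__ = ["RunManifest", "analyze_recording", "run_pipeline"]

log = logging.getLogger("pulsetransit")


@dataclass
class RunManifest:
    """Per-run record counts, outputs and provenance."""

    seed: int | None
    config: dict
    counts: dict[str, dict[str, int]]
    output_files: list[str]
    version: str = __version__

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "seed": self.seed,
                    "version": self.version,
                    "config": self.config,
                    "counts": self.counts,
                    "output_files": self.output_files,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")


def analyze_recording(
    recording: PressureRecording,
    detection_params: dict | None = None,
    pressure_source: str = "distal",
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Process one recording into beat and pair tables plus stage counts.

    Returns ``(beat_table, pair_table, counts)`` where counts reconcile
    with the table row counts (detected, valid, premature-flagged,
    matched, rejected).
    """
    params = detection_params or {}
    prox = annotate_channel(recording.proximal, recording.sampling_rate, **params)
    dist = annotate_channel(recording.distal, recording.sampling_rate, **params)
    pairs, rejected = build_pairs(prox, dist, recording.sensor_distance)
    beat_table = pd.concat(
        [beats_to_frame(prox, "proximal"), beats_to_frame(dist, "distal")],
        ignore_index=True,
    )
    pair_table = pairs_to_frame(pairs, pressure_source)
    counts = {
        "beats_detected_proximal": len(prox),
        "beats_detected_distal": len(dist),
        "beats_valid_proximal": sum(b.valid for b in prox),
        "beats_valid_distal": sum(b.valid for b in dist),
        "premature_flagged": sum(b.premature for b in prox) + sum(b.premature for b in dist),
        "pairs_matched": len(pairs),
        "pairs_rejected": rejected,
    }
    pwv = pair_table["pwv_mps"].dropna()
    n_implausible = int(((pwv < PWV_PLAUSIBLE[0]) | (pwv > PWV_PLAUSIBLE[1])).sum())
    if n_implausible:
        log.warning(
            "%s: %d pairs with wave velocity outside %s m/s",
            recording.animal_id,
            n_implausible,
            PWV_PLAUSIBLE,
        )
    return beat_table, pair_table, counts


def run_pipeline(
    inputs: Mapping[str, SimulationConfig] | Mapping[str, PressureRecording],
    output_dir: str | Path,
    group: str = "cohort",
    detection_params: dict | None = None,
    pressure_source: str = "distal",
    pooling_method: str = "unweighted_z_mean",
) -> tuple[RunManifest, CohortResults]:
    """Run every animal through the full chain and write result tables.

    ``inputs`` maps animal id to either a :class:`SimulationConfig`
    (simulated at run time) or a ready :class:`PressureRecording`.
    Outputs in ``output_dir``: ``beats_<animal>.csv``,
    ``pairs_<animal>.csv``, ``per_animal_regressions.csv``,
    ``pooled_summary.csv``, ``manifest.json``.
    """
    if not inputs:
        raise ValueError("no recordings or simulation scenarios supplied")
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    counts: dict[str, dict[str, int]] = {}
    pair_tables: dict[str, pd.DataFrame] = {}
    config_snapshot: dict = {}
    outputs: list[str] = []
    seed = None
    for animal, item in inputs.items():
        t0 = time.perf_counter()
        if isinstance(item, SimulationConfig):
            config_snapshot[animal] = item.to_dict()
            seed = item.seed if seed is None else seed
            recording = simulate_experiment(item).recording
            recording.animal_id = animal
        elif isinstance(item, PressureRecording):
            recording = item
            config_snapshot[animal] = {"source": "recording", "animal_id": animal}
        else:
            raise TypeError(f"input for {animal!r} is neither config nor recording")
        beat_table, pair_table, animal_counts = analyze_recording(
            recording, detection_params, pressure_source
        )
        if pair_table.empty:
            raise RuntimeError(f"{animal}: no valid beat pairs after exclusions")
        counts[animal] = animal_counts
        pair_tables[animal] = pair_table
        for name, table in (("beats", beat_table), ("pairs", pair_table)):
            path = outdir / f"{name}_{animal}.csv"
            table.to_csv(path, index=False, float_format="%.6f")
            outputs.append(str(path))
        log.info("%s: %.2f s, %s", animal, time.perf_counter() - t0, animal_counts)

    results = analyze_cohort(pair_tables, group=group, pooling_method=pooling_method)
    reg_path = outdir / "per_animal_regressions.csv"
    results.per_animal.to_csv(reg_path, index=False, float_format="%.6f")
    pooled_path = outdir / "pooled_summary.csv"
    results.pooled_table().to_csv(pooled_path, index=False, float_format="%.6f")
    outputs += [str(reg_path), str(pooled_path)]

    manifest = RunManifest(
        seed=seed, config=config_snapshot, counts=counts, output_files=outputs
    )
    manifest.to_json(outdir / "manifest.json")
    return manifest, results
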