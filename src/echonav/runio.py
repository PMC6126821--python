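"""File formats and run artifacts.

Formats: 2-channel float32 WAV at the sonar sample rate, JSON scenes (see
:mod:`echonav.scene`), CSV trajectories, PNG occupancy maps with a JSON
sidecar carrying origin/resolution, and JSON-lines detections.  Every run
directory embeds the config snapshot and its hash, so config + seed
reproduce the run exactly.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml
from PIL import Image
from scipy.io import wavfile

from .acoustics import BinauralRecording, Pose
from .config import RunConfig
from .mapping import OccupancyMap
from .navigation import MissionResult
from .perception import DetectedObject

logger = logging.getLogger(__name__)


# -- WAV ---------------------------------------------------------------------

def write_wav(path, recording: BinauralRecording) -> None:
    data = np.stack([recording.left, recording.right], axis=1).astype(np.float32)
    wavfile.write(path, int(recording.sample_rate), data)


def read_wav(path, pose: Pose = (0.0, 0.0, 0.0),
             heading_offset_deg=0.0) -> BinauralRecording:
    rate, data = wavfile.read(path)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError("expected a 2-channel WAV")
    return BinauralRecording(left=data[:, 0].astype(np.float64),
                             right=data[:, 1].astype(np.float64),
                             sample_rate=float(rate), pose=pose,
                             heading_offset_deg=heading_offset_deg)


# -- config ------------------------------------------------------------------

def load_config(path) -> RunConfig:
    """Load a YAML config; missing keys fall back to the package defaults.

    Unknown keys and out-of-range values raise a validation error.  An
    empty file yields all defaults.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    return RunConfig.model_validate(data)


# -- map ---------------------------------------------------------------------

def write_map(path_png, path_json, occ: OccupancyMap) -> None:
    img = Image.fromarray((occ.grid.astype(np.uint8) * 255)[::-1])  # y up
    img.save(path_png)
    sidecar = {
        "origin_m": list(occ.origin),
        "resolution_m": occ.config.resolution_m,
        "grid_size": occ.config.grid_size,
        "occupied_cells": int(occ.grid.sum()),
    }
    Path(path_json).write_text(json.dumps(sidecar, indent=1))


def read_map(path_png, path_json) -> OccupancyMap:
    sidecar = json.loads(Path(path_json).read_text())
    img = np.asarray(Image.open(path_png))[::-1] > 0
    from .config import MappingConfig

    cfg = MappingConfig(grid_size=sidecar["grid_size"],
                        resolution_m=sidecar["resolution_m"])
    return OccupancyMap(config=cfg, origin=tuple(sidecar["origin_m"]),
                        grid=img.copy())


# -- detections / trajectory -------------------------------------------------

def detection_to_json(obj: DetectedObject, pose: Pose, step: int) -> dict:
    return {
        "step": step,
        "pose": list(pose),
        "range_m": obj.range_m,
        "azimuth_deg": obj.azimuth_deg,
        "C": obj.C,
        "T": obj.T,
        "P": obj.P,
    }


def write_run_artifacts(rundir, result: MissionResult, config: RunConfig) -> dict:
    """Write trajectory CSV, map PNG+JSON, detections JSONL, report and config.

    Returns the report dict.  Rerunning with the same config and seed
    produces byte-identical CSV/JSONL.
    """
    rundir = Path(rundir)
    rundir.mkdir(parents=True, exist_ok=True)
    with open(rundir / "trajectory.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["step", "x_m", "y_m", "heading_deg"])
        for k, (x, y, h) in enumerate(result.trajectory):
            w.writerow([k, f"{x:.6f}", f"{y:.6f}", f"{h:.3f}"])
    with open(rundir / "detections.jsonl", "w") as fh:
        for step, pose, objs in result.detections_log:
            for obj in objs:
                fh.write(json.dumps(detection_to_json(obj, pose, step)) + "\n")
    write_map(rundir / "map.png", rundir / "map.json", result.map)
    with open(rundir / "run.log", "w") as fh:
        for step, pose, objs in result.detections_log:
            fh.write(f"step={step} pose=({pose[0]:.3f},{pose[1]:.3f},"
                     f"{pose[2]:.1f}) detections={len(objs)}\n")
    (rundir / "config.yaml").write_text(
        yaml.safe_dump(config.model_dump(), sort_keys=True))
    report = {
        "status": result.status,
        "steps": len(result.trajectory) - 1,
        "n_detections": sum(len(objs) for _, _, objs in result.detections_log),
        "occupied_cells": int(result.map.grid.sum()),
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
    (rundir / "report.json").write_text(json.dumps(report, indent=1))
    logger.info("run artifacts written to %s (%d steps, %d detections)",
                rundir, report["steps"], report["n_detections"])
    return report
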