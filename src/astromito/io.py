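"""Reading and writing stacks, ground truth and result tables."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .morphometry import CellRecord, MitoFeatures
from .simulate import AcquisitionConfig, FrameStack, MitoGroundTruth

__all__ = [
    "read_stack",
    "write_features_csv",
    "write_ground_truth",
    "write_stack",
]


def write_stack(stack: FrameStack, outdir: str | Path) -> Path:
    """Write one stack as multi-page TIFF per channel plus a metadata JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dtype = np.uint16 if stack.config.bit_depth <= 16 else np.float32
    tifffile.imwrite(outdir / "green.tif", stack.green.astype(dtype))
    tifffile.imwrite(outdir / "red.tif", stack.red.astype(dtype))
    meta = {
        "cell_id": stack.cell_id,
        "condition": stack.condition,
        "timepoint": stack.timepoint,
        "config": dataclasses.asdict(stack.config),
    }
    (outdir / "meta.json").write_text(json.dumps(meta, indent=2))
    return outdir


def read_stack(indir: str | Path) -> FrameStack:
    indir = Path(indir)
    meta = json.loads((indir / "meta.json").read_text())
    cfg = meta["config"]
    cfg["image_shape"] = tuple(cfg["image_shape"])
    config = AcquisitionConfig(**cfg)
    return FrameStack(
        green=tifffile.imread(indir / "green.tif").astype(float),
        red=tifffile.imread(indir / "red.tif").astype(float),
        config=config,
        cell_id=meta["cell_id"],
        condition=meta["condition"],
        timepoint=meta["timepoint"],
    )


def write_ground_truth(gt: MitoGroundTruth, outdir: str | Path) -> None:
    """Ground truth as JSON (objects, motion, counts) + event-schedule CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = {
        "mitochondria": [dataclasses.asdict(m) for m in gt.mitochondria],
        "drift_velocity": list(gt.drift_velocity),
        "diffusion": gt.diffusion,
        "live_counts": gt.live_counts.tolist(),
    }
    (outdir / "ground_truth.json").write_text(json.dumps(payload, indent=2))
    rows = [
        {"frame": ev.frame, "type": ev.kind,
         "ids": ";".join(map(str, ev.participants))}
        for ev in gt.events
    ]
    pd.DataFrame(rows, columns=["frame", "type", "ids"]).to_csv(
        outdir / "events.csv", index=False
    )


def write_features_csv(features: list[MitoFeatures], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(f) for f in features]).to_csv(path, index=False)
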