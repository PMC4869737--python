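"""Reading and writing the pipeline's on-disk formats.

Movies travel as multi-page TIFF (one page per frame) with a JSON sidecar
holding the physical calibration (and, for synthetic scenes, the generative
parameters and seed); event tables, GTT curves and calcium traces are plain
CSV.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import tifffile

from .core import FusionEvent, ImagingScene, events_to_frame, frame_to_events
from .synthetic import CalciumTrace, GTTCurve, SceneGroundTruth, SceneParams

__all__ = [
    "write_scene", "read_scene", "write_ground_truth", "read_ground_truth",
    "write_events", "read_events", "read_gtt", "read_calcium_trace",
]

PathLike = Union[str, Path]


def write_scene(scene: ImagingScene, out_dir: PathLike,
                stem: str = "movie",
                params: Optional[SceneParams] = None) -> Path:
    """Write a movie as multi-page TIFF plus a calibration sidecar JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tiff_path = out_dir / f"{stem}.tif"
    tifffile.imwrite(tiff_path, scene.frames)
    sidecar = {
        "pixel_size_um": scene.pixel_size_um,
        "frame_interval_s": scene.frame_interval_s,
    }
    if params is not None:
        fields = dataclasses.asdict(params)
        if not isinstance(fields["cluster_size_dist"], (int, float)):
            fields["cluster_size_dist"] = str(fields["cluster_size_dist"])
        sidecar["params"] = fields
        sidecar["seed"] = params.seed
    (out_dir / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))
    if scene.cell_mask is not None:
        tifffile.imwrite(out_dir / f"{stem}_mask.tif",
                         scene.cell_mask.astype(np.int32))
    return tiff_path


def read_scene(tiff_path: PathLike,
               pixel_size_um: Optional[float] = None,
               frame_interval_s: Optional[float] = None,
               mask_path: Optional[PathLike] = None) -> ImagingScene:
    """Read a movie TIFF; calibration comes from the sidecar JSON unless
    given explicitly."""
    tiff_path = Path(tiff_path)
    frames = tifffile.imread(tiff_path)
    if frames.ndim == 2:
        frames = frames[None]
    sidecar_path = tiff_path.with_suffix(".json")
    if (pixel_size_um is None or frame_interval_s is None):
        if not sidecar_path.exists():
            raise ValueError(
                "missing calibration: provide pixel_size_um and "
                "frame_interval_s or a sidecar JSON")
        sidecar = json.loads(sidecar_path.read_text())
        pixel_size_um = pixel_size_um or sidecar["pixel_size_um"]
        frame_interval_s = frame_interval_s or sidecar["frame_interval_s"]
    mask = None
    if mask_path is not None:
        mask = tifffile.imread(mask_path)
    else:
        default_mask = tiff_path.with_name(tiff_path.stem + "_mask.tif")
        if default_mask.exists():
            mask = tifffile.imread(default_mask)
    return ImagingScene(frames=frames, pixel_size_um=pixel_size_um,
                        frame_interval_s=frame_interval_s, cell_mask=mask)


def write_ground_truth(truth: SceneGroundTruth, path: PathLike) -> Path:
    path = Path(path)
    df = events_to_frame(truth.events)
    df = df.rename(columns={"frame_index": "frame"})
    df[["x_um", "y_um", "t_s", "amplitude", "site_id", "site_kind"]].to_csv(
        path, index=False)
    return path


def read_ground_truth(path: PathLike, frame_interval_s: float) -> list[FusionEvent]:
    df = pd.read_csv(path)
    events = []
    for row in df.itertuples(index=False):
        events.append(FusionEvent(
            x_um=float(row.x_um), y_um=float(row.y_um), t_s=float(row.t_s),
            frame_index=int(np.ceil(row.t_s / frame_interval_s)),
            amplitude=float(row.amplitude),
            site_id=int(row.site_id), site_kind=str(row.site_kind)))
    return events


def write_events(events: Sequence[FusionEvent], path: PathLike) -> Path:
    path = Path(path)
    df = events_to_frame(events).rename(columns={"frame_index": "frame"})
    df[["x_um", "y_um", "t_s", "frame", "amplitude", "size_um", "cell_id"]].to_csv(
        path, index=False)
    return path


def read_events(path: PathLike) -> list[FusionEvent]:
    df = pd.read_csv(path)
    if "frame" in df.columns:
        df = df.rename(columns={"frame": "frame_index"})
    if "frame_index" not in df.columns:
        df["frame_index"] = 0
    if "amplitude" not in df.columns:
        df["amplitude"] = 1.0
    if "t_s" not in df.columns:
        df["t_s"] = 0.0
    return frame_to_events(df)


def read_gtt(path: PathLike) -> pd.DataFrame:
    """Long-format GTT table: time_min, glucose_mmol_l (+ optional animal_id)."""
    df = pd.read_csv(path)
    missing = {"time_min", "glucose_mmol_l"} - set(df.columns)
    if missing:
        raise ValueError(f"GTT CSV is missing columns: {sorted(missing)}")
    return df


def read_calcium_trace(path: PathLike) -> CalciumTrace:
    df = pd.read_csv(path)
    missing = {"time_s", "ratio"} - set(df.columns)
    if missing:
        raise ValueError(f"calcium CSV is missing columns: {sorted(missing)}")
    return CalciumTrace(times_s=df["time_s"].to_numpy(),
                        ratio=df["ratio"].to_numpy())
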