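"""Shared domain containers for islet exocytosis analysis.

The two objects every stage of the pipeline exchanges are the imaging scene
(a time-ordered fluorescence stack with physical calibration) and the fusion
event (one granule-fusion occurrence with sub-pixel position, time, amplitude
and an optional size / cell / site annotation).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["ImagingScene", "FusionEvent", "events_to_frame", "frame_to_events"]


@dataclass
class ImagingScene:
    """A single-channel time-lapse stack with physical calibration.

    Frames are time-major ``(n_frames, ny, nx)``; pixel ``(i, j)`` sits at
    physical position ``(j * pixel_size_um, i * pixel_size_um)`` and frame
    ``k`` at time ``k * frame_interval_s``.  ``cell_mask`` is an optional
    label image (0 = extracellular, k >= 1 = cell k) with the frame shape.
    """

    frames: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    cell_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, ny, nx) stack")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if np.any(self.frames < 0):
            raise ValueError("intensities must be non-negative")
        if self.cell_mask is not None:
            self.cell_mask = np.asarray(self.cell_mask)
            if self.cell_mask.shape != self.frames.shape[1:]:
                raise ValueError("cell_mask shape must match frame shape")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def field_size_um(self) -> tuple[float, float]:
        """(width, height) of the field in micrometres."""
        ny, nx = self.shape
        return nx * self.pixel_size_um, ny * self.pixel_size_um


@dataclass
class FusionEvent:
    """One granule-fusion event: dye entry at a point in space and time."""

    x_um: float
    y_um: float
    t_s: float
    frame_index: int
    amplitude: float
    size_um: Optional[float] = None
    cell_id: Optional[int] = None
    site_id: Optional[int] = None
    site_kind: Optional[str] = None  # "primary" | "compound" (ground truth)

    def as_dict(self) -> dict:
        return asdict(self)


_EVENT_COLUMNS = [
    "x_um", "y_um", "t_s", "frame_index", "amplitude",
    "size_um", "cell_id", "site_id", "site_kind",
]


def events_to_frame(events: Sequence[FusionEvent]) -> pd.DataFrame:
    """Tabulate events as a DataFrame (one row per event)."""
    rows = [e.as_dict() for e in events]
    df = pd.DataFrame(rows, columns=_EVENT_COLUMNS)
    return df


def frame_to_events(df: pd.DataFrame) -> list[FusionEvent]:
    """Rebuild FusionEvent objects from a table with the standard columns."""
    events = []
    for row in df.itertuples(index=False):
        events.append(FusionEvent(
            x_um=float(row.x_um),
            y_um=float(row.y_um),
            t_s=float(row.t_s),
            frame_index=int(row.frame_index),
            amplitude=float(row.amplitude),
            size_um=None if _isna(getattr(row, "size_um", None)) else float(row.size_um),
            cell_id=None if _isna(getattr(row, "cell_id", None)) else int(row.cell_id),
            site_id=None if _isna(getattr(row, "site_id", None)) else int(row.site_id),
            site_kind=None if _isna(getattr(row, "site_kind", None)) else str(row.site_kind),
        ))
    return events


def _isna(value) -> bool:
    return value is None or (isinstance(value, float) and np.isnan(value)) or (
        not isinstance(value, (int, float)) and pd.isna(value)
    )
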