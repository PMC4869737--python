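"""Neighborhood-count statistics and compound-exocytosis classification.

For each fusion event we count how many fusion events (the focal event
included, by default) fall inside a small window — 4 um^2 by default —
centred on it, pooling the whole recording.  The normalised histogram of
these counts is the neighborhood frequency profile; an event whose window
holds at least seven granules is classified as compound exocytosis
(sequential granule–granule fusion through one pore), otherwise primary.

The window is an axis-aligned square of side sqrt(area) with
boundary-inclusive membership; a disc of equal area is available for
sensitivity analysis.  Counts use a k-d tree but agree exactly with the
brute-force all-pairs rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import FusionEvent

__all__ = [
    "SpatialParams",
    "NeighborhoodProfile",
    "ExocytosisClassification",
    "neighborhood_counts",
    "classify_exocytosis",
    "tail_frequency",
]

EventsLike = Union[Sequence[FusionEvent], pd.DataFrame, np.ndarray]


@dataclass
class SpatialParams:
    """Window geometry and the compound threshold.

    window_area_um2
        Neighborhood area around each focal event (default 4 um^2, i.e. a
        2 x 2 um square).
    compound_threshold
        Minimum granules in the window (focal included) for the event to be
        called compound (default 7).
    window_shape
        "square" (default) or "disc" of equal area.
    include_focal
        Whether the focal event itself is counted (default True, so the
        compound rule reads "at least seven granules in the window").
    """

    window_area_um2: float = 4.0
    compound_threshold: int = 7
    window_shape: str = "square"
    include_focal: bool = True

    def __post_init__(self) -> None:
        if self.window_area_um2 <= 0:
            raise ValueError("window_area_um2 must be positive")
        if self.compound_threshold < 2:
            raise ValueError("compound_threshold must be >= 2")
        if self.window_shape not in ("square", "disc"):
            raise ValueError("window_shape must be 'square' or 'disc'")


@dataclass
class NeighborhoodProfile:
    """Per-event window counts and their normalised histogram."""

    per_event_counts: np.ndarray
    frequency: dict[int, float]


@dataclass
class ExocytosisClassification:
    """Per-event primary/compound labels and the aggregate split."""

    labels: list[str]
    n_primary: int
    n_compound: int
    fraction_compound: float


def _coords(events: EventsLike) -> np.ndarray:
    if isinstance(events, pd.DataFrame):
        xy = events[["x_um", "y_um"]].to_numpy(dtype=float)
    elif isinstance(events, np.ndarray):
        xy = np.asarray(events, dtype=float)
        if xy.ndim != 2 or xy.shape[1] != 2:
            raise ValueError("coordinate array must have shape (n, 2)")
    else:
        xy = np.array([[e.x_um, e.y_um] for e in events], dtype=float)
    if xy.shape[0] == 0:
        raise ValueError("at least one event is required")
    return xy


def neighborhood_counts(events: EventsLike,
                        params: SpatialParams | None = None
                        ) -> NeighborhoodProfile:
    """Count, for every event, the events inside its centred window.

    All events of the recording are pooled (no time windowing, matching the
    pooled 20-min stimulation).  Window membership is boundary-inclusive.
    """
    if params is None:
        params = SpatialParams()
    xy = _coords(events)
    tree = cKDTree(xy)
    if params.window_shape == "square":
        half_side = np.sqrt(params.window_area_um2) / 2.0
        neighbors = tree.query_ball_point(xy, r=half_side, p=np.inf)
    else:
        radius = np.sqrt(params.window_area_um2 / np.pi)
        neighbors = tree.query_ball_point(xy, r=radius, p=2)
    counts = np.array([len(n) for n in neighbors], dtype=int)
    if not params.include_focal:
        counts = counts - 1
    values, occurrences = np.unique(counts, return_counts=True)
    n = counts.size
    frequency = {int(v): float(c) / n for v, c in zip(values, occurrences)}
    return NeighborhoodProfile(per_event_counts=counts, frequency=frequency)


def classify_exocytosis(events: EventsLike,
                        params: SpatialParams | None = None
                        ) -> ExocytosisClassification:
    """Label each event compound (window count >= threshold) or primary."""
    if params is None:
        params = SpatialParams()
    profile = neighborhood_counts(events, params)
    compound = profile.per_event_counts >= params.compound_threshold
    n_compound = int(compound.sum())
    n_total = compound.size
    labels = ["compound" if c else "primary" for c in compound]
    return ExocytosisClassification(
        labels=labels,
        n_primary=n_total - n_compound,
        n_compound=n_compound,
        fraction_compound=n_compound / n_total,
    )


def tail_frequency(profile: NeighborhoodProfile, k: int) -> float:
    """Fraction of events with window count >= k.

    With k equal to the compound threshold this is, by definition, the
    fraction of compound events (the quantity reported as 4.62% in healthy
    vs 22.71% in stage-1 prediabetic islets).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    return float(sum(f for count, f in profile.frequency.items() if count >= k))
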