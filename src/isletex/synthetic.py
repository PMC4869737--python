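"""Seeded synthetic data: two-photon fusion movies, GTT curves, calcium traces.

The movie generator emulates sulforhodamine-B (SRB) imaging of islets: the
bath dye makes the extracellular space bright, cell interiors are dark, and
each granule fusion lets dye into the granule, producing an abrupt punctate
brightening that persists (the granule stays dye-filled).  Fusion sites are a
superposition of two point processes:

* *primary* events — a homogeneous spatial Poisson process, uniform in time;
* *compound* sites — a Neyman–Scott cluster process: parent sites are Poisson,
  each parent spawns >= 2 granules jittered by ``cluster_sd_um`` that fuse
  sequentially with exponential inter-fusion gaps, stacking amplitude steps at
  (nearly) one location, the staircase signature of compound exocytosis.

Everything is seeded; identical parameters give bit-identical output.  The
root seed is split into independent sub-streams (cells, positions, times,
noise) so that e.g. changing the noise level does not move the events.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Union

import numpy as np

from .core import FusionEvent, ImagingScene

__all__ = [
    "SceneParams",
    "SceneGroundTruth",
    "GTTCurve",
    "CalciumTrace",
    "FuraCalibration",
    "generate_scene",
    "sample_ground_truth",
    "render_scene",
    "generate_cell_mask",
    "generate_gtt_curve",
    "generate_calcium_trace",
    "concentration_to_ratio",
]

# cluster_size_dist may be a fixed integer, a {count: probability} mapping, or
# a callable rng -> int; support must be >= 2 granules per compound site.
ClusterSizeDist = Union[int, dict, Callable[[np.random.Generator], int]]


@dataclass
class SceneParams:
    """Generative parameters of one synthetic recording.

    Geometry is in micrometres; conversion to pixels happens only at render
    time.  Rates are per um^2 per whole recording.  Defaults emulate a
    20 min recording (240 frames x 5 s) of a 50x50 um field stimulated with
    15 mmol/l glucose in a 0.8 mmol/l SRB bath.
    """

    field_width_um: float = 50.0
    field_height_um: float = 50.0
    pixel_size_um: float = 0.25
    n_frames: int = 240
    frame_interval_s: float = 5.0
    background_level: float = 100.0   # extracellular SRB intensity (a.u.)
    cell_interior_level: float = 20.0
    noise_sd: float = 2.0
    primary_rate: float = 0.02        # primary events / um^2 / recording
    cluster_rate: float = 0.0         # compound sites / um^2 / recording
    cluster_size_dist: ClusterSizeDist = 8
    cluster_sd_um: float = 0.2
    event_radius_um: float = 0.5      # Gaussian sigma of the rendered spot
    event_amplitude: float = 20.0
    inter_fusion_interval_s: float = 10.0
    decay_tau_s: Optional[float] = None  # None = dye-filled granule, no decay
    with_cell_mask: bool = False
    cell_diameter_um: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.field_width_um <= 0 or self.field_height_um <= 0:
            raise ValueError("field dimensions must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel_size_um and frame_interval_s must be positive")
        for name in ("background_level", "cell_interior_level", "noise_sd",
                     "primary_rate", "cluster_rate", "cluster_sd_um",
                     "event_amplitude", "inter_fusion_interval_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.event_radius_um <= 0:
            raise ValueError("event_radius_um must be positive")
        if self.cell_interior_level >= self.background_level:
            raise ValueError("cell_interior_level must be below background_level")
        if isinstance(self.cluster_size_dist, int) and self.cluster_size_dist < 2:
            raise ValueError("cluster_size_dist support must be >= 2")
        if isinstance(self.cluster_size_dist, dict):
            if min(self.cluster_size_dist) < 2:
                raise ValueError("cluster_size_dist support must be >= 2")
            if not np.isclose(sum(self.cluster_size_dist.values()), 1.0):
                raise ValueError("cluster_size_dist probabilities must sum to 1")

    @property
    def area_um2(self) -> float:
        return self.field_width_um * self.field_height_um

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval_s


@dataclass
class SceneGroundTruth:
    """True event list and generative parameters, for validating estimators."""

    events: list[FusionEvent]
    params: SceneParams
    true_compound_fraction: float


@dataclass
class GTTCurve:
    """Blood glucose vs time during a glucose tolerance test."""

    times_min: np.ndarray
    glucose_mmol_l: np.ndarray

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.glucose_mmol_l = np.asarray(self.glucose_mmol_l, dtype=float)
        if self.times_min.shape != self.glucose_mmol_l.shape:
            raise ValueError("times and glucose must have equal length")
        if self.times_min.size < 2:
            raise ValueError("a GTT curve needs at least two samples")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.glucose_mmol_l <= 0):
            raise ValueError("glucose must be positive")


@dataclass
class CalciumTrace:
    """Background-corrected Fura-2 ratio trace."""

    times_s: np.ndarray
    ratio: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.ratio = np.asarray(self.ratio, dtype=float)
        if self.times_s.shape != self.ratio.shape:
            raise ValueError("times and ratio must have equal length")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class FuraCalibration:
    """Ratiometric (Grynkiewicz) calibration constants for Fura-2.

    ``kd_nmol_l`` is the indicator dissociation constant (default 224 nmol/l
    at 37 C); ``beta`` is the free/bound fluorescence ratio at the denominator
    wavelength and is instrument-specific, so it has no default.
    """

    r_min: float
    r_max: float
    beta: float
    kd_nmol_l: float = 224.0

    def __post_init__(self) -> None:
        if not self.r_min < self.r_max:
            raise ValueError("r_min must be below r_max")
        if self.kd_nmol_l <= 0 or self.beta <= 0:
            raise ValueError("kd_nmol_l and beta must be positive")


# ---------------------------------------------------------------------------
# Point-process sampling
# ---------------------------------------------------------------------------

def _sample_cluster_size(dist: ClusterSizeDist, rng: np.random.Generator) -> int:
    if isinstance(dist, int):
        return dist
    if isinstance(dist, dict):
        values = np.array(sorted(dist))
        probs = np.array([dist[v] for v in values], dtype=float)
        return int(rng.choice(values, p=probs / probs.sum()))
    return max(2, int(dist(rng)))


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(4)
    names = ("cells", "positions", "times", "noise")
    return {n: np.random.default_rng(s) for n, s in zip(names, children)}


def _place_uniform(n: int, params: SceneParams, rng: np.random.Generator,
                   mask: Optional[np.ndarray]) -> np.ndarray:
    """Uniform positions on the field, restricted to cell footprints if masked."""
    if n == 0:
        return np.empty((0, 2))
    if mask is None:
        x = rng.uniform(0, params.field_width_um, n)
        y = rng.uniform(0, params.field_height_um, n)
        return np.column_stack([x, y])
    out = np.empty((n, 2))
    got = 0
    for _ in range(1000):  # rejection sampling onto labelled pixels
        need = n - got
        x = rng.uniform(0, params.field_width_um, need)
        y = rng.uniform(0, params.field_height_um, need)
        keep = _mask_label_at(mask, x, y, params.pixel_size_um) > 0
        k = int(keep.sum())
        out[got:got + k] = np.column_stack([x[keep], y[keep]])
        got += k
        if got == n:
            return out
    raise RuntimeError("could not place events on cell footprints")


def _mask_label_at(mask: np.ndarray, x_um, y_um, pixel_size_um: float) -> np.ndarray:
    j = np.clip(np.rint(np.asarray(x_um) / pixel_size_um).astype(int), 0, mask.shape[1] - 1)
    i = np.clip(np.rint(np.asarray(y_um) / pixel_size_um).astype(int), 0, mask.shape[0] - 1)
    return mask[i, j]


def generate_cell_mask(params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    """Voronoi partition of seeded cell centres, with a thin extracellular
    boundary band (label 0) between cells where the bright bath dye sits."""
    ny = int(round(params.field_height_um / params.pixel_size_um))
    nx = int(round(params.field_width_um / params.pixel_size_um))
    n_cells = max(1, int(round(params.area_um2 / (params.cell_diameter_um ** 2))))
    cx = rng.uniform(0, params.field_width_um, n_cells)
    cy = rng.uniform(0, params.field_height_um, n_cells)
    xs = np.arange(nx) * params.pixel_size_um
    ys = np.arange(ny) * params.pixel_size_um
    gx, gy = np.meshgrid(xs, ys)
    d2 = (gx[..., None] - cx) ** 2 + (gy[..., None] - cy) ** 2
    order = np.argsort(d2, axis=-1)
    label = order[..., 0] + 1
    if n_cells > 1:
        d_sorted = np.take_along_axis(np.sqrt(d2), order[..., :2], axis=-1)
        boundary = (d_sorted[..., 1] - d_sorted[..., 0]) < 0.5  # um band
        label[boundary] = 0
    return label.astype(np.int32)


def sample_ground_truth(params: SceneParams,
                        mask: Optional[np.ndarray] = None) -> SceneGroundTruth:
    """Draw the true event list (positions, times, site structure) without
    rendering any pixels.  Primary events form a homogeneous Poisson process;
    compound sites follow a Neyman-Scott process with sequential fusion times.
    """
    params.validate()
    rngs = _substreams(params.seed)
    pos_rng, time_rng = rngs["positions"], rngs["times"]
    events: list[FusionEvent] = []
    site_id = 0

    n_primary = pos_rng.poisson(params.primary_rate * params.area_um2)
    primary_xy = _place_uniform(n_primary, params, pos_rng, mask)
    primary_t = np.sort(time_rng.uniform(0, params.duration_s, n_primary))
    for (x, y), t in zip(primary_xy, primary_t):
        events.append(_make_event(x, y, t, params, site_id, "primary"))
        site_id += 1

    n_sites = pos_rng.poisson(params.cluster_rate * params.area_um2)
    parent_xy = _place_uniform(n_sites, params, pos_rng, mask)
    for px, py in parent_xy:
        k = _sample_cluster_size(params.cluster_size_dist, pos_rng)
        jitter = pos_rng.normal(0.0, params.cluster_sd_um, (k, 2))
        xy = np.clip(np.array([px, py]) + jitter,
                     [0, 0], [params.field_width_um, params.field_height_um])
        # sequential fusion: first granule at a uniform time, later granules
        # after exponential gaps; times beyond the recording are wrapped back
        # inside so every true event is observable
        t0 = time_rng.uniform(0, params.duration_s)
        gaps = time_rng.exponential(params.inter_fusion_interval_s, k - 1)
        times = np.minimum(t0 + np.concatenate([[0.0], np.cumsum(gaps)]),
                           params.duration_s - params.frame_interval_s * 1e-3)
        for (x, y), t in zip(xy, times):
            events.append(_make_event(x, y, t, params, site_id, "compound"))
        site_id += 1

    events.sort(key=lambda e: (e.t_s, e.x_um, e.y_um))
    n_compound = sum(e.site_kind == "compound" for e in events)
    frac = n_compound / len(events) if events else 0.0
    return SceneGroundTruth(events=events, params=params, true_compound_fraction=frac)


def _make_event(x: float, y: float, t: float, params: SceneParams,
                site_id: int, kind: str) -> FusionEvent:
    frame = int(np.ceil(t / params.frame_interval_s))
    frame = min(frame, params.n_frames - 1)
    return FusionEvent(x_um=float(x), y_um=float(y), t_s=float(t),
                       frame_index=frame, amplitude=params.event_amplitude,
                       size_um=None, site_id=site_id, site_kind=kind)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_scene(truth: SceneGroundTruth,
                 mask: Optional[np.ndarray] = None,
                 noise_rng: Optional[np.random.Generator] = None) -> ImagingScene:
    """Render the ground truth into a movie.

    Each event adds a Gaussian spot (sigma = ``event_radius_um``) from its
    first frame onward; overlapping spots add, so sequential fusions at one
    compound site produce a fluorescence staircase.  Spots are truncated at
    the field edge without wrap-around.
    """
    params = truth.params
    ny = int(round(params.field_height_um / params.pixel_size_um))
    nx = int(round(params.field_width_um / params.pixel_size_um))
    base = np.full((ny, nx), params.cell_interior_level, dtype=np.float64)
    if mask is not None:
        base[mask == 0] = params.background_level
    frames = np.repeat(base[None], params.n_frames, axis=0)

    px = params.pixel_size_um
    sigma_px = params.event_radius_um / px
    half = max(1, int(np.ceil(4 * sigma_px)))
    for ev in truth.events:
        cj, ci = ev.x_um / px, ev.y_um / px
        j0, j1 = max(0, int(np.floor(cj)) - half), min(nx, int(np.floor(cj)) + half + 1)
        i0, i1 = max(0, int(np.floor(ci)) - half), min(ny, int(np.floor(ci)) + half + 1)
        if j0 >= j1 or i0 >= i1:
            continue
        jj, ii = np.meshgrid(np.arange(j0, j1), np.arange(i0, i1))
        spot = ev.amplitude * np.exp(-((jj - cj) ** 2 + (ii - ci) ** 2) / (2 * sigma_px ** 2))
        k0 = ev.frame_index
        if params.decay_tau_s is None:
            frames[k0:, i0:i1, j0:j1] += spot
        else:
            dt = (np.arange(k0, params.n_frames) - k0) * params.frame_interval_s
            decay = np.exp(-dt / params.decay_tau_s)
            frames[k0:, i0:i1, j0:j1] += decay[:, None, None] * spot

    if params.noise_sd > 0:
        if noise_rng is None:
            noise_rng = _substreams(params.seed)["noise"]
        frames = frames + noise_rng.normal(0.0, params.noise_sd, frames.shape)
    frames = np.clip(frames, 0.0, None)
    return ImagingScene(frames=frames.astype(np.float32),
                        pixel_size_um=px,
                        frame_interval_s=params.frame_interval_s,
                        cell_mask=mask)


def generate_scene(params: SceneParams) -> tuple[ImagingScene, SceneGroundTruth]:
    """Generate one seeded synthetic SRB recording and its ground truth."""
    params.validate()
    rngs = _substreams(params.seed)
    mask = generate_cell_mask(params, rngs["cells"]) if params.with_cell_mask else None
    truth = sample_ground_truth(params, mask=mask)
    scene = render_scene(truth, mask=mask, noise_rng=rngs["noise"])
    return scene, truth


# ---------------------------------------------------------------------------
# GTT and calcium forward models
# ---------------------------------------------------------------------------

def generate_gtt_curve(fasting_mmol_l: float,
                       peak_mmol_l: float,
                       peak_time_min: float = 30.0,
                       duration_min: float = 120.0,
                       decay_rate: float = 0.02,
                       times_min: Optional[np.ndarray] = None,
                       noise_sd: float = 0.0,
                       seed: int = 0) -> GTTCurve:
    """Synthetic intraperitoneal-GTT glucose trace.

    Glucose rises linearly from fasting to ``peak_mmol_l`` at
    ``peak_time_min`` and then relaxes exponentially toward fasting at
    ``decay_rate`` (1/min).  A flat curve (peak == fasting) is allowed and
    useful as an AUC fixture.
    """
    if duration_min <= 0:
        raise ValueError("duration_min must be positive")
    if decay_rate < 0:
        raise ValueError("decay_rate must be non-negative")
    if peak_mmol_l < fasting_mmol_l:
        raise ValueError("peak must be >= fasting glucose")
    if peak_time_min > duration_min:
        raise ValueError("peak_time_min must not exceed duration_min")
    if times_min is None:
        times_min = np.array([0, 15, 30, 45, 60, 90, 120], dtype=float)
        times_min = times_min[times_min <= duration_min]
        if times_min[-1] < duration_min:
            times_min = np.append(times_min, duration_min)
    times_min = np.asarray(times_min, dtype=float)
    rise = peak_mmol_l - fasting_mmol_l
    glucose = np.where(
        times_min <= peak_time_min,
        fasting_mmol_l + rise * (times_min / peak_time_min if peak_time_min > 0 else 1.0),
        fasting_mmol_l + rise * np.exp(-decay_rate * (times_min - peak_time_min)),
    )
    if noise_sd > 0:
        glucose = glucose + np.random.default_rng(seed).normal(0, noise_sd, glucose.shape)
        glucose = np.clip(glucose, 0.1, None)
    return GTTCurve(times_min=times_min, glucose_mmol_l=glucose)


def concentration_to_ratio(concentration_nmol_l, cal: FuraCalibration):
    """Inverse of the ratiometric calibration: concentration -> Fura-2 ratio."""
    c = np.asarray(concentration_nmol_l, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    s = c / (cal.kd_nmol_l * cal.beta)
    return (cal.r_min + s * cal.r_max) / (1.0 + s)


def generate_calcium_trace(baseline_nmol_l: float,
                           peak_nmol_l: float,
                           stimulus_time_s: float,
                           cal: FuraCalibration,
                           duration_s: float = 600.0,
                           sample_interval_s: float = 2.0,
                           rise_tau_s: float = 20.0,
                           noise_sd_ratio: float = 0.0,
                           seed: int = 0) -> CalciumTrace:
    """Synthetic Fura-2 ratio trace from a known concentration profile.

    Concentration sits at baseline, then relaxes exponentially toward
    ``peak_nmol_l`` after the stimulus; it is pushed through the inverse
    calibration so that ``ratio_to_concentration`` round-trips exactly at
    zero noise.  Gaussian noise (``noise_sd_ratio``) is added in ratio units,
    where photon noise actually lives.
    """
    if baseline_nmol_l < 0 or peak_nmol_l < 0:
        raise ValueError("concentrations must be non-negative")
    if peak_nmol_l < baseline_nmol_l:
        raise ValueError("peak must be >= baseline")
    if stimulus_time_s < 0 or stimulus_time_s >= duration_s:
        raise ValueError("stimulus_time_s must lie inside the recording")
    times = np.arange(0.0, duration_s, sample_interval_s)
    conc = np.full_like(times, float(baseline_nmol_l))
    after = times >= stimulus_time_s
    conc[after] = peak_nmol_l + (baseline_nmol_l - peak_nmol_l) * np.exp(
        -(times[after] - stimulus_time_s) / rise_tau_s)
    ratio = concentration_to_ratio(conc, cal)
    if np.any(ratio >= cal.r_max) or np.any(ratio < cal.r_min):
        raise ValueError("requested concentrations fall outside the calibration range")
    if noise_sd_ratio > 0:
        ratio = ratio + np.random.default_rng(seed).normal(0, noise_sd_ratio, ratio.shape)
    return CalciumTrace(times_s=times, ratio=ratio)
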