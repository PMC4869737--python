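"""Fura-2 ratio traces to calcium concentration and response summaries.

The ratiometric (Grynkiewicz) calibration maps a background-corrected
excitation ratio R to free calcium:

    [Ca2+] = Kd * beta * (R - Rmin) / (Rmax - R)

with Kd the indicator dissociation constant, Rmin/Rmax the ratios at zero
and saturating calcium, and beta the free/bound fluorescence ratio at the
denominator wavelength.  Responses are summarised as the mean baseline
before the stimulus and the peak after it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .synthetic import CalciumTrace, FuraCalibration

__all__ = ["CalciumSummary", "ratio_to_concentration", "summarize_response"]


@dataclass
class CalciumSummary:
    baseline_nmol_l: float
    peak_nmol_l: float
    delta_nmol_l: float


def ratio_to_concentration(ratio, cal: FuraCalibration):
    """Convert Fura-2 ratio(s) to calcium concentration in nmol/l.

    Strictly increasing on [r_min, r_max); ratios at or above r_max (the pole
    of the calibration) or below r_min are out of range.
    """
    r = np.asarray(ratio, dtype=float)
    if np.any(r < cal.r_min) or np.any(r >= cal.r_max):
        raise ValueError("ratio outside the calibration range [r_min, r_max)")
    conc = cal.kd_nmol_l * cal.beta * (r - cal.r_min) / (cal.r_max - r)
    return float(conc) if np.isscalar(ratio) else conc


def summarize_response(trace: CalciumTrace,
                       cal: FuraCalibration,
                       stimulus_time_s: float,
                       baseline_window_s: float,
                       smooth_window: Optional[int] = None) -> CalciumSummary:
    """Baseline and stimulus-evoked peak calcium of one trace.

    Baseline is the mean converted concentration over the
    ``baseline_window_s`` seconds preceding the stimulus; the peak is the
    maximum converted sample at or after the stimulus (optionally after a
    centred moving-average pre-filter of ``smooth_window`` samples).
    """
    if stimulus_time_s < trace.times_s[0]:
        raise ValueError("stimulus precedes the first sample")
    if baseline_window_s <= 0:
        raise ValueError("baseline_window_s must be positive")
    conc = ratio_to_concentration(trace.ratio, cal)
    if smooth_window is not None and smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        conc = np.convolve(conc, kernel, mode="same")
    pre = (trace.times_s >= stimulus_time_s - baseline_window_s) & \
          (trace.times_s < stimulus_time_s)
    post = trace.times_s >= stimulus_time_s
    if not pre.any():
        raise ValueError("baseline window contains no samples before the stimulus")
    if not post.any():
        raise ValueError("no samples at or after the stimulus")
    baseline = float(conc[pre].mean())
    peak = float(conc[post].max())
    return CalciumSummary(baseline_nmol_l=baseline, peak_nmol_l=peak,
                          delta_nmol_l=peak - baseline)
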