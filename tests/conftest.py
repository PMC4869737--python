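import numpy as np
import pytest

from isletex import FuraCalibration, ImagingScene, SceneParams


@pytest.fixture
def default_cal() -> FuraCalibration:
    return FuraCalibration(r_min=0.5, r_max=5.0, beta=6.0, kd_nmol_l=224.0)


@pytest.fixture
def small_params() -> SceneParams:
    """A small, fast scene: 25x25 um, 60 frames, a handful of events."""
    return SceneParams(field_width_um=25.0, field_height_um=25.0,
                       n_frames=60, primary_rate=0.01, seed=7)


def make_staircase_scene(n_steps: int = 3,
                         offsets_um=None,
                         amplitude: float = 20.0,
                         noise_sd: float = 0.0) -> ImagingScene:
    """Movie with sequential amplitude steps at (nearly) one site: the
    fluorescence staircase of compound exocytosis."""
    px, sigma_um = 0.25, 0.5
    ny = nx = 80  # 20 x 20 um
    n_frames = 10 * n_steps
    frames = np.full((n_frames, ny, nx), 20.0)
    cx = cy = 10.0  # um
    xs = np.arange(nx) * px
    ys = np.arange(ny) * px
    gx, gy = np.meshgrid(xs, ys)
    if offsets_um is None:
        offsets_um = [(0.0, 0.0)] * n_steps
    for k in range(n_steps):
        dx, dy = offsets_um[k]
        spot = amplitude * np.exp(-((gx - cx - dx) ** 2 + (gy - cy - dy) ** 2)
                                  / (2 * sigma_um ** 2))
        frames[10 * (k + 1) - 5:] += spot
    if noise_sd > 0:
        frames += np.random.default_rng(0).normal(0, noise_sd, frames.shape)
    return ImagingScene(frames=np.clip(frames, 0, None),
                        pixel_size_um=px, frame_interval_s=5.0)
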