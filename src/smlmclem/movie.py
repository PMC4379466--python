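"""Forward model: ground-truth schedule -> EMCCD camera movie.

Each active emitter contributes a pixel-integrated Gaussian spot carrying its
in-frame photon count.  The camera chain is simplified to

    counts = Poisson(QE * (signal + background)) * em_gain
             + Normal(0, read_noise) + offset

i.e. Poisson shot noise, multiplicative EM gain, Gaussian read noise and a
baseline offset.  The full EM-register gamma cascade is omitted; downstream
estimators only need a realistic variance structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .camera import CameraModel, PSFModel, integrated_gaussian
from .switching import GroundTruthSchedule

__all__ = ["MovieStack", "render_movie"]

logger = logging.getLogger(__name__)


@dataclass
class MovieStack:
    """Frames x height x width raster of nonnegative camera counts."""

    data: np.ndarray
    camera: CameraModel

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ValueError("movie data must be (frames, H, W) with >= 1 frame")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def render_movie(
    schedule: GroundTruthSchedule,
    psf: PSFModel,
    camera: CameraModel,
    shape: tuple[int, int],
    background: float = 5.0,
    noise: bool = True,
    seed: int | None = None,
) -> MovieStack:
    """Render a camera movie from a ground-truth schedule.

    Parameters
    ----------
    schedule : GroundTruthSchedule
        Active emitters per frame with photon counts (from
        :func:`~smlmclem.switching.simulate_switching`).
    psf : PSFModel
        Gaussian PSF; its ``sigma_psf`` (nm) sets the spot width.
    camera : CameraModel
        Pixel size, gain, read noise, offset, quantum efficiency.
    shape : (int, int)
        Frame height and width in pixels.
    background : float or (n_frames,) array
        Background photons per pixel per frame (before quantum efficiency).
        A per-frame array models a photo-bleaching non-switching population
        in the dense limit where its many overlapping PSFs blur into a
        spatially uniform glow that decays over the acquisition.
    noise : bool
        With ``noise=False`` the stack is the deterministic expectation
        (no Poisson/read noise), useful for oracle tests.
    seed : int
        Random seed for the noise draws.
    """
    bg = np.asarray(background, dtype=float)
    if np.any(bg < 0):
        raise ValueError("background must be nonnegative")
    h, w = shape
    px = camera.pixel_size
    sigma_px = psf.sigma_psf / px
    n_frames = schedule.n_frames
    if bg.ndim == 0:
        expected = np.full((n_frames, h, w), float(bg))
    else:
        if bg.shape != (n_frames,):
            raise ValueError("per-frame background must have length n_frames")
        expected = np.tile(bg[:, None, None], (1, h, w))

    fov_x, fov_y = w * px, h * px
    n_clipped = 0
    for k, eid, x, y, ph in zip(
        schedule.frame, schedule.emitter_id, schedule.x, schedule.y, schedule.photons
    ):
        if not (0.0 <= x < fov_x and 0.0 <= y < fov_y):
            n_clipped += 1
        # render into a local window (+-5 sigma) for speed; the truncated
        # mass at that radius is < 1e-6 of the spot
        xp, yp = x / px, y / px
        r = int(np.ceil(5.0 * sigma_px)) + 1
        c0, c1 = max(0, int(xp) - r), min(w, int(xp) + r + 1)
        r0, r1 = max(0, int(yp) - r), min(h, int(yp) + r + 1)
        if c1 <= c0 or r1 <= r0:
            continue
        spot = integrated_gaussian(xp - c0, yp - r0, sigma_px, (r1 - r0, c1 - c0))
        expected[k, r0:r1, c0:c1] += ph * spot
    if n_clipped:
        logger.warning(
            "%d schedule entries fall outside the %dx%d px field; "
            "their contribution is clipped",
            n_clipped,
            h,
            w,
        )

    expected *= camera.quantum_efficiency
    if noise:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(expected).astype(float) * camera.em_gain
        counts += rng.normal(0.0, camera.read_noise, size=counts.shape)
        counts += camera.offset
        counts = np.clip(counts, 0.0, None)
    else:
        counts = expected * camera.em_gain + camera.offset
    return MovieStack(data=counts, camera=camera)
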