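"""Canonical simulated experiments used in validation and examples.

These functions fix complete study conditions (structure, kinetics, camera,
noise) so that downstream estimators can be exercised end to end with known
ground truth.
"""

from __future__ import annotations

import numpy as np

from .camera import CameraModel, PSFModel
from .localize import LocalizationTable, LocalizeSettings, localize_movie
from .movie import MovieStack, render_movie
from .structures import EmitterSet, generate_structure
from .switching import GroundTruthSchedule, SwitchingParams, simulate_switching

__all__ = ["bleaching_background_movie", "localize_for_nena"]


def bleaching_background_movie(
    seed: int,
    n_frames: int = 1000,
    field_nm: float = 3840.0,
    shape_px: tuple[int, int] = (48, 48),
    emitter_density_per_um2: float = 47.5,
    bg_floor: float = 2.0,
    bg_initial: float = 43.0,
    bg_bleach_rate: float = 0.06,
) -> tuple[MovieStack, GroundTruthSchedule, EmitterSet, PSFModel]:
    """Acquisition with a photo-bleaching non-switching background.

    Dense samples contain a population of fluorophores that never enters the
    dark state; its many overlapping PSFs form a near-uniform glow that
    photo-bleaches over the measurement, so localization accuracy improves
    from the start of the acquisition to its end.  This scenario renders a
    sparse switching population over a uniform background that decays
    exponentially at ``bg_bleach_rate`` (1/s) from ``bg_floor + bg_initial``
    to ``bg_floor`` photons/pixel/frame.

    Camera: EMCCD, 80 nm pixels, 50 ms integration at 17 fps, gain 30.
    Switching: ~60 ms on-times, 100-1000 photons per burst.

    Returns the movie, the ground-truth schedule, the emitter set, and the
    PSF model used.
    """
    camera = CameraModel(em_gain=30.0, read_noise=20.0)
    psf = PSFModel()
    fov = (field_nm, field_nm)
    emitters = generate_structure(
        "uniform", {"density_per_um2": emitter_density_per_um2}, fov, seed=seed
    )
    params = SwitchingParams(recovery_rate=0.18, bleach_prob=0.1)
    schedule = simulate_switching(emitters, params, n_frames, camera, seed=seed + 1)
    t_s = np.arange(n_frames) * camera.frame_period_ms / 1000.0
    background = bg_floor + bg_initial * np.exp(-bg_bleach_rate * t_s)
    movie = render_movie(
        schedule, psf, camera, shape_px, background=background, seed=seed + 2
    )
    return movie, schedule, emitters, psf


def localize_for_nena(movie: MovieStack, psf: PSFModel) -> LocalizationTable:
    """Localize a movie for adjacent-frame accuracy estimation.

    Burst merging is disabled: merging collapses the repeated localizations
    of one fluorophore in consecutive frames into a single record, which are
    exactly the pairs the nearest-neighbor accuracy estimator measures.
    """
    return localize_movie(movie, psf, LocalizeSettings(merge=False))
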