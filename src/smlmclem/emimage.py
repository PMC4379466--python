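"""Synthetic TEM-like images of a known ground-truth structure.

Produces a grayscale image in which the labelled structure appears as dark
ridges on a bright background (heavy-metal-stained membranes in bright-field
TEM), rendered in a coordinate system related to the SMLM frame by a known
similarity or affine transform.  This gives every registration and overlay
routine a fixture with exact ground truth.
"""

from __future__ import annotations

import numpy as np

from .camera import integrated_gaussian
from .register import Transform2D
from .structures import EmitterSet

__all__ = ["synthesize_em_image"]


def synthesize_em_image(
    emitters: EmitterSet,
    transform: Transform2D,
    size: tuple[int, int] = (256, 256),
    noise_level: float = 0.02,
    seed: int | None = None,
    ridge_sigma_px: float = 1.5,
    background_level: float = 0.85,
    contrast: float = 0.6,
) -> tuple[np.ndarray, Transform2D]:
    """Render an EM-like image of the ground-truth structure.

    Parameters
    ----------
    emitters : EmitterSet
        Ground truth in SMLM nm coordinates.
    transform : Transform2D
        Maps SMLM nm -> EM pixel coordinates (must be invertible; the
        :class:`Transform2D` constructor rejects singular matrices).
    size : (int, int)
        Output image height and width in px.
    noise_level : float
        Gaussian noise sd as a fraction of full scale; 0 gives a
        deterministic image.
    seed : int
        Seed for the noise draw.
    ridge_sigma_px : float
        Width of the dark ridge drawn around each structure point.
    background_level, contrast : float
        Bright background value and ridge depth, both in [0, 1] full scale.

    Returns
    -------
    (image, transform)
        Float image in [0, 1] and the true transform used (echoed back so
        pipelines can carry it alongside the image).
    """
    h, w = size
    density = np.zeros((h, w))
    if len(emitters):
        em_px = transform.apply(emitters.positions)
        r = int(np.ceil(5.0 * ridge_sigma_px)) + 1
        for x, y in em_px:
            c0, c1 = max(0, int(x) - r), min(w, int(x) + r + 1)
            r0, r1 = max(0, int(y) - r), min(h, int(y) + r + 1)
            if c1 <= c0 or r1 <= r0:
                continue
            density[r0:r1, c0:c1] += integrated_gaussian(
                x - c0, y - r0, ridge_sigma_px, (r1 - r0, c1 - c0)
            )
    if density.max() > 0:
        density = density / density.max()
    image = background_level - contrast * density
    if noise_level > 0:
        rng = np.random.default_rng(seed)
        image = image + rng.normal(0.0, noise_level, size=image.shape)
    return np.clip(image, 0.0, 1.0), transform
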