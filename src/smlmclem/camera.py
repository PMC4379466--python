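"""Camera and point-spread-function models.

The acquisition model is an EMCCD camera recording blinking fluorophores
through a high-NA oil objective.  The PSF is approximated by a 2D Gaussian
whose standard deviation is tied to the emission wavelength and numerical
aperture by ``sigma = 0.25 * wavelength / NA``, a common Gaussian fit to the
Airy profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf


@dataclass(frozen=True)
class CameraModel:
    """EMCCD acquisition parameters.

    Parameters
    ----------
    pixel_size : float
        Back-projected pixel size in the sample plane, nm.
    integration_time : float
        Exposure per frame, ms.
    frame_rate : float
        Frames per second; ``integration_time`` must fit in the frame period.
    em_gain : float
        Electron-multiplying gain (counts per photoelectron).
    read_noise : float
        Gaussian read noise, counts rms.
    offset : float
        Camera baseline, counts.
    quantum_efficiency : float
        Probability that an incident photon yields a photoelectron.
    """

    pixel_size: float = 80.0
    integration_time: float = 50.0
    frame_rate: float = 17.0
    em_gain: float = 1.0
    read_noise: float = 1.0
    offset: float = 100.0
    quantum_efficiency: float = 0.9

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.integration_time <= 0 or self.frame_rate <= 0:
            raise ValueError("integration_time and frame_rate must be positive")
        if self.frame_rate * self.integration_time > 1000.0 + 1e-9:
            raise ValueError(
                "integration_time exceeds the frame period (negative dead time)"
            )
        if not 0.0 <= self.quantum_efficiency <= 1.0:
            raise ValueError("quantum_efficiency must lie in [0, 1]")

    @property
    def frame_period_ms(self) -> float:
        return 1000.0 / self.frame_rate

    @property
    def dead_time_ms(self) -> float:
        return self.frame_period_ms - self.integration_time


@dataclass(frozen=True)
class PSFModel:
    """Gaussian approximation of the microscope point spread function.

    ``sigma_psf`` defaults to ``0.25 * wavelength / numerical_aperture`` (nm),
    the standard Gaussian-to-Airy matching for a well-corrected objective.
    """

    wavelength: float = 510.0
    numerical_aperture: float = 1.4
    sigma_psf: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.sigma_psf <= 0.0:
            object.__setattr__(
                self, "sigma_psf", 0.25 * self.wavelength / self.numerical_aperture
            )
        if self.sigma_psf <= 0:
            raise ValueError("sigma_psf must be positive")


def integrated_gaussian(
    x0: float, y0: float, sigma: float, shape: tuple[int, int]
) -> np.ndarray:
    """Pixel-integrated 2D Gaussian of unit total mass (over the infinite plane).

    Parameters are in pixel units; pixel ``(r, c)`` spans ``[c, c+1) x [r, r+1)``
    so a spot centred in pixel ``(r, c)`` has ``x0 = c + 0.5``, ``y0 = r + 0.5``.

    Returns an array of shape ``shape`` whose entry ``(r, c)`` is the Gaussian
    mass falling inside that pixel.
    """
    h, w = shape
    s = sigma * np.sqrt(2.0)
    xe = np.arange(w + 1.0)
    ye = np.arange(h + 1.0)
    fx = 0.5 * (erf((xe - x0) / s))
    fy = 0.5 * (erf((ye - y0) / s))
    gx = np.diff(fx)
    gy = np.diff(fy)
    return np.outer(gy, gx)
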