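"""Control-point registration between SMLM and EM coordinate systems.

Distinct features visible in both modalities are marked as paired control
points; a least-squares transform between the two coordinate systems is then
estimated.  A similarity ("linear conformal") transform — rotation, uniform
scale and translation — is sufficient when the section does not shrink during
EM acquisition; an affine transform (adding shear and anisotropic scale) can
absorb shrinkage.  The tool reports residuals for whichever model is requested
and never auto-selects between them.

Conventions: points are ``(x, y)`` rows; SMLM coordinates are in nm, EM
coordinates in pixels.  The fitted transform maps SMLM -> EM.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

__all__ = [
    "RegistrationError",
    "ControlPointSet",
    "Transform2D",
    "LineProfile",
    "estimate_transform",
    "apply_transform",
    "make_overlay",
    "line_profile",
]


class RegistrationError(ValueError):
    """Raised for degenerate control points or singular transforms."""


@dataclass
class ControlPointSet:
    """Paired coordinates: ``source`` (SMLM, nm) and ``target`` (EM, px)."""

    source: np.ndarray
    target: np.ndarray

    def __post_init__(self) -> None:
        self.source = np.asarray(self.source, dtype=float).reshape(-1, 2)
        self.target = np.asarray(self.target, dtype=float).reshape(-1, 2)
        if len(self.source) != len(self.target):
            raise RegistrationError("source and target must pair up one-to-one")

    def __len__(self) -> int:
        return len(self.source)


@dataclass
class Transform2D:
    """2D similarity or affine map ``p' = A p + t``.

    ``matrix`` is the 2x3 array ``[A | t]``.  For ``kind='similarity'`` the
    2x2 block is a scaled rotation (equal axis scaling, no shear).
    ``residual_rms`` is the root-mean-square control-point misfit in target
    units, when the transform was estimated from control points.
    """

    kind: str
    matrix: np.ndarray
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(2, 3)
        if abs(np.linalg.det(self.matrix[:, :2])) < 1e-12:
            raise RegistrationError("transform matrix is singular")

    @classmethod
    def identity(cls, kind: str = "similarity") -> "Transform2D":
        return cls(kind=kind, matrix=np.array([[1.0, 0, 0], [0, 1.0, 0]]))

    @classmethod
    def similarity(
        cls, scale: float, rotation_deg: float, translation: tuple[float, float]
    ) -> "Transform2D":
        th = np.deg2rad(rotation_deg)
        a = scale * np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        m = np.c_[a, np.asarray(translation, dtype=float)]
        return cls(kind="similarity", matrix=m)

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:, :2]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:, 2]

    @property
    def scale(self) -> float:
        """Uniform scale factor (sqrt of |det A|)."""
        return float(np.sqrt(abs(np.linalg.det(self.linear))))

    @property
    def rotation_deg(self) -> float:
        return float(np.rad2deg(np.arctan2(self.linear[1, 0], self.linear[0, 0])))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        return pts @ self.linear.T + self.translation

    def inverse(self) -> "Transform2D":
        a_inv = np.linalg.inv(self.linear)
        m = np.c_[a_inv, -a_inv @ self.translation]
        return Transform2D(kind=self.kind, matrix=m)

    # serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "coefficients": self.matrix.ravel().tolist(),
            "residual_rms": self.residual_rms,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Transform2D":
        return cls(
            kind=d["kind"],
            matrix=np.asarray(d["coefficients"], dtype=float).reshape(2, 3),
            residual_rms=float(d.get("residual_rms", 0.0)),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "Transform2D":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class LineProfile:
    """Intensity profile along a line segment.

    ``positions`` are distances along the segment (strictly increasing;
    units = pixel units times ``scale``); ``intensities`` are width-averaged
    samples; ``inverted`` records whether values were flipped (max - value),
    as done for TEM images whose structures are dark on bright.
    """

    positions: np.ndarray
    intensities: np.ndarray
    inverted: bool = False


def count_resolved_peaks(
    intensities: np.ndarray, min_prominence: float = 0.5
) -> int:
    """Number of resolved maxima in a profile, Rayleigh-style.

    Two nearby structures only count as resolved when the dip between their
    maxima drops below about half of the peak height; a shallow modulation is
    not a resolved feature.  Counts local maxima of the max-normalized
    profile with prominence >= ``min_prominence``; a profile with no such
    peak still has one (unresolved) maximum, so the count is at least 1 for
    any non-flat profile.
    """
    from scipy.signal import find_peaks

    prof = np.asarray(intensities, dtype=float)
    if prof.max() <= prof.min():
        return 0
    prof = prof / prof.max()
    peaks, _ = find_peaks(prof, prominence=min_prominence)
    return max(1, len(peaks))


def _collinear(points: np.ndarray, tol: float = 1e-9) -> bool:
    if len(points) < 3:
        return True
    c = points - points.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    return s[1] <= tol * max(s[0], 1.0)


def estimate_transform(
    points: ControlPointSet, kind: str = "similarity", allow_reflection: bool = False
) -> Transform2D:
    """Least-squares transform from paired control points.

    Similarity uses orthogonal Procrustes with isotropic scale; affine solves
    the normal equations.  ``residual_rms`` is the RMS misfit of the mapped
    source points against the targets.

    Raises
    ------
    RegistrationError
        Fewer than 2 pairs (similarity) or fewer than 3 non-collinear pairs
        (affine).
    """
    src, dst = points.source, points.target
    if kind == "similarity":
        if len(points) < 2:
            raise RegistrationError("similarity needs >= 2 control point pairs")
        mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
        sc, dc = src - mu_s, dst - mu_d
        var_s = (sc**2).sum() / len(src)
        if var_s <= 0:
            raise RegistrationError("control points are coincident")
        cov = dc.T @ sc / len(src)
        u, d, vt = np.linalg.svd(cov)
        s = np.ones(2)
        if not allow_reflection and np.linalg.det(u) * np.linalg.det(vt) < 0:
            s[-1] = -1.0
        rot = u @ np.diag(s) @ vt
        scale = float((d * s).sum() / var_s)
        if scale <= 0:
            raise RegistrationError("degenerate similarity fit (nonpositive scale)")
        a = scale * rot
        t = mu_d - a @ mu_s
    elif kind == "affine":
        if len(points) < 3 or _collinear(src):
            raise RegistrationError("affine needs >= 3 non-collinear control points")
        design = np.c_[src, np.ones(len(src))]
        coef, *_ = np.linalg.lstsq(design, dst, rcond=None)
        a = coef[:2].T
        t = coef[2]
    else:
        raise RegistrationError(f"unknown transform kind {kind!r}")
    tform = Transform2D(kind=kind, matrix=np.c_[a, t])
    resid = tform.apply(src) - dst
    tform.residual_rms = float(np.sqrt((resid**2).sum(axis=1).mean()))
    return tform


def apply_transform(
    target: np.ndarray,
    t: Transform2D,
    *,
    raster: bool = False,
    out_shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Apply a transform to points (forward map) or a raster (inverse resample).

    Points (default): each ``(x, y)`` row is mapped forward through ``t``.
    Raster (``raster=True``): the output grid, in target coordinates, is
    filled by inverse-mapping each output pixel into the input raster and
    bilinearly interpolating; pixels mapping outside the input are 0.
    Raster indices follow ``x = column, y = row``.
    """
    if not raster:
        return t.apply(target)
    img = np.asarray(target, dtype=float)
    out_shape = out_shape or img.shape[:2]
    inv = t.inverse()
    rows, cols = np.mgrid[0 : out_shape[0], 0 : out_shape[1]]
    pts = np.c_[cols.ravel(), rows.ravel()]  # (x, y) in target frame
    src = inv.apply(pts)
    coords = np.vstack([src[:, 1], src[:, 0]])  # (row, col) in input frame
    if img.ndim == 2:
        out = ndimage.map_coordinates(img, coords, order=1, cval=0.0)
        return out.reshape(out_shape)
    chans = [
        ndimage.map_coordinates(img[..., c], coords, order=1, cval=0.0).reshape(
            out_shape
        )
        for c in range(img.shape[2])
    ]
    return np.stack(chans, axis=-1)


def make_overlay(
    sr_color: np.ndarray,
    em: np.ndarray,
    t: Transform2D,
    alpha: float = 0.5,
    sr_pixel_nm: float = 5.0,
    sr_origin_nm: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Alpha-composite the super-resolution image onto the EM image.

    ``t`` maps SMLM nm coordinates to EM pixel coordinates; the SR raster is
    resampled into the EM frame through the inverse map.  Outside the SR
    support the EM image is shown unchanged.

    Returns an (H, W, 3) float RGB array in [0, 1].
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    em = np.asarray(em, dtype=float)
    if em.size == 0 or np.asarray(sr_color).size == 0:
        raise ValueError("rasters must be nonempty")
    lo, hi = em.min(), em.max()
    em_norm = (em - lo) / (hi - lo) if hi > lo else np.zeros_like(em)
    out = np.stack([em_norm] * 3, axis=-1)

    sr = np.asarray(sr_color, dtype=float)
    if sr.ndim == 2:
        sr = np.stack([sr] * 3, axis=-1)
    if sr.max() > 1.0:
        sr = sr / sr.max()

    h, w = em.shape[:2]
    rows, cols = np.mgrid[0:h, 0:w]
    em_pts = np.c_[cols.ravel(), rows.ravel()].astype(float)
    nm = t.inverse().apply(em_pts)
    sr_px = (nm - np.asarray(sr_origin_nm)) / sr_pixel_nm
    sh, sw = sr.shape[:2]
    inside = (
        (sr_px[:, 0] >= 0)
        & (sr_px[:, 0] <= sw - 1)
        & (sr_px[:, 1] >= 0)
        & (sr_px[:, 1] <= sh - 1)
    ).reshape(h, w)
    coords = np.vstack([sr_px[:, 1], sr_px[:, 0]])
    sr_resampled = np.stack(
        [
            ndimage.map_coordinates(sr[..., c], coords, order=1, cval=0.0).reshape(h, w)
            for c in range(3)
        ],
        axis=-1,
    )
    mask = inside[..., None]
    out = np.where(mask, (1.0 - alpha) * out + alpha * sr_resampled, out)
    return np.clip(out, 0.0, 1.0)


def line_profile(
    image: np.ndarray,
    p0: tuple[float, float],
    p1: tuple[float, float],
    width: int = 1,
    invert: bool = False,
    n_samples: int | None = None,
    scale: float = 1.0,
) -> LineProfile:
    """Width-averaged intensity profile along a segment.

    Parameters
    ----------
    image : 2D array
        Raster to sample; endpoint coordinates are ``(x, y)`` pixel indices.
    p0, p1 : (float, float)
        Distinct endpoints inside the raster.
    width : int
        Number of perpendicular samples (1 px spacing) averaged per position.
    invert : bool
        Report ``max - value``; used for TEM where structures are dark.
    n_samples : int
        Number of positions along the segment (default: ~1 per pixel).
    scale : float
        Physical units per pixel for the reported positions (e.g. nm/px).
    """
    img = np.asarray(image, dtype=float)
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    if np.allclose(p0, p1):
        raise ValueError("endpoints must be distinct")
    h, w = img.shape
    for p in (p0, p1):
        if not (0 <= p[0] <= w - 1 and 0 <= p[1] <= h - 1):
            raise ValueError(f"endpoint {tuple(p)} outside the raster")
    length = float(np.linalg.norm(p1 - p0))
    n = n_samples or max(2, int(np.ceil(length)) + 1)
    ts = np.linspace(0.0, 1.0, n)
    along = p0[None, :] + ts[:, None] * (p1 - p0)[None, :]
    perp = np.array([-(p1 - p0)[1], (p1 - p0)[0]]) / length
    offsets = (np.arange(width) - (width - 1) / 2.0)[:, None] * perp[None, :]
    # (width, n, 2) sample positions in (x, y)
    pts = along[None, :, :] + offsets[:, None, :]
    coords = np.vstack([pts[..., 1].ravel(), pts[..., 0].ravel()])
    vals = ndimage.map_coordinates(img, coords, order=1, mode="nearest")
    vals = vals.reshape(width, n).mean(axis=0)
    if invert:
        vals = vals.max() - vals
    return LineProfile(positions=ts * length * scale, intensities=vals, inverted=invert)
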