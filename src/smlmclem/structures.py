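"""Ground-truth emitter structures.

Generates point sets that emulate fluorophore-decorated cellular structures:
pairs of parallel membranes, single membrane profiles, vesicle-like rings,
nuclear clusters, and uniform fields.  Coordinates are continuous, in nm,
x rightward and y downward, with the field of view anchored at the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["EmitterSet", "StructureError", "generate_structure", "STRUCTURE_KINDS"]


class StructureError(ValueError):
    """Raised for unknown structure kinds or invalid geometry parameters."""


@dataclass
class EmitterSet:
    """Ground-truth fluorophore coordinates on a parametrised structure.

    Attributes
    ----------
    positions : (n, 2) ndarray
        Emitter coordinates (x, y) in nm.
    structure_kind : str
        One of ``STRUCTURE_KINDS``.
    structure_params : dict
        The geometry parameters used for generation.
    field_of_view : (float, float)
        Extent of the field in nm, x then y.
    """

    positions: np.ndarray
    structure_kind: str
    structure_params: dict[str, Any] = field(default_factory=dict)
    field_of_view: tuple[float, float] = (5000.0, 5000.0)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        if not np.all(np.isfinite(self.positions)):
            raise StructureError("emitter coordinates must be finite")

    def __len__(self) -> int:
        return len(self.positions)


STRUCTURE_KINDS = ("membrane_pair", "line", "ring", "nuclear_blobs", "uniform")


def _segment_points(
    p0: np.ndarray, p1: np.ndarray, linear_density: float, rng: np.random.Generator
) -> np.ndarray:
    """Poisson point process on a segment, ``linear_density`` per nm."""
    length = float(np.linalg.norm(p1 - p0))
    n = rng.poisson(linear_density * length)
    t = rng.uniform(0.0, 1.0, size=n)
    return p0[None, :] + t[:, None] * (p1 - p0)[None, :]


def generate_structure(
    kind: str,
    params: dict[str, Any] | None = None,
    field_of_view: tuple[float, float] = (5000.0, 5000.0),
    seed: int | None = None,
) -> EmitterSet:
    """Generate a ground-truth :class:`EmitterSet`.

    Parameters
    ----------
    kind : str
        Structure label, one of ``STRUCTURE_KINDS``.
    params : dict
        Geometry parameters.  Common keys:

        ``uniform``
            ``density_per_um2`` (points/um^2).
        ``line``
            ``length`` (nm), ``density_per_um`` (points/um along the line),
            optional ``angle_deg`` and ``center``.
        ``membrane_pair``
            as ``line``, plus ``spacing`` (nm) between the two parallel lines.
        ``ring``
            ``radius`` (nm), ``density_per_um``, optional ``center``.
        ``nuclear_blobs``
            ``n_blobs``, ``blob_sigma`` (nm), ``emitters_per_blob``.
    field_of_view : (float, float)
        Field extent in nm.
    seed : int
        Seed for the pseudo-random generator; identical seeds give identical
        point sets.

    Raises
    ------
    StructureError
        For unrecognised kinds or a degenerate field of view.
    """
    params = dict(params or {})
    fov = (float(field_of_view[0]), float(field_of_view[1]))
    if fov[0] <= 0 or fov[1] <= 0:
        raise StructureError("field_of_view must have positive extent")
    if kind not in STRUCTURE_KINDS:
        raise StructureError(
            f"unknown structure kind {kind!r}; expected one of {STRUCTURE_KINDS}"
        )
    rng = np.random.default_rng(seed)
    cx, cy = params.get("center", (fov[0] / 2.0, fov[1] / 2.0))
    center = np.array([cx, cy], dtype=float)

    if kind == "uniform":
        rho = float(params.get("density_per_um2", 100.0))
        if rho < 0:
            raise StructureError("density_per_um2 must be nonnegative")
        area_um2 = fov[0] * fov[1] * 1e-6
        n = rng.poisson(rho * area_um2)
        pts = rng.uniform([0.0, 0.0], [fov[0], fov[1]], size=(n, 2))
    elif kind in ("line", "membrane_pair"):
        length = float(params.get("length", 0.8 * min(fov)))
        lam = float(params.get("density_per_um", 100.0)) * 1e-3  # per nm
        if length <= 0 or lam < 0:
            raise StructureError("length must be positive, density nonnegative")
        angle = np.deg2rad(float(params.get("angle_deg", 0.0)))
        u = np.array([np.cos(angle), np.sin(angle)])  # along the line
        v = np.array([-np.sin(angle), np.cos(angle)])  # perpendicular
        if kind == "line":
            p0 = center - 0.5 * length * u
            pts = _segment_points(p0, p0 + length * u, lam, rng)
        else:
            spacing = float(params.get("spacing", 300.0))
            if spacing <= 0:
                raise StructureError("spacing must be positive")
            half = 0.5 * spacing * v
            a0 = center - 0.5 * length * u - half
            b0 = center - 0.5 * length * u + half
            pts_a = _segment_points(a0, a0 + length * u, lam, rng)
            pts_b = _segment_points(b0, b0 + length * u, lam, rng)
            pts = np.vstack([pts_a, pts_b])
    elif kind == "ring":
        radius = float(params.get("radius", 0.2 * min(fov)))
        lam = float(params.get("density_per_um", 100.0)) * 1e-3
        if radius <= 0 or lam < 0:
            raise StructureError("radius must be positive, density nonnegative")
        circumference = 2.0 * np.pi * radius
        n = rng.poisson(lam * circumference)
        theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
        pts = center[None, :] + radius * np.c_[np.cos(theta), np.sin(theta)]
    else:  # nuclear_blobs
        n_blobs = int(params.get("n_blobs", 10))
        blob_sigma = float(params.get("blob_sigma", 80.0))
        per_blob = float(params.get("emitters_per_blob", 50.0))
        if n_blobs < 0 or blob_sigma <= 0 or per_blob < 0:
            raise StructureError("invalid nuclear_blobs parameters")
        margin = 3.0 * blob_sigma
        lo = np.minimum([margin, margin], [fov[0] / 2, fov[1] / 2])
        centers = rng.uniform(lo, [fov[0] - lo[0], fov[1] - lo[1]], size=(n_blobs, 2))
        chunks = []
        for c in centers:
            n = rng.poisson(per_blob)
            chunks.append(c[None, :] + rng.normal(0.0, blob_sigma, size=(n, 2)))
        pts = np.vstack(chunks) if chunks else np.empty((0, 2))

    # keep points inside the declared field of view
    if len(pts):
        inside = (
            (pts[:, 0] >= 0)
            & (pts[:, 0] <= fov[0])
            & (pts[:, 1] >= 0)
            & (pts[:, 1] <= fov[1])
        )
        pts = pts[inside]
    return EmitterSet(
        positions=pts, structure_kind=kind, structure_params=params, field_of_view=fov
    )
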