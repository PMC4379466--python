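"""Local density, Nyquist-limited and structural resolution.

SMLM image resolution is limited by two independent quantities: the
localization accuracy ``sigma`` of individual molecule positions, and the
density ``rho`` of detected positions, which bounds the finest structure that
is adequately sampled (Nyquist).  Both are combined in quadrature into the
structural resolution

    R = sqrt((2.35 sigma)^2 + R_N^2),     R_N = 2 / rho^(1/D),  D = 2.

The local density at each detected position is obtained from the mean
distance to its K nearest neighbors (K = 20 by default).  For a uniform
Poisson process of intensity ``rho`` the expected K-NN mean distance is
``c_K / sqrt(rho)`` with the circular-symmetry normalization factor

    c_K = (1 / (K sqrt(pi))) * sum_{k=1..K} Gamma(k + 1/2) / Gamma(k),

so ``rho = (c_K / mean_dist)^2`` is unbiased for uniform patterns; c_1 = 1/2
recovers the classic nearest-neighbor expectation 1 / (2 sqrt(rho)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import gammaln

from .localize import LocalizationTable

__all__ = [
    "DensityParams",
    "DensityResolutionResult",
    "knn_mean_distance",
    "norm_factor",
    "local_density",
    "nyquist_resolution",
    "structural_resolution",
    "molecules_per_dl_area",
    "compute_density_resolution",
]

logger = logging.getLogger(__name__)

NM2_PER_UM2 = 1e6


def norm_factor(K: int = 20) -> float:
    """Circular-symmetry normalization factor ``c_K``.

    ``c_K / sqrt(rho)`` is the expected mean distance to the K nearest
    neighbors in a uniform Poisson process of intensity ``rho``; the factor
    corrects for the fact that K neighbors cannot all sit at the single-NN
    distance (they cannot be arranged in circular symmetry).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    k = np.arange(1, K + 1)
    terms = np.exp(gammaln(k + 0.5) - gammaln(k))
    return float(terms.sum() / (K * np.sqrt(np.pi)))


@dataclass(frozen=True)
class DensityParams:
    """K-nearest-neighbor density estimation parameters (2D)."""

    K: int = 20
    dimension: int = 2
    c_K: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.dimension != 2:
            raise ValueError("only 2D supported")
        expected = norm_factor(self.K)
        if self.c_K == 0.0:
            object.__setattr__(self, "c_K", expected)
        elif abs(self.c_K - expected) > 1e-9:
            raise ValueError(
                f"c_K={self.c_K} does not match the analytic value {expected} for K={self.K}"
            )


@dataclass
class DensityResolutionResult:
    """Per-localization density/resolution fields plus summary statistics.

    Arrays are aligned with the input table rows.  ``border_flag`` marks
    points whose K-th neighbor lies further than the point's distance to the
    field border (their density is biased low); flagged points and exact
    duplicates are excluded from the summary.
    """

    mean_knn_nm: np.ndarray
    rho_per_um2: np.ndarray
    nyquist_nm: np.ndarray
    structural_nm: np.ndarray
    sigma_loc_nm: float
    border_flag: np.ndarray
    params: DensityParams
    summary: dict[str, float] = field(default_factory=dict)


def knn_mean_distance(points: np.ndarray, K: int = 20) -> np.ndarray:
    """Mean distance from each point to its K nearest other points.

    Exact kd-tree neighbor search; requires more than K points.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) <= K:
        raise ValueError(f"need more than K={K} points, got {len(pts)}")
    d, _ = cKDTree(pts).query(pts, k=K + 1)
    return d[:, 1:].mean(axis=1)


def local_density(
    mean_dist_nm: np.ndarray, params: DensityParams | None = None
) -> np.ndarray:
    """Local density (points/um^2) from the K-NN mean distance (nm).

    ``rho = (c_K / mean_dist)^2``.  Exact duplicates give a zero mean
    distance; those entries are returned as NaN with a warning rather than
    jittered.
    """
    params = params or DensityParams()
    d = np.asarray(mean_dist_nm, dtype=float)
    out = np.full(d.shape, np.nan)
    ok = d > 0
    if np.any(~ok):
        logger.warning(
            "%d positions with zero neighbor distance (duplicates) excluded "
            "from density",
            int((~ok).sum()),
        )
    out[ok] = (params.c_K / d[ok]) ** 2 * NM2_PER_UM2
    return out


def nyquist_resolution(rho_per_um2: np.ndarray | float) -> np.ndarray | float:
    """Nyquist-limited resolution (nm): twice the mean sampling interval.

    ``R_N = 2 / sqrt(rho)`` with ``rho`` in nm^-2 (D = 2 dimensions).
    """
    rho_nm2 = np.asarray(rho_per_um2, dtype=float) / NM2_PER_UM2
    out = 2.0 / np.sqrt(rho_nm2)
    return float(out) if out.ndim == 0 else out


def structural_resolution(
    sigma_loc_nm: float, nyquist_nm: np.ndarray | float
) -> np.ndarray | float:
    """Structural resolution: quadrature of localization FWHM and Nyquist term.

    ``R = sqrt((2.35 sigma)^2 + R_N^2)``; reduces to ``R_N`` for perfect
    localization and to ``2.35 sigma`` for infinitely dense labeling.
    """
    if sigma_loc_nm < 0:
        raise ValueError("sigma_loc must be nonnegative")
    r_n = np.asarray(nyquist_nm, dtype=float)
    out = np.sqrt((2.35 * sigma_loc_nm) ** 2 + r_n**2)
    return float(out) if out.ndim == 0 else out


def molecules_per_dl_area(rho_per_um2: float, dl_diameter_nm: float = 250.0) -> float:
    """Molecule count inside one diffraction-limited area.

    The diffraction-limited area is a circle of the given diameter (250 nm,
    a conventional lateral resolution limit for high-NA visible-light
    imaging); e.g. 22,000 molecules/um^2 -> ~1,080 (> 1,000).
    """
    if dl_diameter_nm <= 0:
        raise ValueError("dl_diameter must be positive")
    area_um2 = np.pi * (dl_diameter_nm / 2.0) ** 2 / NM2_PER_UM2
    return float(rho_per_um2 * area_um2)


def compute_density_resolution(
    table: LocalizationTable | np.ndarray,
    sigma_loc_nm: float,
    params: DensityParams | None = None,
    field_of_view: tuple[float, float] | None = None,
) -> DensityResolutionResult:
    """Full per-localization density and resolution analysis.

    Parameters
    ----------
    table : LocalizationTable or (n, 2) array
        Detected positions in nm.
    sigma_loc_nm : float
        Localization accuracy (e.g. from the adjacent-frame NeNA estimator).
    params : DensityParams
        K and the normalization factor.
    field_of_view : (float, float), optional
        Field extent in nm for border correction; defaults to the bounding
        box of the points.

    Border handling: a point whose K-th neighbor distance exceeds its
    distance to the nearest field border has part of its neighborhood
    outside the field; it is flagged and excluded from the summary.
    """
    params = params or DensityParams()
    pts = table.xy if isinstance(table, LocalizationTable) else np.asarray(table)
    pts = pts.reshape(-1, 2).astype(float)
    d_all, _ = cKDTree(pts).query(pts, k=params.K + 1)
    mean_knn = d_all[:, 1:].mean(axis=1)
    kth = d_all[:, -1]

    if field_of_view is None:
        x0, y0 = pts.min(axis=0)
        x1, y1 = pts.max(axis=0)
    else:
        x0 = y0 = 0.0
        x1, y1 = field_of_view
    border_dist = np.minimum.reduce(
        [pts[:, 0] - x0, x1 - pts[:, 0], pts[:, 1] - y0, y1 - pts[:, 1]]
    )
    border_flag = kth > border_dist

    rho = local_density(mean_knn, params)
    nyq = nyquist_resolution(rho)
    struct = structural_resolution(sigma_loc_nm, nyq)

    ok = ~border_flag & np.isfinite(rho)
    summary = {}
    if np.any(ok):
        # population density from the pooled mean distance: averaging the
        # per-point (c_K/d)^2 values first would be biased upward by the
        # sampling noise of d (Jensen), so the pooled estimate is reported
        pooled_rho = (params.c_K / mean_knn[ok].mean()) ** 2 * NM2_PER_UM2
        summary = {
            "n_points": int(len(pts)),
            "n_interior": int(ok.sum()),
            "mean_knn_nm": float(mean_knn[ok].mean()),
            "mean_rho_per_um2": float(pooled_rho),
            "mean_pointwise_rho_per_um2": float(rho[ok].mean()),
            "median_rho_per_um2": float(np.median(rho[ok])),
            "mean_nyquist_nm": float(nyq[ok].mean()),
            "median_nyquist_nm": float(np.median(nyq[ok])),
            "mean_structural_nm": float(struct[ok].mean()),
            "median_structural_nm": float(np.median(struct[ok])),
            "p90_rho_per_um2": float(np.percentile(rho[ok], 90)),
            "sigma_loc_nm": float(sigma_loc_nm),
        }
    return DensityResolutionResult(
        mean_knn_nm=mean_knn,
        rho_per_um2=rho,
        nyquist_nm=nyq,
        structural_nm=struct,
        sigma_loc_nm=float(sigma_loc_nm),
        border_flag=border_flag,
        params=params,
        summary=summary,
    )
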