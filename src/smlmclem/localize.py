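"""Single-molecule detection and localization.

The chain mirrors standard SMLM processing: a sliding-window temporal-median
background estimate is subtracted, candidate spots are detected as local
maxima above a robust noise threshold, each candidate is fit by maximizing
the Poisson likelihood of a pixel-integrated 2D Gaussian plus flat
background, failed fits are filtered, and localizations appearing in
consecutive frames within a merge radius are combined into single records
(one fluorophore burst often spans ~2 frames when the on-time exceeds the
integration time).

The likelihood model for a region of interest (ROI) with photo-electron
counts ``k_i`` is

    mu_i = N * G_i(x0, y0, sigma) + b,      k_i ~ Poisson(mu_i)

with ``G_i`` the integral of a unit 2D Gaussian over pixel ``i``.  The fit
maximizes ``sum_i (k_i log mu_i - mu_i)`` over ``(x0, y0, N, b, sigma)``
with an analytic gradient; ``sigma`` is free within ``[0.5, 2] x sigma_psf``
to absorb section-induced aberrations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import optimize

from .camera import CameraModel, PSFModel, integrated_gaussian
from .movie import MovieStack

__all__ = [
    "Localization",
    "LocalizationTable",
    "LocalizeSettings",
    "FitResult",
    "subtract_background",
    "robust_sigma",
    "detect_candidates",
    "fit_spot_mle",
    "localize_movie",
    "merge_consecutive",
    "filter_localizations",
]

logger = logging.getLogger(__name__)

TABLE_COLUMNS = [
    "frame",
    "x_nm",
    "y_nm",
    "photons",
    "background",
    "fit_sigma_nm",
    "log_likelihood",
    "n_merged",
]


@dataclass
class Localization:
    """One detected single-molecule position."""

    frame: int
    x_nm: float
    y_nm: float
    photons: float
    background: float
    fit_sigma_nm: float
    log_likelihood: float = 0.0
    n_merged: int = 1


@dataclass
class LocalizationTable:
    """Ordered localization records plus acquisition metadata.

    ``df`` is a pandas DataFrame with at least the columns in
    ``TABLE_COLUMNS`` (extra columns such as ``emitter_id`` are preserved);
    ``metadata`` carries ``pixel_size_nm``, ``frame_time_ms`` and a source id.
    """

    df: Any
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        import pandas as pd

        if not isinstance(self.df, pd.DataFrame):
            self.df = pd.DataFrame(self.df, columns=TABLE_COLUMNS)
        missing = [c for c in TABLE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"missing column {missing[0]}")
        self.df = self.df.sort_values("frame", kind="stable").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def xy(self) -> np.ndarray:
        return self.df[["x_nm", "y_nm"]].to_numpy(dtype=float)

    @classmethod
    def from_records(
        cls, records: list[Localization], metadata: dict[str, Any] | None = None
    ) -> "LocalizationTable":
        import pandas as pd

        df = pd.DataFrame(
            [
                (
                    r.frame,
                    r.x_nm,
                    r.y_nm,
                    r.photons,
                    r.background,
                    r.fit_sigma_nm,
                    r.log_likelihood,
                    r.n_merged,
                )
                for r in records
            ],
            columns=TABLE_COLUMNS,
        )
        return cls(df=df, metadata=dict(metadata or {}))


# ---------------------------------------------------------------------------
# background subtraction


def subtract_background(movie: MovieStack, half_window: int = 10) -> MovieStack:
    """Sliding-window temporal-median background subtraction.

    For every pixel and frame ``t`` the median over frames
    ``[t - half_window, t + half_window]`` (truncated at the movie edges) is
    subtracted.  The median is robust to sparse bursts a few frames long, so
    single-molecule signal survives while slowly varying background — the
    non-switching, photo-bleaching population in dense samples — is removed.
    Residuals are returned signed; clamp at zero for detection.
    """
    if half_window < 1:
        raise ValueError("half_window must be >= 1")
    data = movie.data
    n = data.shape[0]
    if n <= 2 * half_window:
        raise ValueError(
            f"movie has {n} frames; needs more than {2 * half_window} for the window"
        )
    out = np.empty_like(data)
    for t in range(n):
        lo, hi = max(0, t - half_window), min(n, t + half_window + 1)
        out[t] = data[t] - np.median(data[lo:hi], axis=0)
    return MovieStack(data=out, camera=movie.camera)


def robust_sigma(frame: np.ndarray) -> float:
    """1.4826 x median absolute deviation: noise sd robust to sparse spots."""
    med = np.median(frame)
    return float(1.4826 * np.median(np.abs(frame - med)))


# ---------------------------------------------------------------------------
# candidate detection


def detect_candidates(
    residual_frame: np.ndarray,
    threshold_factor: float = 4.0,
    match_sigma_px: float = 0.0,
) -> list[tuple[int, int]]:
    """Local maxima above ``threshold_factor`` x robust noise sd.

    Negative residuals are clamped to zero first.  With ``match_sigma_px``
    > 0 the frame is first convolved with a Gaussian of that width (matched
    filter), which suppresses single-pixel shot-noise spikes — important for
    EMCCD data whose Poisson-times-gain noise is heavier-tailed than
    Gaussian — while preserving PSF-sized spots.  Candidate pixels are 3x3
    local maxima; survivors are greedily selected in order of decreasing
    intensity (ties: smaller row, then column) with a minimum mutual
    separation of 2 px.
    """
    if threshold_factor <= 0:
        raise ValueError("threshold_factor must be positive")
    signed = np.asarray(residual_frame, dtype=float)
    if match_sigma_px > 0:
        from scipy.ndimage import gaussian_filter

        signed = gaussian_filter(signed, match_sigma_px)
    noise = robust_sigma(signed)
    if noise <= 0:
        noise = max(signed.std(), 1e-12)
    thr = float(np.median(signed)) + threshold_factor * noise
    frame = np.clip(signed, 0.0, None)
    from scipy.ndimage import maximum_filter

    is_max = (frame >= maximum_filter(frame, size=3)) & (signed > thr) & (frame > 0)
    rows, cols = np.nonzero(is_max)
    if len(rows) == 0:
        return []
    vals = frame[rows, cols]
    order = np.lexsort((cols, rows, -vals))
    kept: list[tuple[int, int]] = []
    kept_arr = np.empty((0, 2))
    for idx in order:
        p = np.array([rows[idx], cols[idx]], dtype=float)
        if len(kept) and np.min(np.linalg.norm(kept_arr - p, axis=1)) < 2.0:
            continue
        kept.append((int(rows[idx]), int(cols[idx])))
        kept_arr = np.vstack([kept_arr, p])
    return kept


# ---------------------------------------------------------------------------
# maximum-likelihood fitting


@dataclass
class FitResult:
    """Outcome of a single-spot MLE fit, in ROI pixel units."""

    success: bool
    x0: float = np.nan
    y0: float = np.nan
    photons: float = np.nan
    background: float = np.nan
    sigma: float = np.nan
    log_likelihood: float = np.nan
    message: str = ""


def _nll_and_grad(
    theta: np.ndarray, counts: np.ndarray, shape: tuple[int, int]
) -> tuple[float, np.ndarray]:
    x0, y0, nphot, b, sigma = theta
    h, w = shape
    s = sigma * np.sqrt(2.0)
    xe = np.arange(w + 1.0)
    ye = np.arange(h + 1.0)
    ux = (xe - x0) / s
    uy = (ye - y0) / s
    from scipy.special import erf

    gx = 0.5 * np.diff(erf(ux))
    gy = 0.5 * np.diff(erf(uy))
    phix = np.exp(-(ux**2)) / np.sqrt(np.pi)
    phiy = np.exp(-(uy**2)) / np.sqrt(np.pi)
    dgx_dx0 = (phix[:-1] - phix[1:]) / s
    dgy_dy0 = (phiy[:-1] - phiy[1:]) / s
    dgx_ds = (ux[:-1] * phix[:-1] - ux[1:] * phix[1:]) / sigma
    dgy_ds = (uy[:-1] * phiy[:-1] - uy[1:] * phiy[1:]) / sigma

    g = np.outer(gy, gx)
    mu = nphot * g + b
    mu = np.clip(mu, 1e-12, None)
    nll = float(np.sum(mu - counts * np.log(mu)))
    resid = 1.0 - counts / mu  # d nll / d mu
    d_x0 = nphot * np.outer(gy, dgx_dx0)
    d_y0 = nphot * np.outer(dgy_dy0, gx)
    d_sig = nphot * (np.outer(gy, dgx_ds) + np.outer(dgy_ds, gx))
    grad = np.array(
        [
            np.sum(resid * d_x0),
            np.sum(resid * d_y0),
            np.sum(resid * g),
            np.sum(resid),
            np.sum(resid * d_sig),
        ]
    )
    return nll, grad


def fit_spot_mle(
    roi: np.ndarray,
    psf: PSFModel,
    camera: CameraModel,
    sigma_bounds: tuple[float, float] = (0.5, 2.0),
) -> FitResult:
    """Poisson MLE fit of one spot in an ROI of photo-electron counts.

    The ROI must be odd-sized (default workflow: 7x7) with nonnegative
    counts; coordinates in the result are ROI pixel units with pixel (0, 0)
    spanning ``[0, 1)`` on each axis.  A degenerate (flat) ROI or a fit that
    fails to converge returns ``success=False`` rather than raising.
    ``sigma_bounds`` are multiples of the nominal PSF sigma.
    """
    roi = np.asarray(roi, dtype=float)
    if roi.ndim != 2 or roi.shape[0] % 2 == 0 or roi.shape[1] % 2 == 0:
        raise ValueError("ROI must be 2D and odd-sized")
    if np.any(roi < 0):
        roi = np.clip(roi, 0.0, None)
    if np.ptp(roi) == 0:
        return FitResult(success=False, message="degenerate ROI (flat counts)")
    h, w = roi.shape
    sigma_px = psf.sigma_psf / camera.pixel_size

    b0 = max(float(np.median([roi[0, :].mean(), roi[-1, :].mean(), roi.min()])), 0.0)
    n0 = max(float(roi.sum() - b0 * roi.size), 10.0)
    # moment-based centroid of background-subtracted counts for the start point
    sub = np.clip(roi - b0, 0.0, None)
    tot = sub.sum()
    ys, xs = np.mgrid[0:h, 0:w]
    x_init = float((sub * (xs + 0.5)).sum() / tot) if tot > 0 else w / 2.0
    y_init = float((sub * (ys + 0.5)).sum() / tot) if tot > 0 else h / 2.0

    theta0 = np.array([x_init, y_init, n0, b0 + 0.1, sigma_px])
    bounds = [
        (0.0, float(w)),
        (0.0, float(h)),
        (1e-3, None),
        (1e-6, None),
        (sigma_bounds[0] * sigma_px, sigma_bounds[1] * sigma_px),
    ]
    res = optimize.minimize(
        _nll_and_grad,
        theta0,
        args=(roi, roi.shape),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-9},
    )
    x0, y0, nphot, b, sigma = res.x
    ok = bool(res.success) and np.isfinite(res.fun)
    # log-likelihood up to the data-only term sum(log k!)
    return FitResult(
        success=ok,
        x0=float(x0),
        y0=float(y0),
        photons=float(nphot),
        background=float(b),
        sigma=float(sigma),
        log_likelihood=float(-res.fun),
        message=str(res.message),
    )


# ---------------------------------------------------------------------------
# movie-level pipeline


@dataclass(frozen=True)
class LocalizeSettings:
    """Parameters of the movie localization chain."""

    half_window: int = 10
    threshold_factor: float = 4.0
    roi_size: int = 7
    merge_radius_nm: float = 50.0
    merge: bool = True
    min_photons: float = 100.0  # applied after merging; detected range starts at 100
    matched_filter: bool = True  # Gaussian-smooth residuals before detection


def _roi_bounds(peak: tuple[int, int], half: int, shape: tuple[int, int]):
    r, c = peak
    h, w = shape
    if r - half < 0 or c - half < 0 or r + half >= h or c + half >= w:
        return None
    return r - half, r + half + 1, c - half, c + half + 1


def localize_movie(
    movie: MovieStack,
    psf: PSFModel | None = None,
    settings: LocalizeSettings | None = None,
) -> LocalizationTable:
    """Run the full localization chain on a movie.

    Background-subtract, detect candidates per frame, fit each candidate by
    Poisson MLE on the raw (gain/offset-corrected) ROI, drop failed fits,
    and merge consecutive-frame localizations within the merge radius.
    Per-spot fit failures are logged, never fatal.
    """
    psf = psf or PSFModel()
    settings = settings or LocalizeSettings()
    camera = movie.camera
    half = settings.roi_size // 2
    residual = subtract_background(movie, settings.half_window)
    match_sigma = psf.sigma_psf / camera.pixel_size if settings.matched_filter else 0.0
    records: list[Localization] = []
    n_failed = 0
    for t in range(movie.n_frames):
        peaks = detect_candidates(
            residual.data[t], settings.threshold_factor, match_sigma_px=match_sigma
        )
        for peak in peaks:
            bounds = _roi_bounds(peak, half, movie.data.shape[1:])
            if bounds is None:
                continue
            r0, r1, c0, c1 = bounds
            raw = movie.data[t, r0:r1, c0:c1]
            electrons = np.clip((raw - camera.offset) / camera.em_gain, 0.0, None)
            fit = fit_spot_mle(electrons, psf, camera)
            if not fit.success:
                n_failed += 1
                continue
            records.append(
                Localization(
                    frame=t,
                    x_nm=(c0 + fit.x0) * camera.pixel_size,
                    y_nm=(r0 + fit.y0) * camera.pixel_size,
                    photons=fit.photons / camera.quantum_efficiency,
                    background=fit.background,
                    fit_sigma_nm=fit.sigma * camera.pixel_size,
                    log_likelihood=fit.log_likelihood,
                )
            )
    if n_failed:
        logger.info("%d candidate fits failed and were dropped", n_failed)
    table = LocalizationTable.from_records(
        records,
        metadata={
            "pixel_size_nm": camera.pixel_size,
            "frame_time_ms": camera.frame_period_ms,
            "source": "localize_movie",
        },
    )
    if settings.merge and len(table):
        table = merge_consecutive(table, settings.merge_radius_nm)
    if settings.min_photons > 0 and len(table):
        keep = table.df["photons"] >= settings.min_photons
        table = LocalizationTable(
            df=table.df[keep].reset_index(drop=True), metadata=dict(table.metadata)
        )
    return table


def merge_consecutive(
    table: LocalizationTable, radius_nm: float = 50.0
) -> LocalizationTable:
    """Merge localizations of one burst spanning consecutive frames.

    A localization in frame ``t+1`` within ``radius_nm`` of a chain that was
    last seen in frame ``t`` continues that chain (greedy nearest pairing);
    each finished chain becomes one record at the photon-weighted mean
    position with summed photons and ``n_merged`` set to the chain length.
    Record count never increases and total photons are conserved.
    """
    df = table.df
    if len(df) == 0:
        return table
    chains: list[dict] = []  # finished
    active: list[dict] = []
    for frame, group in df.groupby("frame", sort=True):
        frame = int(frame)
        still_active = [ch for ch in active if ch["last_frame"] == frame - 1]
        chains.extend(ch for ch in active if ch["last_frame"] < frame - 1)
        active = still_active
        used = set()
        rows = list(group.itertuples())
        # greedy nearest chain continuation
        for row in rows:
            best, best_d = None, radius_nm
            for j, ch in enumerate(active):
                if j in used:
                    continue
                d = float(np.hypot(row.x_nm - ch["x"], row.y_nm - ch["y"]))
                if d <= best_d:
                    best, best_d = j, d
            if best is not None:
                ch = active[best]
                used.add(best)
                w_old, w_new = ch["photons"], row.photons
                tot = w_old + w_new
                ch["x"] = (ch["x"] * w_old + row.x_nm * w_new) / tot
                ch["y"] = (ch["y"] * w_old + row.y_nm * w_new) / tot
                ch["photons"] = tot
                ch["background"] += row.background
                ch["fit_sigma_nm"] += row.fit_sigma_nm
                ch["log_likelihood"] += row.log_likelihood
                ch["n"] += 1
                ch["last_frame"] = frame
            else:
                active.append(
                    {
                        "frame": frame,
                        "last_frame": frame,
                        "x": row.x_nm,
                        "y": row.y_nm,
                        "photons": row.photons,
                        "background": row.background,
                        "fit_sigma_nm": row.fit_sigma_nm,
                        "log_likelihood": row.log_likelihood,
                        "n": 1,
                    }
                )
    chains.extend(active)
    records = [
        Localization(
            frame=ch["frame"],
            x_nm=ch["x"],
            y_nm=ch["y"],
            photons=ch["photons"],
            background=ch["background"] / ch["n"],
            fit_sigma_nm=ch["fit_sigma_nm"] / ch["n"],
            log_likelihood=ch["log_likelihood"],
            n_merged=ch["n"],
        )
        for ch in chains
    ]
    return LocalizationTable.from_records(records, metadata=dict(table.metadata))


def remove_persistent(
    table: LocalizationTable, radius_nm: float = 50.0, max_run: int = 5
) -> LocalizationTable:
    """Drop localizations that persist for more than ``max_run`` frames.

    Genuine single-molecule bursts last ~1-3 frames at a ~60 ms on-time;
    signals localized at the same position for many consecutive frames come
    from the non-switching population (e.g. around its bleaching step) and
    are not single-molecule detections.  Operates on an unmerged table:
    consecutive-frame chains are traced exactly as in
    :func:`merge_consecutive` and every record of a chain longer than
    ``max_run`` frames is removed.
    """
    df = table.df
    if len(df) == 0:
        return table
    chain_id = np.full(len(df), -1)
    active: list[dict] = []  # {"x","y","last_frame","id"}
    next_id = 0
    for frame, group in df.groupby("frame", sort=True):
        frame = int(frame)
        active = [ch for ch in active if ch["last_frame"] >= frame - 1]
        used = set()
        for row in group.itertuples():
            best, best_d = None, radius_nm
            for j, ch in enumerate(active):
                if j in used or ch["last_frame"] != frame - 1:
                    continue
                d = float(np.hypot(row.x_nm - ch["x"], row.y_nm - ch["y"]))
                if d <= best_d:
                    best, best_d = j, d
            if best is not None:
                ch = active[best]
                used.add(best)
                ch.update(x=row.x_nm, y=row.y_nm, last_frame=frame)
                chain_id[row.Index] = ch["id"]
            else:
                active.append(
                    {"x": row.x_nm, "y": row.y_nm, "last_frame": frame, "id": next_id}
                )
                chain_id[row.Index] = next_id
                next_id += 1
    lengths = np.bincount(chain_id, minlength=next_id)
    keep = lengths[chain_id] <= max_run
    removed = int((~keep).sum())
    if removed:
        logger.info("remove_persistent dropped %d records in long chains", removed)
    return LocalizationTable(
        df=df[keep].reset_index(drop=True), metadata=dict(table.metadata)
    )


def filter_localizations(
    table: LocalizationTable,
    min_photons: float = 100.0,
    max_photons: float | None = 1000.0,
    max_fit_sigma_nm: float | None = None,
    roi_margin_nm: float | None = None,
    field_of_view: tuple[float, float] | None = None,
) -> LocalizationTable:
    """Quality filter on a localization table.

    Defaults keep records with detected photons in the 100-1000 range typical
    of standard fluorescent proteins.  Order is preserved; the number of
    removed records is logged.
    """
    if min_photons < 0 or (max_fit_sigma_nm is not None and max_fit_sigma_nm < 0):
        raise ValueError("thresholds must be nonnegative")
    df = table.df
    keep = df["photons"] >= min_photons
    if max_photons is not None:
        keep &= df["photons"] <= max_photons
    if max_fit_sigma_nm is not None:
        keep &= df["fit_sigma_nm"] <= max_fit_sigma_nm
    if roi_margin_nm is not None and field_of_view is not None:
        keep &= (
            (df["x_nm"] >= roi_margin_nm)
            & (df["x_nm"] <= field_of_view[0] - roi_margin_nm)
            & (df["y_nm"] >= roi_margin_nm)
            & (df["y_nm"] <= field_of_view[1] - roi_margin_nm)
        )
    removed = int((~keep).sum())
    logger.info("filter_localizations removed %d of %d records", removed, len(df))
    return LocalizationTable(
        df=df[keep].reset_index(drop=True), metadata=dict(table.metadata)
    )
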