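"""Localization accuracy from adjacent-frame nearest-neighbor distances (NeNA).

A fluorophore whose burst spans two consecutive frames is localized twice
with independent errors.  If each localization has isotropic per-axis error
sd ``sigma``, the distance between the two follows a Rayleigh distribution
with scale ``sigma * sqrt(2)``:

    p(d) = (d / (2 sigma^2)) * exp(-d^2 / (4 sigma^2))

Collecting, for every localization in frame t, the distance to its nearest
neighbor in frame t+1 (within a search radius) and fitting this model plus a
linear background term (uniform spurious pairs) yields the localization
accuracy directly from the data, independent of photon-count-based
estimates.  Tracking the estimate across acquisition epochs reveals, e.g.,
improving accuracy as a non-switching background population photo-bleaches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.spatial import cKDTree

from .localize import Localization, LocalizationTable

__all__ = [
    "AccuracyEstimate",
    "NenaError",
    "collect_adjacent_pairs",
    "estimate_accuracy_nena",
    "accuracy_trend",
    "nena_pair_pdf",
    "simulate_pair_table",
]

MIN_PAIRS = 50


class NenaError(RuntimeError):
    """Raised when the pair sample or the mixture fit is unusable."""


@dataclass
class AccuracyEstimate:
    """Fitted per-axis localization accuracy for one (epoch of a) table."""

    sigma_loc: float
    n_pairs: int
    fit_background_fraction: float
    confidence_halfwidth: float
    valid: bool = True
    epoch: tuple[int, int] | None = None  # (first frame, last frame), inclusive


def nena_pair_pdf(d: np.ndarray, sigma: float, search_radius: float) -> np.ndarray:
    """Same-molecule distance density, truncated and renormalized on [0, R]."""
    d = np.asarray(d, dtype=float)
    z = 1.0 - np.exp(-(search_radius**2) / (4.0 * sigma**2))
    return (d / (2.0 * sigma**2)) * np.exp(-(d**2) / (4.0 * sigma**2)) / z


def collect_adjacent_pairs(
    table: LocalizationTable, search_radius: float = 200.0
) -> np.ndarray:
    """Nearest-neighbor distances between localizations in adjacent frames.

    For each localization in frame ``t``, the distance to the nearest
    localization in frame ``t + 1`` is recorded if it is within
    ``search_radius`` (nm).
    """
    if search_radius <= 0:
        raise ValueError("search_radius must be positive")
    df = table.df
    frames = df["frame"].to_numpy()
    if len(df) == 0 or frames.max() == frames.min():
        return np.empty(0)
    xy = table.xy
    by_frame = {int(f): xy[frames == f] for f in np.unique(frames)}
    dists: list[np.ndarray] = []
    for f, pts in by_frame.items():
        nxt = by_frame.get(f + 1)
        if nxt is None or len(nxt) == 0:
            continue
        d, _ = cKDTree(nxt).query(pts, k=1)
        dists.append(d[d <= search_radius])
    return np.concatenate(dists) if dists else np.empty(0)


def _fit_mixture(
    distances: np.ndarray, search_radius: float, n_bins: int = 200
) -> tuple[float, float, float]:
    """Binned bounded-ML fit of the Rayleigh + linear-background mixture.

    Returns (sigma, background_fraction, confidence_halfwidth).
    """
    edges = np.linspace(0.0, search_radius, n_bins + 1)
    counts, _ = np.histogram(distances, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    bin_w = edges[1] - edges[0]
    n = counts.sum()

    def nll(theta: np.ndarray) -> float:
        sigma, w = theta
        p = w * nena_pair_pdf(centers, sigma, search_radius) + (1.0 - w) * (
            2.0 * centers / search_radius**2
        )
        p = np.clip(p * bin_w, 1e-300, None)
        return -float(np.sum(counts * np.log(p)))

    sigma0 = max(float(np.median(distances)) / np.sqrt(2.0), 0.5)
    best = None
    for w0 in (0.9, 0.5):
        res = optimize.minimize(
            nll,
            np.array([sigma0, w0]),
            method="L-BFGS-B",
            bounds=[(1e-3, search_radius), (0.0, 1.0)],
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not best.success:
        raise NenaError(f"mixture fit did not converge: {best and best.message}")
    sigma, w = best.x
    # curvature-based interval: numeric second derivative of the profile NLL
    h = max(1e-3 * sigma, 1e-4)
    f0 = nll(np.array([sigma, w]))
    fp = nll(np.array([sigma + h, w]))
    fm = nll(np.array([max(sigma - h, 1e-4), w]))
    curv = (fp - 2 * f0 + fm) / h**2
    halfwidth = 1.96 / np.sqrt(curv) if curv > 0 else np.inf
    return float(sigma), float(1.0 - w), float(halfwidth)


def estimate_accuracy_nena(
    table: LocalizationTable, search_radius: float = 200.0
) -> AccuracyEstimate:
    """Estimate per-axis localization accuracy from adjacent-frame pairs.

    Raises
    ------
    NenaError
        Fewer than ``MIN_PAIRS`` adjacent-frame pairs, or fit non-convergence.
    """
    d = collect_adjacent_pairs(table, search_radius)
    if len(d) < MIN_PAIRS:
        raise NenaError(
            f"insufficient pairs: {len(d)} adjacent-frame pairs "
            f"(need >= {MIN_PAIRS})"
        )
    sigma, bg, half = _fit_mixture(d, search_radius)
    frames = table.df["frame"]
    return AccuracyEstimate(
        sigma_loc=sigma,
        n_pairs=int(len(d)),
        fit_background_fraction=bg,
        confidence_halfwidth=half,
        epoch=(int(frames.min()), int(frames.max())),
    )


def accuracy_trend(
    table: LocalizationTable, n_epochs: int, search_radius: float = 200.0
) -> list[AccuracyEstimate]:
    """Per-epoch accuracy over the acquisition.

    Frames are split into ``n_epochs`` contiguous spans of equal frame count;
    the estimator runs independently in each.  An epoch with too few pairs is
    returned with ``valid=False`` instead of aborting the whole trend.
    """
    if n_epochs < 2:
        raise ValueError("n_epochs must be >= 2")
    df = table.df
    if len(df) == 0:
        raise NenaError("empty table")
    f0, f1 = int(df["frame"].min()), int(df["frame"].max())
    edges = np.linspace(f0, f1 + 1, n_epochs + 1)
    out: list[AccuracyEstimate] = []
    for i in range(n_epochs):
        lo, hi = edges[i], edges[i + 1]
        sub = LocalizationTable(
            df=df[(df["frame"] >= lo) & (df["frame"] < hi)].reset_index(drop=True),
            metadata=dict(table.metadata),
        ) if ((df["frame"] >= lo) & (df["frame"] < hi)).any() else None
        try:
            if sub is None:
                raise NenaError("empty epoch")
            est = estimate_accuracy_nena(sub, search_radius)
            est.epoch = (int(np.ceil(lo)), int(np.floor(hi - 1)))
            out.append(est)
        except NenaError:
            out.append(
                AccuracyEstimate(
                    sigma_loc=np.nan,
                    n_pairs=0,
                    fit_background_fraction=np.nan,
                    confidence_halfwidth=np.inf,
                    valid=False,
                    epoch=(int(np.ceil(lo)), int(np.floor(hi - 1))),
                )
            )
    return out


def simulate_pair_table(
    sigma: float,
    n_pairs: int,
    background_fraction: float = 0.0,
    search_radius: float = 200.0,
    field_nm: float = 20000.0,
    seed: int | None = None,
) -> LocalizationTable:
    """Synthetic adjacent-frame pair sample for estimator validation.

    Each same-molecule pair is a true position (uniform in the field) observed
    in frames ``2k`` and ``2k+1`` with independent per-axis Gaussian error of
    sd ``sigma``.  A ``background_fraction`` of pairs is spurious: the second
    point is instead uniform in the disk of radius ``search_radius`` around
    the first (linear distance density).  Pairs are spread over frames so
    sparsely that nearest-neighbor pairing is unambiguous.
    """
    rng = np.random.default_rng(seed)
    records: list[Localization] = []
    # few pairs per frame-slot keeps cross-talk between pairs negligible
    per_slot = max(1, int(field_nm**2 / (40 * search_radius) ** 2))
    slot = 0
    placed = 0
    while placed < n_pairs:
        k = min(per_slot, n_pairs - placed)
        truth = rng.uniform(0.0, field_nm, size=(k, 2))
        first = truth + rng.normal(0.0, sigma, size=(k, 2))
        is_bg = rng.random(k) < background_fraction
        second = truth + rng.normal(0.0, sigma, size=(k, 2))
        nbg = int(is_bg.sum())
        if nbg:
            r = search_radius * np.sqrt(rng.random(nbg))
            th = rng.uniform(0, 2 * np.pi, nbg)
            second[is_bg] = first[is_bg] + np.c_[r * np.cos(th), r * np.sin(th)]
        f = 2 * slot
        for j in range(k):
            records.append(
                Localization(f, first[j, 0], first[j, 1], 500.0, 5.0, 130.0)
            )
            records.append(
                Localization(f + 1, second[j, 0], second[j, 1], 500.0, 5.0, 130.0)
            )
        placed += k
        slot += 1
    return LocalizationTable.from_records(
        records,
        metadata={"pixel_size_nm": 80.0, "frame_time_ms": 58.8, "source": "synthetic"},
    )
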