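"""Background subtraction, detection, MLE fitting, merging, filtering."""

import numpy as np
import pytest
from scipy.special import erf

import smlmclem as sm
from smlmclem.localize import merge_consecutive, robust_sigma


def _stack(data, camera=None):
    return sm.MovieStack(data=np.asarray(data, float), camera=camera or sm.CameraModel())


# ---------------------------------------------------------------------------
# background subtraction


def test_constant_stack_gives_zero_residual():
    movie = _stack(np.full((30, 6, 6), 7.5))
    res = sm.subtract_background(movie, half_window=10)
    np.testing.assert_allclose(res.data, 0.0)


def test_burst_amplitude_preserved_by_median_window():
    """A 3-frame burst on constant background survives a 21-frame median."""
    data = np.full((41, 5, 5), 50.0)
    data[20:23, 2, 2] += 200.0
    res = sm.subtract_background(_stack(data), half_window=10)
    # oracle: direct temporal median of the window around frame 21
    oracle = data[21, 2, 2] - np.median(data[11:32, 2, 2])
    assert oracle == 200.0
    assert res.data[21, 2, 2] == pytest.approx(200.0, rel=0.05)


def test_linear_ramp_residual_bounded_by_slope_times_halfwindow():
    s = 3.0
    t = np.arange(60)
    data = np.tile((100.0 + s * t)[:, None, None], (1, 4, 4))
    res = sm.subtract_background(_stack(data), half_window=10)
    assert np.abs(res.data).max() <= s * 10 + 1e-9


def test_background_subtraction_idempotent_on_constant_background():
    rng = np.random.default_rng(3)
    data = np.full((40, 6, 6), 20.0)
    data[15, 3, 3] += 300.0
    once = sm.subtract_background(_stack(data), half_window=10)
    twice = sm.subtract_background(_stack(once.data), half_window=10)
    np.testing.assert_allclose(once.data, twice.data, atol=1e-9)


def test_window_larger_than_movie_raises():
    with pytest.raises(ValueError, match="frames"):
        sm.subtract_background(_stack(np.zeros((10, 4, 4))), half_window=10)


# ---------------------------------------------------------------------------
# detection


def test_all_zero_frame_gives_no_candidates():
    assert sm.detect_candidates(np.zeros((16, 16))) == []


def test_single_noiseless_spot_gives_one_peak_at_brightest_pixel(default_psf):
    camera = sm.CameraModel(em_gain=1.0, offset=0.0, quantum_efficiency=1.0)
    spot = 500.0 * sm.integrated_gaussian(8.3, 7.6, 1.14, (16, 16))
    peaks = sm.detect_candidates(spot)
    assert len(peaks) == 1
    assert peaks[0] == tuple(np.unravel_index(np.argmax(spot), spot.shape))


def test_two_spot_separation_rule():
    g = lambda x, y: 400.0 * sm.integrated_gaussian(x, y, 1.0, (24, 24))
    far = g(6.5, 12.5) + g(16.5, 12.5)  # 10 px apart
    assert len(sm.detect_candidates(far)) == 2
    near = g(11.5, 12.5) + g(12.5, 12.5)  # 1 px apart
    assert len(sm.detect_candidates(near)) == 1


# ---------------------------------------------------------------------------
# MLE fitting


def _roi(x0, y0, n, b, sigma_px, size=7):
    return n * sm.integrated_gaussian(x0, y0, sigma_px, (size, size)) + b


def test_noiseless_centered_spot_fit_below_millipixel(default_psf, default_camera):
    sp = default_psf.sigma_psf / default_camera.pixel_size
    fit = sm.fit_spot_mle(_roi(3.5, 3.5, 500.0, 10.0, sp), default_psf, default_camera)
    assert fit.success
    assert abs(fit.x0 - 3.5) < 1e-3
    assert abs(fit.y0 - 3.5) < 1e-3


def test_degenerate_flat_roi_returns_failure_flag(default_psf, default_camera):
    fit = sm.fit_spot_mle(np.full((7, 7), 4.0), default_psf, default_camera)
    assert not fit.success
    assert "degenerate" in fit.message


@pytest.mark.parametrize("x0,y0", [(3.5, 3.5), (3.82, 3.21), (4.1, 2.9)])
def test_mle_matches_grid_search_likelihood_oracle(
    x0, y0, default_psf, default_camera
):
    """On noiseless ROIs the fitted position agrees with an exhaustive
    grid search of the Poisson likelihood (0.02 px grid) within one step."""
    sp = default_psf.sigma_psf / default_camera.pixel_size
    counts = _roi(x0, y0, 500.0, 10.0, sp)
    fit = sm.fit_spot_mle(counts, default_psf, default_camera)
    assert fit.success

    def nll(xc, yc):
        s = sp * np.sqrt(2.0)
        xe = np.arange(8.0)
        gx = 0.5 * np.diff(erf((xe - xc) / s))
        gy = 0.5 * np.diff(erf((xe - yc) / s))
        mu = 500.0 * np.outer(gy, gx) + 10.0
        return np.sum(mu - counts * np.log(mu))

    grid = np.arange(-0.5, 0.5001, 0.02)
    vals = np.array([[nll(x0 + dx, y0 + dy) for dx in grid] for dy in grid])
    iy, ix = np.unravel_index(np.argmin(vals), vals.shape)
    assert abs(fit.x0 - (x0 + grid[ix])) <= 0.02 + 1e-9
    assert abs(fit.y0 - (y0 + grid[iy])) <= 0.02 + 1e-9


def test_fit_recovers_photons_background_sigma(default_camera):
    psf = sm.PSFModel(sigma_psf=130.0)
    sp = 130.0 / default_camera.pixel_size
    fit = sm.fit_spot_mle(_roi(3.4, 3.7, 600.0, 8.0, sp), psf, default_camera)
    assert fit.photons == pytest.approx(600.0, rel=1e-3)
    assert fit.background == pytest.approx(8.0, rel=1e-2)
    assert fit.sigma == pytest.approx(sp, rel=1e-3)


# ---------------------------------------------------------------------------
# movie-level pipeline


@pytest.fixture(scope="module")
def simulated_movie():
    fov = (2560.0, 2560.0)
    camera = sm.CameraModel(em_gain=30.0, read_noise=20.0)
    psf = sm.PSFModel()
    emitters = sm.generate_structure(
        "uniform", {"density_per_um2": 300 / 6.5536}, fov, seed=1
    )
    params = sm.SwitchingParams(recovery_rate=0.02, bleach_prob=0.5)
    sched = sm.simulate_switching(emitters, params, 300, camera, seed=2)
    movie = sm.render_movie(sched, psf, camera, (32, 32), background=10.0, seed=3)
    return movie, sched, psf, fov


def test_localize_movie_recall_and_precision(simulated_movie):
    """Detections match ground truth at 100 nm: recall >= 0.9 over
    detectable events (>= 100 photons in frame, away from the border),
    precision >= 0.95 over all reported records."""
    movie, sched, psf, fov = simulated_movie
    table = sm.localize_movie(movie, psf)
    df = table.df
    assert len(df) > 30
    gt_by_frame = {}
    for f, x, y, p in zip(sched.frame, sched.x, sched.y, sched.photons):
        gt_by_frame.setdefault(int(f), []).append((x, y, p))
    hits = 0
    locs_by_frame = {}
    for row in df.itertuples():
        ok = False
        for f in range(int(row.frame), int(row.frame) + int(row.n_merged)):
            locs_by_frame.setdefault(f, []).append((row.x_nm, row.y_nm))
            pts = gt_by_frame.get(f)
            if pts and not ok:
                d = np.linalg.norm(
                    np.array(pts)[:, :2] - [row.x_nm, row.y_nm], axis=1
                ).min()
                ok = d <= 100.0
        hits += ok
    precision = hits / len(df)
    margin = 3 * movie.camera.pixel_size
    found = tot = 0
    for f, x, y, p in zip(sched.frame, sched.x, sched.y, sched.photons):
        if p < 100 or not (
            margin < x < fov[0] - margin and margin < y < fov[1] - margin
        ):
            continue
        tot += 1
        pts = locs_by_frame.get(int(f))
        if pts and np.linalg.norm(np.array(pts) - [x, y], axis=1).min() <= 100.0:
            found += 1
    assert precision >= 0.95
    assert found / tot >= 0.9


def test_noise_only_movie_has_low_false_localization_rate(default_psf):
    """<= 1 false localization per 100 frames at default settings."""
    camera = sm.CameraModel(em_gain=30.0, read_noise=20.0)
    empty = sm.GroundTruthSchedule(
        frame=np.empty(0, int), emitter_id=np.empty(0, int),
        x=np.empty(0), y=np.empty(0), photons=np.empty(0), n_frames=300,
    )
    movie = sm.render_movie(empty, default_psf, camera, (32, 32),
                            background=10.0, seed=5)
    table = sm.localize_movie(movie, default_psf)
    assert len(table) <= 3


def test_two_frame_burst_merges_into_single_record():
    recs = [
        sm.Localization(0, 1000.0, 1000.0, 300.0, 5.0, 100.0),
        sm.Localization(1, 1020.0, 1000.0, 200.0, 5.0, 100.0),
    ]
    table = sm.LocalizationTable.from_records(recs, {"pixel_size_nm": 80})
    merged = merge_consecutive(table, radius_nm=50.0)
    assert len(merged) == 1
    row = merged.df.iloc[0]
    assert row.n_merged == 2
    assert row.photons == pytest.approx(500.0)
    # photon-weighted mean position
    assert row.x_nm == pytest.approx((1000 * 300 + 1020 * 200) / 500)


def test_merging_conserves_photons_and_never_increases_count(simulated_movie):
    movie, _, psf, _ = simulated_movie
    raw = sm.localize_movie(movie, psf, sm.LocalizeSettings(merge=False, min_photons=0))
    merged = merge_consecutive(raw, radius_nm=50.0)
    assert len(merged) <= len(raw)
    assert merged.df.photons.sum() == pytest.approx(raw.df.photons.sum())


def test_filter_identity_and_thresholds():
    recs = [
        sm.Localization(0, 10.0, 10.0, 50.0, 1.0, 100.0),
        sm.Localization(1, 20.0, 20.0, 150.0, 1.0, 100.0),
    ]
    table = sm.LocalizationTable.from_records(recs, {})
    same = sm.filter_localizations(table, min_photons=0, max_photons=None)
    assert len(same) == 2
    kept = sm.filter_localizations(table, min_photons=100, max_photons=None)
    assert len(kept) == 1
    assert kept.df.iloc[0].photons == 150.0


def test_robust_sigma_matches_gaussian_sd():
    x = np.random.default_rng(0).normal(0, 2.5, size=100_000)
    assert robust_sigma(x) == pytest.approx(2.5, rel=0.02)
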