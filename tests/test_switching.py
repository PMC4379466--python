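"""Photo-switching simulation against continuous-time oracles."""

import numpy as np
import pytest

import smlmclem as sm


def _frames_per_burst_oracle(
    mean_on_ms: float,
    period_ms: float,
    integration_ms: float,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Brute force: draw exact on/off times, bin into integration windows."""
    t0 = rng.uniform(0.0, period_ms, size=n)
    dur = rng.exponential(mean_on_ms, size=n)
    t1 = t0 + dur
    counts = np.zeros(n, dtype=int)
    for i in range(n):
        k = 0
        while True:
            w0, w1 = k * period_ms, k * period_ms + integration_ms
            if w0 > t1[i]:
                break
            if min(t1[i], w1) - max(t0[i], w0) > 0:
                counts[i] += 1
            k += 1
    return counts


def _observed_frames_per_burst(schedule: sm.GroundTruthSchedule) -> np.ndarray:
    """Consecutive-frame run lengths per emitter (sparse bursts don't abut)."""
    runs = []
    for eid in np.unique(schedule.emitter_id):
        frames = np.sort(schedule.frame[schedule.emitter_id == eid])
        breaks = np.flatnonzero(np.diff(frames) > 1)
        start = 0
        for b in list(breaks) + [len(frames) - 1]:
            runs.append(b - start + 1)
            start = b + 1
    return np.asarray(runs)


@pytest.fixture(scope="module")
def burst_schedule():
    camera = sm.CameraModel()  # 50 ms integration, 17 fps
    emitters = sm.EmitterSet(
        positions=np.random.default_rng(0).uniform(0, 4000, size=(10000, 2)),
        structure_kind="uniform",
    )
    params = sm.SwitchingParams(recovery_rate=0.5, bleach_prob=1.0)
    return sm.simulate_switching(emitters, params, 600, camera, seed=123), camera


def test_no_recovery_no_nonswitching_gives_empty_schedule():
    emitters = sm.EmitterSet(positions=[[100.0, 100.0]], structure_kind="uniform")
    params = sm.SwitchingParams(recovery_rate=0.0, nonswitching_fraction=0.0)
    sched = sm.simulate_switching(emitters, params, 100, sm.CameraModel(), seed=0)
    assert len(sched) == 0


def test_mean_frames_per_burst_matches_continuous_time_oracle(burst_schedule):
    """60 ms on-time discretized by 50 ms windows at 17 fps, ~10^4 bursts."""
    sched, camera = burst_schedule
    observed = _observed_frames_per_burst(sched)
    assert len(observed) > 9000
    oracle = _frames_per_burst_oracle(
        60.0, camera.frame_period_ms, camera.integration_time,
        100_000, np.random.default_rng(9),
    )
    assert observed.mean() == pytest.approx(oracle.mean(), rel=0.02)


def test_burst_length_distribution_ks_against_oracle(burst_schedule):
    sched, camera = burst_schedule
    observed = _observed_frames_per_burst(sched)
    oracle = _frames_per_burst_oracle(
        60.0, camera.frame_period_ms, camera.integration_time,
        100_000, np.random.default_rng(10),
    )
    hi = int(max(observed.max(), oracle.max()))
    cdf_obs = np.cumsum(np.bincount(observed, minlength=hi + 1)) / len(observed)
    cdf_ora = np.cumsum(np.bincount(oracle, minlength=hi + 1)) / len(oracle)
    assert np.abs(cdf_obs - cdf_ora).max() < 0.02


def test_burst_photon_budgets_within_detected_range(burst_schedule):
    """Detected photons per burst stay in the 100-1000 range."""
    sched, camera = burst_schedule
    total_ms = 600 * camera.frame_period_ms
    full = [b for b in sched.bursts if b[2] < total_ms]  # not end-truncated
    budgets = np.array([b[3] for b in full])
    assert budgets.min() >= 100.0
    assert budgets.max() <= 1000.0


def test_nonswitching_intensity_decays_at_bleach_rate():
    """Summed per-frame photons of the non-switching population decay
    exponentially at the configured bleaching rate (within 10%)."""
    camera = sm.CameraModel()
    rng = np.random.default_rng(5)
    emitters = sm.EmitterSet(
        positions=rng.uniform(0, 4000, size=(5000, 2)), structure_kind="uniform"
    )
    rate = 0.1
    params = sm.SwitchingParams(
        recovery_rate=0.0, nonswitching_fraction=1.0, nonswitching_bleach_rate=rate
    )
    n_frames = 400
    sched = sm.simulate_switching(emitters, params, n_frames, camera, seed=6)
    per_frame = np.bincount(sched.frame, weights=sched.photons, minlength=n_frames)
    t_s = np.arange(n_frames) * camera.frame_period_ms / 1000.0
    # log-linear fit over the well-populated range
    use = per_frame > per_frame[0] * 0.02
    slope, _ = np.polyfit(t_s[use], np.log(per_frame[use]), 1)
    assert -slope == pytest.approx(rate, rel=0.10)


def test_identical_seeds_give_bit_identical_schedules():
    emitters = sm.generate_structure(
        "uniform", {"density_per_um2": 50}, (3000.0, 3000.0), seed=1
    )
    params = sm.SwitchingParams(recovery_rate=0.2, nonswitching_fraction=0.2)
    a = sm.simulate_switching(emitters, params, 200, sm.CameraModel(), seed=77)
    b = sm.simulate_switching(emitters, params, 200, sm.CameraModel(), seed=77)
    np.testing.assert_array_equal(a.frame, b.frame)
    np.testing.assert_array_equal(a.photons, b.photons)
    np.testing.assert_array_equal(a.emitter_id, b.emitter_id)
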