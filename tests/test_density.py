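"""K-NN density, normalization factor, Nyquist and structural resolution."""

import numpy as np
import pytest

import smlmclem as sm
from smlmclem.density import DensityParams


def test_square_grid_k4_mean_distance_is_spacing():
    a = 50.0
    xs, ys = np.meshgrid(np.arange(10) * a, np.arange(10) * a)
    pts = np.c_[xs.ravel(), ys.ravel()]
    md = sm.knn_mean_distance(pts, K=4)
    interior = md.reshape(10, 10)[1:-1, 1:-1]
    np.testing.assert_allclose(interior, a)


def test_k1_collinear_hand_check():
    pts = np.array([[0.0, 0.0], [10.0, 0.0], [30.0, 0.0]])
    np.testing.assert_allclose(sm.knn_mean_distance(pts, K=1), [10.0, 10.0, 20.0])


def test_knn_matches_brute_force_all_pairs_oracle(uniform_points):
    pts = uniform_points[:1500]
    fast = sm.knn_mean_distance(pts, K=20)
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(dist, np.inf)
    slow = np.sort(dist, axis=1)[:, :20].mean(axis=1)
    np.testing.assert_allclose(fast, slow, rtol=1e-12)


def test_too_few_points_raises():
    with pytest.raises(ValueError, match="more than"):
        sm.knn_mean_distance(np.zeros((5, 2)), K=20)


def test_norm_factor_closed_forms_and_monotonicity():
    assert sm.norm_factor(1) == pytest.approx(0.5, abs=1e-12)
    values = [sm.norm_factor(k) for k in range(1, 40)]
    assert np.all(np.diff(values) > 0)


def test_norm_factor_k20_against_monte_carlo():
    """c20 from simulated Poisson patterns (10^6 points aggregate) within 1%."""
    rng = np.random.default_rng(99)
    rho = 0.01  # points per nm^2
    ratios = []
    n_total = 0
    while n_total < 1_000_000:
        side = 400.0
        n = rng.poisson(rho * side * side)
        pts = rng.uniform(0, side, size=(n, 2))
        md = sm.knn_mean_distance(pts, K=20)
        # interior points only: border truncates neighborhoods
        margin = 60.0
        inner = (
            (pts[:, 0] > margin) & (pts[:, 0] < side - margin)
            & (pts[:, 1] > margin) & (pts[:, 1] < side - margin)
        )
        ratios.append(md[inner] * np.sqrt(rho))
        n_total += n
    c20_mc = np.concatenate(ratios).mean()
    assert sm.norm_factor(20) == pytest.approx(c20_mc, rel=0.01)


def test_local_density_definition_and_scaling():
    c20 = sm.norm_factor(20)
    # mean distance equal to c_K gives exactly 1 point per nm^2
    assert sm.local_density(np.array([c20]))[0] == pytest.approx(1e6)
    # doubling all coordinates dilutes density 4x
    rng = np.random.default_rng(1)
    pts = rng.uniform(0, 1000, size=(500, 2))
    rho1 = sm.local_density(sm.knn_mean_distance(pts, 20))
    rho2 = sm.local_density(sm.knn_mean_distance(2 * pts, 20))
    np.testing.assert_allclose(rho1, 4 * rho2, rtol=1e-9)


def test_duplicates_excluded_with_nan():
    assert np.isnan(sm.local_density(np.array([0.0, 10.0]))[0])


@pytest.mark.parametrize(
    "rho,expected",
    [(10_000.0, 20.0), (1_600.0, 50.0), (22_000.0, 13.483997249264842)],
)
def test_nyquist_resolution_arithmetic(rho, expected):
    assert sm.nyquist_resolution(rho) == pytest.approx(expected, rel=1e-9)


def test_structural_resolution_limits_and_value():
    rn = sm.nyquist_resolution(22_000.0)
    r = sm.structural_resolution(17.0, rn)
    assert 40.0 <= r <= 50.0
    assert r == pytest.approx(42.16, abs=0.05)
    assert sm.structural_resolution(0.0, rn) == pytest.approx(rn)
    assert sm.structural_resolution(17.0, 0.0) == pytest.approx(2.35 * 17.0)


def test_structural_resolution_monotone_in_both_arguments():
    sig = np.linspace(0, 30, 7)
    rn = np.linspace(0, 60, 7)
    for r_n in rn:
        vals = [sm.structural_resolution(s, r_n) for s in sig]
        assert np.all(np.diff(vals) >= 0)
    for s in sig:
        vals = [sm.structural_resolution(s, r_n) for r_n in rn]
        assert np.all(np.diff(vals) >= 0)


def test_molecules_per_diffraction_limited_area():
    assert sm.molecules_per_dl_area(22_000.0) == pytest.approx(1079.9, abs=0.1)
    assert sm.molecules_per_dl_area(40_000.0) == pytest.approx(1963.5, abs=0.1)
    assert sm.molecules_per_dl_area(0.0) == 0.0


@pytest.mark.parametrize("rho", [1_000.0, 10_000.0, 40_000.0])
def test_density_recovery_on_uniform_poisson_fields(rho):
    """Edge-corrected mean density within 5% on uniform fields."""
    rng = np.random.default_rng(int(rho))
    side = np.sqrt(3e6 / (rho * 1e-6))  # ~3e6 expected... keep n moderate
    side = min(side, 2000.0)
    n = rng.poisson(rho * 1e-6 * side * side)
    pts = rng.uniform(0, side, size=(n, 2))
    res = sm.compute_density_resolution(pts, sigma_loc_nm=10.0,
                                        field_of_view=(side, side))
    ok = ~res.border_flag
    assert ok.sum() > 200
    assert res.summary["mean_rho_per_um2"] == pytest.approx(rho, rel=0.05)


def test_end_to_end_structural_resolution_on_simulated_field():
    """Known sigma and rho reproduce the closed-form structural resolution
    within 10%."""
    rho = 5_000.0
    sigma = 15.0
    rng = np.random.default_rng(7)
    side = 1500.0
    n = rng.poisson(rho * 1e-6 * side * side)
    truth = rng.uniform(0, side, size=(n, 2))
    observed = truth + rng.normal(0, sigma, size=truth.shape)
    res = sm.compute_density_resolution(observed, sigma, field_of_view=(side, side))
    expected = sm.structural_resolution(sigma, sm.nyquist_resolution(rho))
    assert res.summary["median_structural_nm"] == pytest.approx(expected, rel=0.10)


def test_density_params_reject_wrong_norm_factor():
    with pytest.raises(ValueError, match="does not match"):
        DensityParams(K=20, c_K=0.5)
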