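"""Control-point registration, raster resampling, overlays, line profiles."""

import numpy as np
import pytest

import smlmclem as sm
from smlmclem.register import RegistrationError

try:
    from hypothesis import given, settings, strategies as st

    HAVE_HYPOTHESIS = True
except ImportError:  # pragma: no cover
    HAVE_HYPOTHESIS = False


RNG = np.random.default_rng(17)
POINTS = RNG.uniform(0, 4000, size=(12, 2))
KNOWN = sm.Transform2D.similarity(1.6, 30.0, (100.0, -50.0))


def test_identity_fit_has_zero_residual():
    cps = sm.ControlPointSet(POINTS, POINTS)
    for kind in ("similarity", "affine"):
        t = sm.estimate_transform(cps, kind)
        assert t.residual_rms == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(t.matrix, [[1, 0, 0], [0, 1, 0]], atol=1e-9)


def test_known_similarity_recovered_to_1e6():
    cps = sm.ControlPointSet(POINTS, KNOWN.apply(POINTS))
    t = sm.estimate_transform(cps, "similarity")
    assert t.scale == pytest.approx(1.6, rel=1e-6)
    assert t.rotation_deg == pytest.approx(30.0, rel=1e-6)
    np.testing.assert_allclose(t.translation, [100.0, -50.0], rtol=1e-6, atol=1e-6)
    assert t.residual_rms < 1e-9


def test_known_affine_recovered_to_1e6():
    true = sm.Transform2D(
        kind="affine", matrix=np.array([[1.5, 0.2, 30.0], [-0.1, 0.9, -12.0]])
    )
    cps = sm.ControlPointSet(POINTS, true.apply(POINTS))
    t = sm.estimate_transform(cps, "affine")
    np.testing.assert_allclose(t.matrix, true.matrix, rtol=1e-6, atol=1e-6)


def test_anisotropic_scale_needs_affine():
    aniso = sm.Transform2D(
        kind="affine", matrix=np.array([[1.5, 0.0, 0.0], [0.0, 1.0, 0.0]])
    )
    cps = sm.ControlPointSet(POINTS, aniso.apply(POINTS))
    t_sim = sm.estimate_transform(cps, "similarity")
    t_aff = sm.estimate_transform(cps, "affine")
    assert t_aff.residual_rms < 1e-9
    assert t_sim.residual_rms > 1.0


def test_affine_residual_never_exceeds_similarity_residual():
    """Nested models: the affine LSQ fit is at least as good."""
    for seed in range(5):
        rng = np.random.default_rng(seed)
        src = rng.uniform(0, 1000, size=(8, 2))
        dst = KNOWN.apply(src) + rng.normal(0, 5.0, size=(8, 2))
        cps = sm.ControlPointSet(src, dst)
        r_aff = sm.estimate_transform(cps, "affine").residual_rms
        r_sim = sm.estimate_transform(cps, "similarity").residual_rms
        assert r_aff <= r_sim + 1e-12


def test_similarity_invariant_to_global_rotation():
    """Rotating both point sets rigidly leaves the fitted scale/residual
    unchanged."""
    rng = np.random.default_rng(3)
    src = rng.uniform(0, 1000, size=(10, 2))
    dst = KNOWN.apply(src) + rng.normal(0, 2.0, size=(10, 2))
    base = sm.estimate_transform(sm.ControlPointSet(src, dst), "similarity")
    rot = sm.Transform2D.similarity(1.0, 73.0, (0.0, 0.0))
    turned = sm.estimate_transform(
        sm.ControlPointSet(rot.apply(src), rot.apply(dst)), "similarity"
    )
    assert turned.scale == pytest.approx(base.scale, rel=1e-9)
    assert turned.residual_rms == pytest.approx(base.residual_rms, rel=1e-9)


def test_insufficient_or_collinear_points_raise():
    with pytest.raises(RegistrationError):
        sm.estimate_transform(sm.ControlPointSet(POINTS[:1], POINTS[:1]), "similarity")
    line = np.c_[np.arange(5.0), np.arange(5.0)]
    with pytest.raises(RegistrationError, match="collinear"):
        sm.estimate_transform(sm.ControlPointSet(line, line), "affine")


def test_forward_then_inverse_is_identity_on_points():
    pts = RNG.uniform(-500, 500, size=(30, 2))
    back = KNOWN.inverse().apply(KNOWN.apply(pts))
    np.testing.assert_allclose(back, pts, atol=1e-9)


if HAVE_HYPOTHESIS:

    @settings(max_examples=25, deadline=None)
    @given(
        scale=st.floats(0.2, 5.0),
        rot=st.floats(-180.0, 180.0),
        tx=st.floats(-200.0, 200.0),
        ty=st.floats(-200.0, 200.0),
    )
    def test_similarity_roundtrip_property(scale, rot, tx, ty):
        t = sm.Transform2D.similarity(scale, rot, (tx, ty))
        pts = np.array([[0.0, 0.0], [100.0, 0.0], [0.0, 100.0], [37.0, -41.0]])
        cps = sm.ControlPointSet(pts, t.apply(pts))
        fit = sm.estimate_transform(cps, "similarity")
        np.testing.assert_allclose(fit.matrix, t.matrix, rtol=1e-6, atol=1e-5)


def test_raster_identity_resample():
    img = RNG.uniform(0, 1, size=(20, 20))
    out = sm.apply_transform(img, sm.Transform2D.identity(), raster=True)
    np.testing.assert_allclose(out, img, atol=1e-12)


def test_integer_translation_equals_roll():
    img = RNG.uniform(0, 1, size=(30, 30))
    t = sm.Transform2D.similarity(1.0, 0.0, (4.0, 7.0))
    out = sm.apply_transform(img, t, raster=True)
    rolled = np.roll(img, (7, 4), axis=(0, 1))
    np.testing.assert_allclose(out[8:, 5:], rolled[8:, 5:], atol=1e-12)


def test_overlay_alpha_extremes():
    em = RNG.uniform(0, 255, size=(40, 40))
    sr = np.zeros((40, 40, 3))
    sr[10:20, 10:20, 0] = 1.0
    t = sm.Transform2D.identity()
    em_norm = (em - em.min()) / (em.max() - em.min())
    out0 = sm.make_overlay(sr, em, t, alpha=0.0, sr_pixel_nm=1.0)
    np.testing.assert_allclose(out0[..., 0], em_norm, atol=1e-12)
    out1 = sm.make_overlay(sr, em, t, alpha=1.0, sr_pixel_nm=1.0)
    # inside the SR support the composite equals the resampled SR
    np.testing.assert_allclose(out1[12:18, 12:18], sr[12:18, 12:18], atol=1e-9)


def test_overlay_centerlines_align_with_em_ridges(membrane_pair_emitters):
    """With the fitted transform, SR ridge centerlines fall on the EM dark
    ridges within one EM pixel."""
    emitters = membrane_pair_emitters
    true_t = sm.Transform2D.similarity(0.05, 20.0, (30.0, 40.0))
    em_img, _ = sm.synthesize_em_image(
        emitters, true_t, size=(256, 256), noise_level=0.0
    )
    idx = np.arange(0, len(emitters), max(1, len(emitters) // 6))[:6]
    cps = sm.ControlPointSet(
        emitters.positions[idx], true_t.apply(emitters.positions[idx])
    )
    fit = sm.estimate_transform(cps, "similarity")
    # map ground-truth membrane points through the fit and check they land
    # on the dark EM ridge: the intensity minimum along the direction
    # perpendicular to the membranes must lie within one EM pixel
    from scipy.ndimage import map_coordinates

    th = np.deg2rad(true_t.rotation_deg)
    perp = np.array([-np.sin(th), np.cos(th)])  # membranes run along angle 0
    offsets = np.linspace(-3.0, 3.0, 61)
    probe = emitters.positions[10:40]
    mapped = fit.apply(probe)
    for x, y in mapped:
        xs = x + offsets * perp[0]
        ys = y + offsets * perp[1]
        vals = map_coordinates(em_img, np.vstack([ys, xs]), order=1, mode="nearest")
        assert abs(offsets[np.argmin(vals)]) <= 1.0


def test_line_profile_constant_and_inverted():
    img = np.full((20, 20), 7.0)
    prof = sm.line_profile(img, (2.0, 3.0), (15.0, 12.0), width=3)
    np.testing.assert_allclose(prof.intensities, 7.0)
    assert np.all(np.diff(prof.positions) > 0)
    inv = sm.line_profile(img, (2.0, 3.0), (15.0, 12.0), width=3, invert=True)
    np.testing.assert_allclose(inv.intensities, 0.0)


def test_line_profile_endpoint_validation():
    img = np.zeros((10, 10))
    with pytest.raises(ValueError, match="distinct"):
        sm.line_profile(img, (2.0, 2.0), (2.0, 2.0))
    with pytest.raises(ValueError, match="outside"):
        sm.line_profile(img, (0.0, 0.0), (20.0, 5.0))
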