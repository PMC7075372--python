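import pytest
from hypothesis import given, strategies as st

from shiftcheck.geometry import Vector3
from shiftcheck.origin_check import (
    AmbiguousMarkerError,
    ApSurface,
    MarkerNotFoundError,
    MarkerRoleError,
    MarkerSet,
    NamingConfig,
    Verdict,
    check_user_origin,
    classify_fallback,
    contour_centroid,
    expected_user_origin,
    find_marker_contours,
)

from conftest import contour, vec


# -- centroid ---------------------------------------------------------------

def test_centroid_single_point():
    assert contour_centroid(contour("BB", (1, 2, 3))) == vec(1, 2, 3)


def test_centroid_square_symmetry():
    c = contour("BB", (-1, 9, 5), (1, 9, 5), (1, 11, 5), (-1, 11, 5))
    assert contour_centroid(c) == vec(0, 10, 5)


def test_centroid_two_points():
    assert contour_centroid(contour("BB", (0, 0, 0), (2, 4, 6))) == vec(1, 2, 3)


def test_empty_contour_rejected():
    with pytest.raises(ValueError):
        contour("BB")


# -- role matching ----------------------------------------------------------

def _markers(*names):
    offsets = [(120, 20, 10), (-118, 22, 10), (1, -95, 10), (2, 130, 10)]
    return [contour(n, o) for n, o in zip(names, offsets)]


def test_default_patterns_find_all_roles():
    ms = find_marker_contours(_markers("BB LT", "BB RT", "BB ANT"), NamingConfig())
    assert ms.left == vec(120, 20, 10)
    assert ms.right == vec(-118, 22, 10)
    assert ms.ap == vec(1, -95, 10)
    assert ms.ap_surface is ApSurface.ANTERIOR


def test_posterior_marker_detected():
    ms = find_marker_contours(_markers("BB LT", "BB RT", "BB POST"), NamingConfig())
    assert ms.ap_surface is ApSurface.POSTERIOR


def test_case_insensitive_matching():
    ms = find_marker_contours(_markers("bb lt", "Bb Rt", "bb ant"), NamingConfig())
    assert ms.ap_surface is ApSurface.ANTERIOR


def test_missing_role_is_not_evaluable():
    with pytest.raises(MarkerNotFoundError, match="right lateral"):
        find_marker_contours(_markers("BB LT", "BB ANT"), NamingConfig())


def test_duplicate_role_is_ambiguous():
    structs = _markers("BB LT", "BB RT", "BB ANT", "BB LT COPY")
    with pytest.raises(AmbiguousMarkerError, match="BB LT"):
        find_marker_contours(structs, NamingConfig())


def test_anterior_and_posterior_pair_gives_both():
    ms = find_marker_contours(
        _markers("BB LT", "BB RT", "BB ANT", "BB POST"), NamingConfig()
    )
    assert ms.ap_surface is ApSurface.BOTH
    assert ms.ap_secondary is not None


def test_config_validation():
    with pytest.raises(ValueError):
        NamingConfig(tolerance_mm=0.0)
    with pytest.raises(ValueError):
        NamingConfig(ap_patterns=())


# -- geometric fallback -----------------------------------------------------

def test_fallback_classifies_by_x_extremes():
    ms = classify_fallback([vec(-120, 20, 10), vec(118, 22, 10), vec(0, -95, 10)])
    assert ms.left == vec(118, 22, 10)
    assert ms.right == vec(-120, 20, 10)
    assert ms.ap_surface is ApSurface.ANTERIOR


def test_fallback_posterior_by_sign():
    ms = classify_fallback([vec(-120, 20, 10), vec(118, 22, 10), vec(0, 90, 10)])
    assert ms.ap_surface is ApSurface.POSTERIOR


def test_fallback_collinear_in_x_is_degenerate():
    with pytest.raises(MarkerRoleError):
        classify_fallback([vec(0, 0, 0), vec(0, 10, 0), vec(0, -90, 0)])


def test_fallback_surface_marker_off_center_is_degenerate():
    with pytest.raises(MarkerRoleError):
        classify_fallback([vec(-100, 20, 0), vec(100, 20, 0), vec(80, -95, 0)])


def test_fallback_needs_three():
    with pytest.raises(ValueError):
        classify_fallback([vec(0, 0, 0), vec(1, 0, 0)])


# -- intersection rule ------------------------------------------------------

def test_expected_origin_quoted_rule():
    ms = MarkerSet(left=vec(-120, 18, 9), right=vec(118, 22, 11),
                   ap=vec(1.2, -95, 40), ap_surface=ApSurface.ANTERIOR)
    assert expected_user_origin(ms) == vec(1.2, 20.0, 10.0)


def test_expected_origin_left_right_swap_invariant():
    a = MarkerSet(left=vec(-120, 18, 9), right=vec(118, 22, 11),
                  ap=vec(1.2, -95, 40), ap_surface=ApSurface.ANTERIOR)
    b = MarkerSet(left=vec(118, 22, 11), right=vec(-120, 18, 9),
                  ap=vec(1.2, -95, 40), ap_surface=ApSurface.ANTERIOR)
    assert expected_user_origin(a) == expected_user_origin(b)


def test_expected_origin_averages_both_surfaces():
    ms = MarkerSet(left=vec(-120, 18, 9), right=vec(118, 22, 11),
                   ap=vec(2.0, -95, 40), ap_surface=ApSurface.BOTH,
                   ap_secondary=vec(4.0, 130, 40))
    assert expected_user_origin(ms).x == pytest.approx(3.0)


def test_ap_marker_z_is_ignored():
    base = MarkerSet(left=vec(-120, 18, 9), right=vec(118, 22, 11),
                     ap=vec(1.2, -95, 40), ap_surface=ApSurface.ANTERIOR)
    moved = MarkerSet(left=base.left, right=base.right,
                      ap=vec(1.2, -95, 999), ap_surface=ApSurface.ANTERIOR)
    assert expected_user_origin(base) == expected_user_origin(moved)


def test_expected_origin_vertex_order_invariant():
    pts = [(-122, 18, 9), (-118, 18, 9), (-120, 20, 9), (-120, 16, 9)]
    fwd = contour_centroid(contour("BB LT", *pts))
    rev = contour_centroid(contour("BB LT", *reversed(pts)))
    assert fwd.x == pytest.approx(rev.x, abs=1e-12)
    assert fwd.y == pytest.approx(rev.y, abs=1e-12)
    assert fwd.z == pytest.approx(rev.z, abs=1e-12)


# -- verdict ----------------------------------------------------------------

def test_flag_at_smallest_clinical_offset():
    res = check_user_origin(vec(2.7, 0, 0), vec(0, 0, 0), tolerance_mm=2.0)
    assert res.verdict is Verdict.FLAG
    assert res.magnitude_mm == pytest.approx(2.7)


def test_flag_at_largest_clinical_offset():
    res = check_user_origin(vec(0, 0, 82.3), vec(0, 0, 0), tolerance_mm=2.0)
    assert res.verdict is Verdict.FLAG
    assert res.magnitude_mm == pytest.approx(82.3)


def test_exact_match_passes():
    res = check_user_origin(vec(1, 2, 3), vec(1, 2, 3), tolerance_mm=2.0)
    assert res.verdict is Verdict.PASS
    assert res.magnitude_mm == 0.0


def test_delta_sign_convention():
    res = check_user_origin(vec(3, 0, 0), vec(1, 0, 0), tolerance_mm=5.0)
    assert res.per_axis_delta == vec(2, 0, 0)


def test_magnitude_is_norm_of_delta():
    res = check_user_origin(vec(3, 4, 0), vec(0, 0, 0), tolerance_mm=1.0)
    assert res.magnitude_mm == pytest.approx(5.0)
    assert res.verdict is Verdict.FLAG


@given(
    delta=st.tuples(*[st.floats(-100, 100, allow_nan=False)] * 3),
    t1=st.floats(0.1, 50),
    t2=st.floats(0.1, 50),
)
def test_verdict_monotone_in_tolerance(delta, t1, t2):
    lo, hi = sorted((t1, t2))
    expected, actual = vec(*delta), vec(0, 0, 0)
    if check_user_origin(expected, actual, hi).verdict is Verdict.FLAG:
        assert check_user_origin(expected, actual, lo).verdict is Verdict.FLAG


def test_boundary_behaviour():
    tol = 2.0
    just_under = check_user_origin(vec(tol - 1e-9, 0, 0), vec(0, 0, 0), tol)
    just_over = check_user_origin(vec(tol + 1e-9, 0, 0), vec(0, 0, 0), tol)
    at = check_user_origin(vec(tol, 0, 0), vec(0, 0, 0), tol)
    assert just_under.verdict is Verdict.PASS
    assert at.verdict is Verdict.PASS  # FLAG strictly above tolerance
    assert just_over.verdict is Verdict.FLAG
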