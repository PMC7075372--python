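import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from shiftcheck.geometry import (
    NO_SHIFT,
    AxisLabel,
    Frame,
    FrameMismatchError,
    OrientationMatrix,
    PatientPosition,
    Vector3,
    anatomical_labels,
    dicom_to_iec,
    iec_to_dicom,
    orientation_matrix,
)

ALL_POSITIONS = list(PatientPosition)

finite = st.floats(min_value=-1e4, max_value=1e4, allow_nan=False,
                   allow_infinity=False)
vectors = st.tuples(finite, finite, finite)
positions = st.sampled_from(ALL_POSITIONS)


# ---------------------------------------------------------------------------
# independent oracle: compose the anatomical axis definitions for each pose
# with the fixed-room axis definitions, using only cross products.

def oracle_matrix(position: PatientPosition) -> np.ndarray:
    """Room-frame directions of the patient's left/posterior/superior axes,
    derived from the pose name alone (head/feet first; supine/prone/decubitus),
    assembled into the DICOM->IEC matrix as column vectors."""
    Y = np.array([0.0, 1.0, 0.0])  # toward gantry
    Z = np.array([0.0, 0.0, 1.0])  # up
    sup = Y if position.value.startswith("HF") else -Y
    suffix = position.value[2:]
    if suffix in ("S", "P"):
        ant = Z if suffix == "S" else -Z  # face up / face down
        post = -ant
        left = np.cross(post, sup)
    else:
        left = Z if suffix == "DR" else -Z  # right side down -> left points up
        post = np.cross(sup, left)
    return np.column_stack([left, post, sup])


@pytest.mark.parametrize("position", ALL_POSITIONS)
def test_orientation_matrix_matches_axis_composition_oracle(position):
    assert np.array_equal(
        orientation_matrix(position).as_array(), oracle_matrix(position)
    )


@pytest.mark.parametrize("position", ALL_POSITIONS)
def test_orientation_matrix_is_proper_signed_permutation(position):
    m = orientation_matrix(position).as_array()
    assert np.allclose(m @ m.T, np.eye(3))
    assert np.all((np.abs(m) > 0).sum(axis=0) == 1)
    assert np.all((np.abs(m) > 0).sum(axis=1) == 1)
    assert set(np.unique(m[m != 0])) <= {-1.0, 1.0}
    assert np.isclose(np.linalg.det(m), 1.0)


def test_hfs_maps_like_the_axis_table():
    out = dicom_to_iec(Vector3(10, -20, 30), PatientPosition.HFS)
    assert (out.x, out.y, out.z) == (10, 30, 20)
    assert out.frame is Frame.IEC_FIXED


def test_ffs_maps_like_the_axis_table():
    out = dicom_to_iec(Vector3(10, -20, 30), PatientPosition.FFS)
    assert (out.x, out.y, out.z) == (-10, -30, 20)


def test_ffp_row_table():
    # (x, y, z) -> (x, -z, y)
    out = dicom_to_iec(Vector3(1, 2, 3), PatientPosition.FFP)
    assert (out.x, out.y, out.z) == (1, -3, 2)


@pytest.mark.parametrize("position", ALL_POSITIONS)
def test_origin_is_fixed(position):
    out = dicom_to_iec(Vector3(0, 0, 0), position)
    assert (out.x, out.y, out.z) == (0, 0, 0)


def test_iec_to_dicom_inverts_hfs_example():
    out = iec_to_dicom(Vector3(10, 30, 20, Frame.IEC_FIXED), PatientPosition.HFS)
    assert (out.x, out.y, out.z) == (10, -20, 30)


def test_frame_mismatch_is_rejected():
    with pytest.raises(FrameMismatchError):
        dicom_to_iec(Vector3(1, 2, 3, Frame.IEC_FIXED), PatientPosition.HFS)
    with pytest.raises(FrameMismatchError):
        iec_to_dicom(Vector3(1, 2, 3, Frame.DICOM_PATIENT), PatientPosition.HFS)
    with pytest.raises(FrameMismatchError):
        Vector3(1, 2, 3) + Vector3(1, 2, 3, Frame.IEC_FIXED)


def test_unknown_position_code_rejected():
    with pytest.raises(ValueError):
        PatientPosition.from_code("SITTING")
    with pytest.raises(ValueError):
        orientation_matrix("XX")


def test_vector_rejects_non_finite():
    with pytest.raises(ValueError):
        Vector3(float("nan"), 0, 0)
    with pytest.raises(ValueError):
        Vector3(0, float("inf"), 0)


def test_improper_matrix_rejected():
    with pytest.raises(ValueError):
        OrientationMatrix(((1, 0, 0), (0, 1, 0), (0, 0, -1)))  # det = -1
    with pytest.raises(ValueError):
        OrientationMatrix(((1, 1, 0), (0, 0, 1), (0, -1, 0)))


@given(v=vectors, position=positions)
def test_round_trip_is_identity(v, position):
    p = Vector3(*v)
    q = iec_to_dicom(dicom_to_iec(p, position), position)
    assert math.isclose(q.x, p.x, abs_tol=1e-12)
    assert math.isclose(q.y, p.y, abs_tol=1e-12)
    assert math.isclose(q.z, p.z, abs_tol=1e-12)


@given(v=vectors, position=positions)
def test_norm_preserved(v, position):
    p = Vector3(*v)
    assert math.isclose(dicom_to_iec(p, position).norm(), p.norm(),
                        rel_tol=1e-12, abs_tol=1e-12)


@given(a=vectors, b=vectors, position=positions)
def test_linearity(a, b, position):
    pa, pb = Vector3(*a), Vector3(*b)
    lhs = dicom_to_iec(pa + pb, position)
    rhs = dicom_to_iec(pa, position) + dicom_to_iec(pb, position)
    assert math.isclose(lhs.x, rhs.x, abs_tol=1e-9)
    assert math.isclose(lhs.y, rhs.y, abs_tol=1e-9)
    assert math.isclose(lhs.z, rhs.z, abs_tol=1e-9)


def test_hfs_hfp_differ_by_180_about_iec_y():
    rot_y = np.diag([-1.0, 1.0, -1.0])  # 180 degrees about IEC Y
    hfs = orientation_matrix(PatientPosition.HFS).as_array()
    hfp = orientation_matrix(PatientPosition.HFP).as_array()
    assert np.array_equal(hfp, rot_y @ hfs)


def test_hfs_ffs_differ_by_180_about_iec_z():
    rot_z = np.diag([-1.0, -1.0, 1.0])  # 180 degrees about IEC Z
    hfs = orientation_matrix(PatientPosition.HFS).as_array()
    ffs = orientation_matrix(PatientPosition.FFS).as_array()
    assert np.array_equal(ffs, rot_z @ hfs)


# -- anatomical labels ------------------------------------------------------

def test_labels_example_left_inferior():
    labels = anatomical_labels(Vector3(15, 0, -42))
    assert labels == (
        AxisLabel("Left", 15, "lateral"),
        AxisLabel(NO_SHIFT, 0.0, "ant/post"),
        AxisLabel("Inferior", 42, "sup/inf"),
    )


def test_labels_example_right_posterior():
    labels = anatomical_labels(Vector3(-3, 4, 0))
    assert [(l.direction, l.magnitude_mm) for l in labels] == [
        ("Right", 3), ("Posterior", 4), (NO_SHIFT, 0.0)
    ]


def test_labels_zero_vector():
    assert all(l.direction == NO_SHIFT for l in anatomical_labels(Vector3(0, 0, 0)))


def test_labels_zero_threshold():
    labels = anatomical_labels(Vector3(0.49, -0.51, 0.5))
    assert [l.direction for l in labels] == [NO_SHIFT, "Anterior", "Superior"]


def test_labels_require_patient_frame():
    with pytest.raises(FrameMismatchError):
        anatomical_labels(Vector3(1, 2, 3, Frame.IEC_FIXED))


_OPPOSITE = {"Left": "Right", "Right": "Left", "Anterior": "Posterior",
             "Posterior": "Anterior", "Superior": "Inferior",
             "Inferior": "Superior", NO_SHIFT: NO_SHIFT}


@given(v=vectors)
def test_label_negation_flips_direction_words(v):
    p = Vector3(*v)
    for fwd, rev in zip(anatomical_labels(p), anatomical_labels(-p)):
        assert rev.direction == _OPPOSITE[fwd.direction]
        assert math.isclose(rev.magnitude_mm, fwd.magnitude_mm, abs_tol=1e-12)
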