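"""Generate synthetic DICOM bundles (CT + RT Structure Set + RT Plan) with
known ground-truth geometry.

A bundle emulates the simulation workflow: three radiopaque markers (two
lateral, one anterior or posterior), a user origin placed at — or deliberately
offset from — the marker intersection, and one or more beams with a shared
isocenter. Exported coordinates follow the TPS convention of placing the user
origin at the DICOM origin, so an injected ``origin_offset`` shows up exactly
as the deviation the origin check must detect.

Everything is deterministic: the same spec and seed produce identical files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from shiftcheck import _dicom
from shiftcheck.geometry import Frame, PatientPosition, Vector3, dicom_to_iec
from shiftcheck.origin_check import ApSurface

Triple = Tuple[float, float, float]

MAX_JITTER_MM = 0.1
_RING_RADIUS_MM = 2.0
_RING_VERTICES = 8


class FixtureSpecError(ValueError):
    """Inconsistent fixture specification."""


def _vec(t: Sequence[float]) -> Vector3:
    x, y, z = (float(v) for v in t)
    return Vector3(x, y, z, Frame.DICOM_PATIENT)


@dataclass(frozen=True)
class FixtureSpec:
    """Ground-truth geometry for one synthetic bundle (scanner coords, mm)."""

    position: PatientPosition = PatientPosition.HFS
    left_marker: Triple = (120.0, 20.0, 10.0)
    right_marker: Triple = (-118.0, 22.0, 10.0)
    ap_marker: Triple = (1.0, -95.0, 10.0)
    ap_surface: ApSurface = ApSurface.ANTERIOR
    #: optional second surface marker (the opposite surface), for BOTH setups
    ap_secondary_marker: Optional[Triple] = None
    #: displacement of the user origin from the marker intersection
    origin_offset: Triple = (0.0, 0.0, 0.0)
    #: isocenter displacement from the user origin (the shift ground truth)
    isocenter_offset: Triple = (0.0, 0.0, 0.0)
    n_beams: int = 2
    #: per-beam isocenter displacements from the user origin; overrides
    #: isocenter_offset/n_beams when set (used to build multi-isocenter plans)
    beam_isocenter_offsets: Optional[Tuple[Triple, ...]] = None
    roi_names: Tuple[str, ...] = ()
    patient_id: str = "SYN-0001"
    plan_label: str = "PLAN-A"
    jitter_mm: float = 0.0
    seed: int = 0
    tolerance_mm: float = 2.0
    allow_degenerate: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.jitter_mm <= MAX_JITTER_MM:
            raise FixtureSpecError(
                f"jitter must be within [0, {MAX_JITTER_MM}] mm, got {self.jitter_mm}"
            )
        if self.n_beams < 1:
            raise FixtureSpecError("need at least one beam")
        if not self.allow_degenerate:
            self._check_consistency()

    def _check_consistency(self) -> None:
        left, right, ap = map(_vec, (self.left_marker, self.right_marker,
                                     self.ap_marker))
        span = left.x - right.x
        if span <= 0:
            raise FixtureSpecError(
                "left marker must have larger x than right marker (LPS); "
                "pass allow_degenerate=True to build a degenerate fixture"
            )
        if abs(ap.x - (left.x + right.x) / 2.0) > span / 4.0:
            raise FixtureSpecError(
                "surface marker x must lie in the middle half of the lateral "
                "x-interval; pass allow_degenerate=True to override"
            )
        lateral_y = (left.y + right.y) / 2.0
        anterior = ap.y < lateral_y
        if anterior != (self.ap_surface is ApSurface.ANTERIOR) and (
            self.ap_surface is not ApSurface.BOTH
        ):
            raise FixtureSpecError(
                f"ap_surface={self.ap_surface.value} contradicts marker geometry"
            )

    # -- derived ground truth ------------------------------------------------

    def marker_intersection(self) -> Vector3:
        """Apply the origin-placement rule to the true marker centroids."""
        left, right, ap = map(_vec, (self.left_marker, self.right_marker,
                                     self.ap_marker))
        if self.ap_secondary_marker is not None:
            x = (ap.x + _vec(self.ap_secondary_marker).x) / 2.0
        else:
            x = ap.x
        return Vector3(x, (left.y + right.y) / 2.0, (left.z + right.z) / 2.0,
                       Frame.DICOM_PATIENT)

    def user_origin(self) -> Vector3:
        return self.marker_intersection() + _vec(self.origin_offset)

    def isocenters(self) -> Tuple[Vector3, ...]:
        origin = self.user_origin()
        if self.beam_isocenter_offsets is not None:
            return tuple(origin + _vec(o) for o in self.beam_isocenter_offsets)
        return tuple(origin + _vec(self.isocenter_offset)
                     for _ in range(self.n_beams))

    def default_roi_names(self) -> Tuple[str, ...]:
        if self.roi_names:
            return self.roi_names
        ap_name = ("BB POST" if self.ap_surface is ApSurface.POSTERIOR else "BB ANT")
        names = ["BB LT", "BB RT", ap_name]
        if self.ap_secondary_marker is not None:
            names.append("BB POST" if ap_name == "BB ANT" else "BB ANT")
        return tuple(names)

    def ground_truth(self) -> Dict:
        """The exact quantities every downstream check should recover."""
        shift = _vec(self.isocenter_offset)
        offset = _vec(self.origin_offset)
        magnitude = offset.norm()
        iec = dicom_to_iec(shift, self.position)
        return {
            "position": self.position.value,
            "shift_mm": [shift.x, shift.y, shift.z],
            "shift_iec_mm": [iec.x, iec.y, iec.z],
            "origin_offset_mm": [offset.x, offset.y, offset.z],
            "origin_delta_mm": [-offset.x, -offset.y, -offset.z],
            "origin_delta_magnitude_mm": magnitude,
            "tolerance_mm": self.tolerance_mm,
            "expected_verdict": "FLAG" if magnitude > self.tolerance_mm else "PASS",
        }


def perturb_origin(spec: FixtureSpec, offset: Sequence[float]) -> FixtureSpec:
    """Spec with the user origin displaced by ``offset`` from the marker
    intersection; the ground-truth verdict updates accordingly."""
    x, y, z = (float(v) for v in offset)
    return replace(spec, origin_offset=(x, y, z))


@dataclass(frozen=True)
class FixtureBundle:
    """Paths and ground truth for one generated bundle."""

    ct_file: Path
    rtstruct_file: Path
    rtplan_file: Path
    ground_truth_file: Path
    ground_truth: Dict
    frame_of_reference: str
    spec: FixtureSpec


def _marker_ring(center: Vector3, rng: np.random.Generator, jitter: float):
    """Planar 8-vertex ring (axial plane) around a centroid, optional jitter."""
    pts = []
    for k in range(_RING_VERTICES):
        theta = 2.0 * math.pi * k / _RING_VERTICES
        x = center.x + _RING_RADIUS_MM * math.cos(theta)
        y = center.y + _RING_RADIUS_MM * math.sin(theta)
        z = center.z
        if jitter > 0:
            dx, dy, dz = rng.uniform(-jitter, jitter, size=3)
            x, y, z = x + dx, y + dy, z + dz
        pts.extend((x, y, z))
    return pts


def _ct_dataset(spec: FixtureSpec, frame_uid: str, uids: Dict[str, str]) -> _dicom.Dataset:
    ds = _dicom.Dataset()
    ds.SOPClassUID = _dicom.CT_IMAGE_STORAGE
    ds.SOPInstanceUID = uids["ct"]
    ds.Modality = "CT"
    ds.PatientID = spec.patient_id
    ds.PatientName = "Synthetic^Phantom"
    ds.StudyInstanceUID = uids["study"]
    ds.SeriesInstanceUID = uids["ct_series"]
    ds.FrameOfReferenceUID = frame_uid
    ds.PatientPosition = spec.position.value
    ds.ImagePositionPatient = [-8.0, -8.0, 0.0]
    ds.ImageOrientationPatient = [1.0, 0.0, 0.0, 0.0, 1.0, 0.0]
    ds.PixelSpacing = [1.0, 1.0]
    ds.SliceThickness = 2.0
    ds.Rows = 16
    ds.Columns = 16
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelData = b"\x00" * (16 * 16 * 2)
    return ds


def _rtstruct_dataset(
    spec: FixtureSpec, frame_uid: str, uids: Dict[str, str],
    rng: np.random.Generator,
) -> _dicom.Dataset:
    origin = spec.user_origin()
    centers = [_vec(spec.left_marker), _vec(spec.right_marker), _vec(spec.ap_marker)]
    if spec.ap_secondary_marker is not None:
        centers.append(_vec(spec.ap_secondary_marker))
    names = spec.default_roi_names()
    if len(names) != len(centers):
        raise FixtureSpecError(
            f"{len(centers)} markers but {len(names)} ROI names"
        )

    ds = _dicom.Dataset()
    ds.SOPClassUID = _dicom.RT_STRUCTURE_SET_STORAGE
    ds.SOPInstanceUID = uids["rtstruct"]
    ds.Modality = "RTSTRUCT"
    ds.PatientID = spec.patient_id
    ds.PatientName = "Synthetic^Phantom"
    ds.StudyInstanceUID = uids["study"]
    ds.SeriesInstanceUID = uids["rs_series"]
    ds.StructureSetLabel = "SIM MARKERS"

    ref = _dicom.Dataset()
    ref.FrameOfReferenceUID = frame_uid
    ds.ReferencedFrameOfReferenceSequence = [ref]

    roi_seq = []
    contour_seq = []
    for num, (name, center) in enumerate(zip(names, centers), start=1):
        roi = _dicom.Dataset()
        roi.ROINumber = num
        roi.ROIName = name
        roi.ReferencedFrameOfReferenceUID = frame_uid
        roi_seq.append(roi)

        exported = center - origin  # export convention: user origin at (0,0,0)
        plane = _dicom.Dataset()
        plane.ContourGeometricType = "CLOSED_PLANAR"
        plane.ContourData = _marker_ring(exported, rng, spec.jitter_mm)
        plane.NumberOfContourPoints = _RING_VERTICES

        rc = _dicom.Dataset()
        rc.ReferencedROINumber = num
        rc.ContourSequence = [plane]
        contour_seq.append(rc)

    ds.StructureSetROISequence = roi_seq
    ds.ROIContourSequence = contour_seq
    return ds


def _rtplan_dataset(spec: FixtureSpec, frame_uid: str, uids: Dict[str, str]) -> _dicom.Dataset:
    origin = spec.user_origin()
    ds = _dicom.Dataset()
    ds.SOPClassUID = _dicom.RT_PLAN_STORAGE
    ds.SOPInstanceUID = uids["rtplan"]
    ds.Modality = "RTPLAN"
    ds.PatientID = spec.patient_id
    ds.PatientName = "Synthetic^Phantom"
    ds.StudyInstanceUID = uids["study"]
    ds.SeriesInstanceUID = uids["rp_series"]
    ds.FrameOfReferenceUID = frame_uid
    ds.RTPlanLabel = spec.plan_label

    setup = _dicom.Dataset()
    setup.PatientSetupNumber = 1
    setup.PatientPosition = spec.position.value
    ds.PatientSetupSequence = [setup]

    beams = []
    for i, iso in enumerate(spec.isocenters(), start=1):
        exported = iso - origin
        cp = _dicom.Dataset()
        cp.ControlPointIndex = 0
        cp.IsocenterPosition = [exported.x, exported.y, exported.z]
        beam = _dicom.Dataset()
        beam.BeamNumber = i
        beam.BeamName = f"Field {i}"
        beam.ControlPointSequence = [cp]
        beams.append(beam)
    ds.BeamSequence = beams
    return ds


def _uid_from(rng: np.random.Generator) -> str:
    return "2.25." + "".join(str(rng.integers(0, 10)) for _ in range(30))


def generate_bundle(spec: FixtureSpec, out_dir) -> FixtureBundle:
    """Write ct.dcm / rs.dcm / rp.dcm / ground_truth.json into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    frame_uid = _uid_from(rng)
    uids = {key: _uid_from(rng)
            for key in ("study", "ct_series", "rs_series", "rp_series",
                        "ct", "rtstruct", "rtplan")}

    ct = _ct_dataset(spec, frame_uid, uids)
    rs = _rtstruct_dataset(spec, frame_uid, uids, rng)
    rp = _rtplan_dataset(spec, frame_uid, uids)

    ct_file = out / "ct.dcm"
    rs_file = out / "rs.dcm"
    rp_file = out / "rp.dcm"
    _dicom.write_file(ct_file, ct, _dicom.CT_IMAGE_STORAGE)
    _dicom.write_file(rs_file, rs, _dicom.RT_STRUCTURE_SET_STORAGE)
    _dicom.write_file(rp_file, rp, _dicom.RT_PLAN_STORAGE)

    truth = spec.ground_truth()
    truth["frame_of_reference"] = frame_uid
    truth_file = out / "ground_truth.json"
    truth_file.write_text(json.dumps(truth, indent=2) + "\n")

    return FixtureBundle(
        ct_file=ct_file,
        rtstruct_file=rs_file,
        rtplan_file=rp_file,
        ground_truth_file=truth_file,
        ground_truth=truth,
        frame_of_reference=frame_uid,
        spec=spec,
    )


def random_spec(
    rng: np.random.Generator,
    position: Optional[PatientPosition] = None,
    origin_offset: Optional[Triple] = None,
    tolerance_mm: float = 2.0,
) -> FixtureSpec:
    """A plausible random fixture spec (marker layout, isocenter shift)."""
    if position is None:
        position = list(PatientPosition)[int(rng.integers(0, 8))]
    z0 = float(rng.uniform(-200.0, 200.0))
    left = (float(rng.uniform(100.0, 160.0)), float(rng.uniform(-10.0, 40.0)), z0)
    right = (-float(rng.uniform(100.0, 160.0)), left[1] + float(rng.uniform(-6.0, 6.0)),
             z0 + float(rng.uniform(-3.0, 3.0)))
    anterior = bool(rng.integers(0, 2))
    lateral_y = (left[1] + right[1]) / 2.0
    ap_y = lateral_y + (-1 if anterior else 1) * float(rng.uniform(80.0, 140.0))
    ap = (float(rng.uniform(-25.0, 25.0)), ap_y, z0 + float(rng.uniform(-5.0, 5.0)))
    if origin_offset is None:
        origin_offset = tuple(float(v) for v in rng.uniform(-40.0, 40.0, size=3))
    iso_offset = tuple(float(v) for v in rng.uniform(-80.0, 80.0, size=3))
    return FixtureSpec(
        position=position,
        left_marker=left,
        right_marker=right,
        ap_marker=ap,
        ap_surface=ApSurface.ANTERIOR if anterior else ApSurface.POSTERIOR,
        origin_offset=tuple(origin_offset),
        isocenter_offset=iso_offset,
        seed=int(rng.integers(0, 2**31 - 1)),
        tolerance_mm=tolerance_mm,
    )
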