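"""Read plan / structure-set geometry from DICOM files.

All coordinates stay in the DICOM patient frame, in millimeters; no unit
conversion or pixel indexing happens here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

from shiftcheck import _dicom
from shiftcheck.geometry import Frame, PatientPosition, Vector3

log = logging.getLogger(__name__)

#: Beams whose isocenters differ by more than this are a multi-isocenter plan.
ISOCENTER_COINCIDENCE_TOL_MM = 0.01


class DicomIOError(ValueError):
    """Problem reading geometry from a DICOM file."""


class EmptyPlanError(DicomIOError):
    """RT Plan contains no beams with an isocenter."""


class MultiIsocenterError(DicomIOError):
    """Beams disagree on the isocenter; a single shift is undefined."""


@dataclass(frozen=True)
class PlanGeometry:
    """The geometry of one treatment plan needed for shift calculation."""

    plan_id: str
    frame_of_reference: Optional[str]
    position: PatientPosition
    user_origin: Vector3
    isocenter: Vector3
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.user_origin.require_frame(Frame.DICOM_PATIENT)
        self.isocenter.require_frame(Frame.DICOM_PATIENT)


@dataclass(frozen=True)
class StructureContour:
    """One ROI's contour vertices (all planes concatenated), patient frame mm."""

    roi_name: str
    points: Tuple[Vector3, ...]

    def __post_init__(self) -> None:
        if not self.points:
            raise ValueError(f"contour {self.roi_name!r} has no points")
        for p in self.points:
            p.require_frame(Frame.DICOM_PATIENT)


def resolve_user_origin(explicit_origin: Optional[Sequence[float]] = None) -> Vector3:
    """The plan user origin in the exported DICOM patient frame.

    Plain DICOM has no "user origin" attribute; TPS exports conventionally
    shift coordinates so the user origin sits at (0,0,0). An explicit
    override (config or CLI) covers exports that do not follow that
    convention.
    """
    if explicit_origin is None:
        return Vector3(0.0, 0.0, 0.0, Frame.DICOM_PATIENT)
    if isinstance(explicit_origin, Vector3):
        explicit_origin.require_frame(Frame.DICOM_PATIENT)
        return explicit_origin
    vals = [float(v) for v in explicit_origin]
    if len(vals) != 3:
        raise ValueError("user origin override must have exactly 3 components")
    if not all(math.isfinite(v) for v in vals):
        raise ValueError(f"user origin override {vals} has non-finite components")
    return Vector3(vals[0], vals[1], vals[2], Frame.DICOM_PATIENT)


def _triplet(values, what: str) -> Vector3:
    if not isinstance(values, (list, tuple)) or len(values) != 3:
        raise DicomIOError(f"{what}: expected 3 values, got {values!r}")
    return Vector3(float(values[0]), float(values[1]), float(values[2]),
                   Frame.DICOM_PATIENT)


def read_patient_position(path) -> Optional[PatientPosition]:
    """Patient Position from a CT (or any) DICOM file, if present."""
    ds = _dicom.read_file(path)
    code = ds.get("PatientPosition")
    return PatientPosition.from_code(code) if code else None


def read_plan_geometry(
    rtplan_file,
    position: Optional[PatientPosition] = None,
    explicit_origin: Optional[Sequence[float]] = None,
) -> PlanGeometry:
    """Extract plan id, frame of reference, patient position and the unique
    beam isocenter from an RT Plan file.

    ``position`` overrides (or supplies, when absent from the file) the
    Patient Position; it is never silently assumed.
    """
    ds = _dicom.read_file(rtplan_file)

    beams = ds.get("BeamSequence") or []
    isocenters: List[Vector3] = []
    for beam in beams:
        cps = beam.get("ControlPointSequence") or []
        for cp in cps:
            iso = cp.get("IsocenterPosition")
            if iso is not None:
                isocenters.append(_triplet(iso, "IsocenterPosition"))
                break
    if not isocenters:
        raise EmptyPlanError(f"{rtplan_file}: plan has no beams with an isocenter")

    first = isocenters[0]
    for other in isocenters[1:]:
        if (other - first).norm() > ISOCENTER_COINCIDENCE_TOL_MM:
            raise MultiIsocenterError(
                f"{rtplan_file}: beam isocenters differ by "
                f"{(other - first).norm():.3f} mm "
                f"(> {ISOCENTER_COINCIDENCE_TOL_MM} mm); "
                "multi-isocenter plans are unsupported"
            )

    frame_uid = ds.get("FrameOfReferenceUID")
    if frame_uid is None:
        raise DicomIOError(f"{rtplan_file}: missing FrameOfReferenceUID")

    file_position = None
    for setup in ds.get("PatientSetupSequence") or []:
        code = setup.get("PatientPosition")
        if code:
            file_position = PatientPosition.from_code(code)
            break
    if position is None:
        position = file_position
    if position is None:
        raise DicomIOError(
            f"{rtplan_file}: Patient Position not present in plan; "
            "supply it explicitly (config/CLI)"
        )

    return PlanGeometry(
        plan_id=str(ds.get("RTPlanLabel") or ds.get("SOPInstanceUID") or "plan"),
        frame_of_reference=str(frame_uid),
        position=position,
        user_origin=resolve_user_origin(explicit_origin),
        isocenter=first,
        patient_id=str(ds.get("PatientID") or ""),
    )


def read_structure_set(rtstruct_file) -> Tuple[List[StructureContour], Optional[str]]:
    """All ROIs with contour data, plus the structure set's frame of reference.

    ROIs without contour data are skipped with a logged warning.
    """
    ds = _dicom.read_file(rtstruct_file)

    names = {}
    frame_uid = None
    for roi in ds.get("StructureSetROISequence") or []:
        num = roi.get("ROINumber")
        if num is not None:
            names[int(num)] = str(roi.get("ROIName") or f"ROI {num}")
        if frame_uid is None and roi.get("ReferencedFrameOfReferenceUID"):
            frame_uid = str(roi.ReferencedFrameOfReferenceUID)
    if frame_uid is None:
        for ref in ds.get("ReferencedFrameOfReferenceSequence") or []:
            if ref.get("FrameOfReferenceUID"):
                frame_uid = str(ref.FrameOfReferenceUID)
                break

    contours: List[StructureContour] = []
    seen = set()
    for rc in ds.get("ROIContourSequence") or []:
        num = rc.get("ReferencedROINumber")
        name = names.get(int(num), f"ROI {num}") if num is not None else "ROI ?"
        seen.add(int(num) if num is not None else -1)
        points: List[Vector3] = []
        for plane in rc.get("ContourSequence") or []:
            data = plane.get("ContourData")
            if data is None:
                continue
            if isinstance(data, (int, float)):
                data = [data]
            if len(data) % 3 != 0:
                raise DicomIOError(
                    f"{rtstruct_file}: ROI {name!r} ContourData length "
                    f"{len(data)} is not a multiple of 3"
                )
            for i in range(0, len(data), 3):
                points.append(
                    Vector3(float(data[i]), float(data[i + 1]), float(data[i + 2]),
                            Frame.DICOM_PATIENT)
                )
        if not points:
            log.warning("ROI %r has no contour data; skipped", name)
            continue
        contours.append(StructureContour(roi_name=name, points=tuple(points)))

    for num, name in names.items():
        if num not in seen:
            log.warning("ROI %r has no contour data; skipped", name)

    return contours, frame_uid


def validate_frame_of_reference(a: PlanGeometry, b: PlanGeometry) -> bool:
    """True iff both plans share a (present) Frame of Reference UID."""
    if not a.frame_of_reference or not b.frame_of_reference:
        return False
    return a.frame_of_reference == b.frame_of_reference
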