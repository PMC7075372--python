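"""Build and render the "Treat Sheet": couch-shift instructions plus checklist.

Shift values are reported in centimeters, always — the unit is hardcoded to
close off the wrong-unit error pathway. Directions are given in anatomical
terms (Left/Right, Anterior/Posterior, Superior/Inferior) with the IEC
fixed-frame components included as a secondary line. Computed values may be
overridden for in-room setups, but the original values are always retained
and the sheet visibly marks the override.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, replace
from datetime import datetime
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Optional, Sequence, Tuple

from shiftcheck import _pdf
from shiftcheck.dicom_io import PlanGeometry, validate_frame_of_reference
from shiftcheck.geometry import (
    NO_SHIFT,
    ZERO_SHIFT_THRESHOLD_MM,
    Frame,
    PatientPosition,
    Vector3,
    anatomical_labels,
    dicom_to_iec,
)

DEFAULT_CHECKLIST = (
    "Verify patient identity with two identifiers",
    "Confirm patient position matches the plan",
    "Align lasers to the simulation marks before shifting",
    "Apply the shifts listed above (centimeters)",
    "Imaging per departmental protocol before beam-on",
)

OVERRIDE_BANNER = "MANUAL OVERRIDE"

_AXIS_TITLES = {"lateral": "Lateral", "ant/post": "Ant/Post", "sup/inf": "Sup/Inf"}


class Source(enum.Enum):
    COMPUTED = "COMPUTED"
    OVERRIDDEN = "OVERRIDDEN"


def _round_cm(mm: float) -> float:
    """mm → cm, two decimals, round-half-even."""
    return float(Decimal(repr(mm / 10.0)).quantize(Decimal("0.01"), ROUND_HALF_EVEN))


@dataclass(frozen=True)
class AxisEntry:
    """One labeled shift component in centimeters."""

    axis_role: str  # lateral | ant/post | sup/inf
    direction: str  # Left/Right, Anterior/Posterior, Superior/Inferior, No shift
    value_cm: float

    def __post_init__(self) -> None:
        if self.value_cm < 0:
            raise ValueError("shift magnitudes are non-negative")

    def display(self) -> str:
        if self.direction == NO_SHIFT:
            return f"{NO_SHIFT} (0.00 cm)"
        return f"{self.direction} {self.value_cm:.2f} cm"


@dataclass(frozen=True)
class ShiftInstruction:
    """The three labeled shift entries plus IEC fixed-frame components."""

    entries: Tuple[AxisEntry, AxisEntry, AxisEntry]
    iec_components: Vector3  # IEC_FIXED, mm
    source: Source = Source.COMPUTED

    def __post_init__(self) -> None:
        self.iec_components.require_frame(Frame.IEC_FIXED)

    def iec_display_cm(self) -> str:
        v = self.iec_components
        return (
            f"{v.x / 10.0:+.2f}, {v.y / 10.0:+.2f}, {v.z / 10.0:+.2f} cm"
        )


@dataclass(frozen=True)
class OverrideRecord:
    """Audit record kept whenever computed values are replaced."""

    operator: str
    timestamp: str
    original: ShiftInstruction
    reason: str = ""


@dataclass(frozen=True)
class TreatSheet:
    patient_id: str
    plan_id: str
    position: PatientPosition
    instruction: ShiftInstruction
    checklist: Tuple[str, ...] = DEFAULT_CHECKLIST
    override_record: Optional[OverrideRecord] = None

    def __post_init__(self) -> None:
        if self.instruction.source is Source.OVERRIDDEN and self.override_record is None:
            raise ValueError("overridden instruction requires an override record")


def compute_shift_vector(user_origin: Vector3, isocenter: Vector3) -> Vector3:
    """Displacement from the user origin (setup marks) to the isocenter, mm."""
    user_origin.require_frame(Frame.DICOM_PATIENT)
    isocenter.require_frame(Frame.DICOM_PATIENT)
    return isocenter - user_origin


def to_instruction(
    delta: Vector3,
    position: PatientPosition,
    zero_threshold_mm: float = ZERO_SHIFT_THRESHOLD_MM,
) -> ShiftInstruction:
    """Convert a patient-frame displacement (mm) into centimeter instructions."""
    delta.require_frame(Frame.DICOM_PATIENT)
    entries = tuple(
        AxisEntry(lbl.axis_role, lbl.direction, _round_cm(lbl.magnitude_mm))
        for lbl in anatomical_labels(delta, zero_threshold_mm)
    )
    return ShiftInstruction(
        entries=entries,
        iec_components=dicom_to_iec(delta, position),
        source=Source.COMPUTED,
    )


def plan_to_plan_shift(a: PlanGeometry, b: PlanGeometry) -> ShiftInstruction:
    """Shift taking the couch from plan ``a``'s isocenter to plan ``b``'s.

    Both plans must share a frame of reference (same CT scan) and patient
    position.
    """
    if not validate_frame_of_reference(a, b):
        raise ValueError(
            "plan-to-plan shifts are undefined across frames of reference: "
            f"{a.frame_of_reference!r} vs {b.frame_of_reference!r}"
        )
    if a.position is not b.position:
        raise ValueError(
            f"patient position mismatch: {a.position.value} vs {b.position.value}"
        )
    return to_instruction(b.isocenter - a.isocenter, a.position)


def make_treat_sheet(
    plan: PlanGeometry,
    checklist: Optional[Sequence[str]] = None,
    instruction: Optional[ShiftInstruction] = None,
) -> TreatSheet:
    """Assemble a sheet for one plan (origin→isocenter shift by default)."""
    if instruction is None:
        delta = compute_shift_vector(plan.user_origin, plan.isocenter)
        instruction = to_instruction(delta, plan.position)
    return TreatSheet(
        patient_id=plan.patient_id,
        plan_id=plan.plan_id,
        position=plan.position,
        instruction=instruction,
        checklist=tuple(checklist) if checklist is not None else DEFAULT_CHECKLIST,
    )


def apply_override(
    sheet: TreatSheet,
    new_values_cm: Sequence[float],
    operator: str,
    timestamp: Optional[str] = None,
    reason: str = "",
) -> TreatSheet:
    """Replace computed shifts with manual values (signed cm on the patient
    x/y/z axes), keeping the original values in the audit record."""
    if sheet.instruction.source is not Source.COMPUTED:
        raise ValueError("sheet has already been overridden")
    if not operator or not str(operator).strip():
        raise ValueError("override requires an operator id")
    vals = [float(v) for v in new_values_cm]
    if len(vals) != 3:
        raise ValueError("override needs exactly 3 values (lateral, ant/post, sup/inf)")
    delta_mm = Vector3(vals[0] * 10.0, vals[1] * 10.0, vals[2] * 10.0,
                       Frame.DICOM_PATIENT)
    new_instruction = replace(
        to_instruction(delta_mm, sheet.position), source=Source.OVERRIDDEN
    )
    record = OverrideRecord(
        operator=str(operator),
        timestamp=timestamp or datetime.now().isoformat(timespec="seconds"),
        original=sheet.instruction,
        reason=reason,
    )
    return replace(sheet, instruction=new_instruction, override_record=record)


# --------------------------------------------------------------------------
# rendering


def _sheet_lines(sheet: TreatSheet) -> list:
    """Common (text, size, bold) line list for the text and PDF renderers."""
    lines = [
        ("TREAT SHEET - pre-treatment shifts and checklist", 16, True),
        ("", 8, False),
        (f"Patient ID: {sheet.patient_id}", 11, False),
        (f"Plan: {sheet.plan_id}", 11, False),
        (f"Patient position: {sheet.position.value}", 11, False),
        ("", 8, False),
    ]
    if sheet.instruction.source is Source.OVERRIDDEN:
        rec = sheet.override_record
        lines.append((f"*** {OVERRIDE_BANNER} ***", 14, True))
        lines.append(
            (f"Values entered by {rec.operator} at {rec.timestamp}"
             + (f" ({rec.reason})" if rec.reason else ""), 10, False)
        )
        lines.append(("Original values: "
                      + " / ".join(e.display() for e in rec.original.entries),
                      10, False))
        lines.append(("", 8, False))
    lines.append(("Shifts from setup marks to isocenter (centimeters):", 12, True))
    for entry in sheet.instruction.entries:
        title = _AXIS_TITLES.get(entry.axis_role, entry.axis_role)
        lines.append((f"  {title + ':':<10} {entry.display()}", 12, False))
    lines.append(
        (f"  IEC fixed frame (X, Y, Z): {sheet.instruction.iec_display_cm()}",
         10, False)
    )
    lines.append(("", 8, False))
    lines.append(("Checklist:", 12, True))
    for item in sheet.checklist:
        lines.append((f"  [ ] {item}", 11, False))
    return lines


def _render_text(sheet: TreatSheet) -> bytes:
    return ("\n".join(text for text, _, _ in _sheet_lines(sheet)) + "\n").encode("utf-8")


def _instruction_to_dict(instr: ShiftInstruction) -> dict:
    return {
        "source": instr.source.value,
        "unit": "cm",
        "entries": [
            {
                "axis": e.axis_role,
                "direction": e.direction,
                "value": e.value_cm,
                "unit": "cm",
            }
            for e in instr.entries
        ],
        "iec_fixed": {
            "unit": "cm",
            "x": instr.iec_components.x / 10.0,
            "y": instr.iec_components.y / 10.0,
            "z": instr.iec_components.z / 10.0,
        },
        # exact model values; key spelled out to keep unit tokens out of shift lines
        "iec_fixed_millimeters": [
            instr.iec_components.x,
            instr.iec_components.y,
            instr.iec_components.z,
        ],
    }


def _instruction_from_dict(data: dict) -> ShiftInstruction:
    entries = tuple(
        AxisEntry(e["axis"], e["direction"], float(e["value"]))
        for e in data["entries"]
    )
    x, y, z = (float(v) for v in data["iec_fixed_millimeters"])
    return ShiftInstruction(
        entries=entries,
        iec_components=Vector3(x, y, z, Frame.IEC_FIXED),
        source=Source(data["source"]),
    )


def sheet_to_dict(sheet: TreatSheet) -> dict:
    data = {
        "patient_id": sheet.patient_id,
        "plan_id": sheet.plan_id,
        "patient_position": sheet.position.value,
        "instruction": _instruction_to_dict(sheet.instruction),
        "checklist": list(sheet.checklist),
        "override_record": None,
    }
    if sheet.override_record is not None:
        rec = sheet.override_record
        data["override_record"] = {
            "operator": rec.operator,
            "timestamp": rec.timestamp,
            "reason": rec.reason,
            "original": _instruction_to_dict(rec.original),
        }
    return data


def sheet_from_dict(data: dict) -> TreatSheet:
    record = None
    if data.get("override_record"):
        rec = data["override_record"]
        record = OverrideRecord(
            operator=rec["operator"],
            timestamp=rec["timestamp"],
            original=_instruction_from_dict(rec["original"]),
            reason=rec.get("reason", ""),
        )
    return TreatSheet(
        patient_id=data["patient_id"],
        plan_id=data["plan_id"],
        position=PatientPosition.from_code(data["patient_position"]),
        instruction=_instruction_from_dict(data["instruction"]),
        checklist=tuple(data["checklist"]),
        override_record=record,
    )


def sheet_from_json(payload: bytes | str) -> TreatSheet:
    if isinstance(payload, bytes):
        payload = payload.decode("utf-8")
    return sheet_from_dict(json.loads(payload))


def render_treat_sheet(sheet: TreatSheet, fmt: str = "text") -> bytes:
    """Render the sheet as ``text``, ``pdf`` or ``json`` document bytes."""
    if fmt == "text":
        return _render_text(sheet)
    if fmt == "pdf":
        return _pdf.render_pdf(_sheet_lines(sheet))
    if fmt == "json":
        return (json.dumps(sheet_to_dict(sheet), indent=2) + "\n").encode("utf-8")
    raise ValueError(f"unknown format {fmt!r}; expected text, pdf or json")
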