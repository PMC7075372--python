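"""Coordinate conventions and patient-orientation-aware transforms.

Two frames are used throughout:

* ``DICOM_PATIENT`` — the DICOM patient coordinate system (LPS): +x toward
  the patient's left, +y toward posterior, +z toward superior, millimeters.
* ``IEC_FIXED`` — the IEC 61217 fixed room system: +X toward the observer's
  right when facing the gantry, +Y toward the gantry, +Z up, millimeters.

The mapping between the two depends on how the patient lies on the couch
(the DICOM Patient Position code). Every vector carries its frame so that a
frame/sign confusion — the exact error class these tools exist to remove —
cannot pass silently.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence, Tuple

import numpy as np

#: Components smaller than this (mm) are reported as "No shift".
ZERO_SHIFT_THRESHOLD_MM = 0.5


class Frame(enum.Enum):
    """Coordinate frame a :class:`Vector3` is expressed in."""

    DICOM_PATIENT = "DICOM_PATIENT"
    IEC_FIXED = "IEC_FIXED"


class FrameMismatchError(ValueError):
    """Raised when an operation receives a vector in the wrong frame."""


class PatientPosition(enum.Enum):
    """The eight standard DICOM patient position codes."""

    HFS = "HFS"  # head first, supine
    HFP = "HFP"  # head first, prone
    FFS = "FFS"  # feet first, supine
    FFP = "FFP"  # feet first, prone
    HFDR = "HFDR"  # head first, decubitus right
    HFDL = "HFDL"  # head first, decubitus left
    FFDR = "FFDR"  # feet first, decubitus right
    FFDL = "FFDL"  # feet first, decubitus left

    @classmethod
    def from_code(cls, code: str) -> "PatientPosition":
        try:
            return cls(code.strip().upper())
        except ValueError:
            raise ValueError(
                f"unknown patient position code {code!r}; expected one of "
                + ", ".join(p.value for p in cls)
            ) from None


@dataclass(frozen=True)
class Vector3:
    """A point or displacement in a named frame, millimeters."""

    x: float
    y: float
    z: float
    frame: Frame = Frame.DICOM_PATIENT

    def __post_init__(self) -> None:
        for name in ("x", "y", "z"):
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or not math.isfinite(v):
                raise ValueError(f"component {name}={v!r} is not a finite number")
        if not isinstance(self.frame, Frame):
            raise TypeError(f"frame must be a Frame, got {self.frame!r}")

    def require_frame(self, frame: Frame) -> None:
        if self.frame is not frame:
            raise FrameMismatchError(
                f"expected vector in {frame.value}, got {self.frame.value}"
            )

    def to_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @classmethod
    def from_array(cls, a: Sequence[float], frame: Frame) -> "Vector3":
        x, y, z = (float(v) for v in a)
        return cls(x, y, z, frame)

    def __add__(self, other: "Vector3") -> "Vector3":
        self._check_same_frame(other)
        return replace(self, x=self.x + other.x, y=self.y + other.y, z=self.z + other.z)

    def __sub__(self, other: "Vector3") -> "Vector3":
        self._check_same_frame(other)
        return replace(self, x=self.x - other.x, y=self.y - other.y, z=self.z - other.z)

    def __neg__(self) -> "Vector3":
        return replace(self, x=-self.x, y=-self.y, z=-self.z)

    def norm(self) -> float:
        return math.hypot(self.x, self.y, self.z)

    def _check_same_frame(self, other: "Vector3") -> None:
        if not isinstance(other, Vector3):
            raise TypeError(f"expected Vector3, got {type(other).__name__}")
        if self.frame is not other.frame:
            raise FrameMismatchError(
                f"cannot mix frames {self.frame.value} and {other.frame.value}"
            )


@dataclass(frozen=True)
class OrientationMatrix:
    """A signed-permutation rotation mapping DICOM patient axes to IEC axes.

    Rows are the IEC X/Y/Z axes expressed in DICOM patient coordinates.
    """

    rows: Tuple[Tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        m = self.as_array()
        if m.shape != (3, 3):
            raise ValueError("orientation matrix must be 3x3")
        for axis in (0, 1):
            counts = (np.abs(m) > 0).sum(axis=axis)
            if not np.all(counts == 1):
                raise ValueError("orientation matrix must be a signed permutation")
        if not np.all(np.isin(m[m != 0], (-1, 1))):
            raise ValueError("nonzero entries must be +1 or -1")
        if round(float(np.linalg.det(m))) != 1:
            raise ValueError("orientation matrix must be a proper rotation (det=+1)")

    def as_array(self) -> np.ndarray:
        return np.array(self.rows, dtype=float)

    def apply(self, v: Sequence[float]) -> np.ndarray:
        return self.as_array() @ np.asarray(v, dtype=float)

    def inverse(self) -> "OrientationMatrix":
        inv = self.as_array().T.astype(int)
        return OrientationMatrix(tuple(tuple(int(c) for c in row) for row in inv))


# (x,y,z)_DICOM -> (X,Y,Z)_IEC for each patient position. Each entry is the
# unique proper rotation consistent with the named pose; validated by the
# OrientationMatrix invariants at import time.
_ORIENTATION_TABLE: dict[PatientPosition, Tuple[Tuple[int, int, int], ...]] = {
    # supine / prone
    PatientPosition.HFS: ((1, 0, 0), (0, 0, 1), (0, -1, 0)),  # (x, z, -y)
    PatientPosition.HFP: ((-1, 0, 0), (0, 0, 1), (0, 1, 0)),  # (-x, z, y)
    PatientPosition.FFS: ((-1, 0, 0), (0, 0, -1), (0, -1, 0)),  # (-x, -z, -y)
    PatientPosition.FFP: ((1, 0, 0), (0, 0, -1), (0, 1, 0)),  # (x, -z, y)
    # decubitus
    PatientPosition.HFDR: ((0, 1, 0), (0, 0, 1), (1, 0, 0)),  # (y, z, x)
    PatientPosition.HFDL: ((0, -1, 0), (0, 0, 1), (-1, 0, 0)),  # (-y, z, -x)
    PatientPosition.FFDR: ((0, -1, 0), (0, 0, -1), (1, 0, 0)),  # (-y, -z, x)
    PatientPosition.FFDL: ((0, 1, 0), (0, 0, -1), (-1, 0, 0)),  # (y, -z, -x)
}

_ORIENTATION_MATRICES = {
    pos: OrientationMatrix(rows) for pos, rows in _ORIENTATION_TABLE.items()
}


def orientation_matrix(position: PatientPosition) -> OrientationMatrix:
    """Return the DICOM→IEC rotation for a patient position code."""
    if isinstance(position, str):
        position = PatientPosition.from_code(position)
    try:
        return _ORIENTATION_MATRICES[position]
    except KeyError:
        raise ValueError(f"unknown patient position {position!r}") from None


def dicom_to_iec(v: Vector3, position: PatientPosition) -> Vector3:
    """Transform a DICOM patient-frame vector into the IEC 61217 fixed frame."""
    v.require_frame(Frame.DICOM_PATIENT)
    out = orientation_matrix(position).apply(v.to_array())
    return Vector3.from_array(out, Frame.IEC_FIXED)


def iec_to_dicom(v: Vector3, position: PatientPosition) -> Vector3:
    """Inverse of :func:`dicom_to_iec` (exact, since the matrix is orthogonal)."""
    v.require_frame(Frame.IEC_FIXED)
    out = orientation_matrix(position).inverse().apply(v.to_array())
    return Vector3.from_array(out, Frame.DICOM_PATIENT)


#: (negative direction word, positive direction word, axis role) per LPS axis.
_AXIS_WORDS = (
    ("Right", "Left", "lateral"),
    ("Anterior", "Posterior", "ant/post"),
    ("Inferior", "Superior", "sup/inf"),
)

NO_SHIFT = "No shift"


@dataclass(frozen=True)
class AxisLabel:
    """One axis of a displacement, as a direction word and magnitude in mm."""

    direction: str
    magnitude_mm: float
    axis_role: str


def anatomical_labels(
    delta: Vector3, zero_threshold_mm: float = ZERO_SHIFT_THRESHOLD_MM
) -> Tuple[AxisLabel, AxisLabel, AxisLabel]:
    """Label each axis of a patient-frame displacement with its direction word.

    Components with magnitude below ``zero_threshold_mm`` are labeled
    ``"No shift"`` with zero magnitude.
    """
    delta.require_frame(Frame.DICOM_PATIENT)
    labels = []
    for value, (neg_word, pos_word, role) in zip(
        (delta.x, delta.y, delta.z), _AXIS_WORDS
    ):
        if abs(value) < zero_threshold_mm:
            labels.append(AxisLabel(NO_SHIFT, 0.0, role))
        else:
            word = pos_word if value > 0 else neg_word
            labels.append(AxisLabel(word, abs(value), role))
    return tuple(labels)


def axis_roles() -> Iterable[str]:
    """The three axis roles in reporting order."""
    return tuple(role for _, _, role in _AXIS_WORDS)
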