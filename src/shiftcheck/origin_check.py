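"""Verify that the plan user origin sits at the simulation marker intersection.

The expected user origin is derived from the three marker contours: the two
lateral markers fix the anterior/posterior (y) and superior/inferior (z)
coordinates through their averages, and the anterior-or-posterior surface
marker fixes the lateral (x) coordinate. The surface marker's own y and z are
deliberately ignored. Plans whose actual user origin deviates from that point
by more than the tolerance are flagged.
"""

from __future__ import annotations

import enum
import fnmatch
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

from shiftcheck.dicom_io import StructureContour
from shiftcheck.geometry import Frame, Vector3

DEFAULT_TOLERANCE_MM = 2.0

DEFAULT_LEFT_PATTERNS = ("*BB*LT*", "*BB*LEFT*", "*MARKER*LT*")
DEFAULT_RIGHT_PATTERNS = ("*BB*RT*", "*BB*RIGHT*", "*MARKER*RT*")
DEFAULT_AP_PATTERNS = ("*BB*ANT*", "*BB*POST*", "*MARKER*ANT*", "*MARKER*POST*")
# Patterns within ap_patterns that specifically indicate a posterior marker.
_POSTERIOR_HINTS = ("*POST*",)


class MarkerRoleError(ValueError):
    """The marker set cannot be assembled; the check is NOT-EVALUABLE."""


class MarkerNotFoundError(MarkerRoleError):
    """A required marker role has no matching contour."""


class AmbiguousMarkerError(MarkerRoleError):
    """More than one contour matches a marker role."""


class ApSurface(enum.Enum):
    ANTERIOR = "ANTERIOR"
    POSTERIOR = "POSTERIOR"
    BOTH = "BOTH"


class Verdict(enum.Enum):
    PASS = "PASS"
    FLAG = "FLAG"


@dataclass(frozen=True)
class NamingConfig:
    """Marker naming convention (case-insensitive globs) and check tolerance."""

    lateral_left_patterns: Tuple[str, ...] = DEFAULT_LEFT_PATTERNS
    lateral_right_patterns: Tuple[str, ...] = DEFAULT_RIGHT_PATTERNS
    ap_patterns: Tuple[str, ...] = DEFAULT_AP_PATTERNS
    tolerance_mm: float = DEFAULT_TOLERANCE_MM

    def __post_init__(self) -> None:
        if not self.tolerance_mm > 0:
            raise ValueError(f"tolerance must be > 0, got {self.tolerance_mm}")
        for name in ("lateral_left_patterns", "lateral_right_patterns", "ap_patterns"):
            if not getattr(self, name):
                raise ValueError(f"{name} must be non-empty")

    @classmethod
    def from_mapping(cls, data: dict) -> "NamingConfig":
        kwargs = {}
        for key in ("lateral_left_patterns", "lateral_right_patterns", "ap_patterns"):
            if key in data:
                kwargs[key] = tuple(data[key])
        if "tolerance_mm" in data:
            kwargs["tolerance_mm"] = float(data["tolerance_mm"])
        return cls(**kwargs)


@dataclass(frozen=True)
class MarkerSet:
    """Centroids of the three simulation markers with their assigned roles."""

    left: Vector3
    right: Vector3
    ap: Vector3
    ap_surface: ApSurface
    #: retained when both an anterior and a posterior marker exist
    ap_secondary: Optional[Vector3] = None

    def __post_init__(self) -> None:
        if self.left == self.right:
            raise ValueError("left and right lateral markers coincide")
        if self.ap_surface is ApSurface.BOTH and self.ap_secondary is None:
            raise ValueError("ap_surface=BOTH requires both centroids")


@dataclass(frozen=True)
class OriginCheckResult:
    """Outcome of comparing the expected and actual user origin."""

    expected_origin: Vector3
    actual_origin: Vector3
    per_axis_delta: Vector3
    magnitude_mm: float
    tolerance_mm: float
    verdict: Verdict

    def to_dict(self) -> dict:
        return {
            "expected_origin_mm": [self.expected_origin.x, self.expected_origin.y,
                                   self.expected_origin.z],
            "actual_origin_mm": [self.actual_origin.x, self.actual_origin.y,
                                 self.actual_origin.z],
            "per_axis_delta_mm": [self.per_axis_delta.x, self.per_axis_delta.y,
                                  self.per_axis_delta.z],
            "magnitude_mm": self.magnitude_mm,
            "tolerance_mm": self.tolerance_mm,
            "verdict": self.verdict.value,
        }


def contour_centroid(contour: StructureContour) -> Vector3:
    """Arithmetic mean of all contour vertices, per axis."""
    n = len(contour.points)
    sx = sum(p.x for p in contour.points)
    sy = sum(p.y for p in contour.points)
    sz = sum(p.z for p in contour.points)
    return Vector3(sx / n, sy / n, sz / n, Frame.DICOM_PATIENT)


def _matches(name: str, patterns: Iterable[str]) -> bool:
    upper = name.upper()
    return any(fnmatch.fnmatchcase(upper, p.upper()) for p in patterns)


def _match_role(
    structures: Sequence[StructureContour], patterns: Iterable[str]
) -> List[StructureContour]:
    return [s for s in structures if _matches(s.roi_name, patterns)]


def find_marker_contours(
    structures: Sequence[StructureContour], cfg: NamingConfig
) -> MarkerSet:
    """Assign marker roles by the naming convention.

    Exactly one contour must match the left-lateral and right-lateral roles.
    The AP role accepts one anterior or one posterior marker; when one of
    each is present, both centroids are kept (``ap_surface=BOTH``).
    """
    left = _match_role(structures, cfg.lateral_left_patterns)
    right = _match_role(structures, cfg.lateral_right_patterns)
    ap = _match_role(structures, cfg.ap_patterns)

    for role, found in (("left lateral", left), ("right lateral", right)):
        if not found:
            raise MarkerNotFoundError(f"marker not found: {role}")
        if len(found) > 1:
            raise AmbiguousMarkerError(
                f"ambiguous {role} marker: "
                + ", ".join(repr(s.roi_name) for s in found)
            )
    if not ap:
        raise MarkerNotFoundError("marker not found: anterior/posterior")

    if len(ap) == 1:
        posterior = _matches(ap[0].roi_name, _POSTERIOR_HINTS)
        return MarkerSet(
            left=contour_centroid(left[0]),
            right=contour_centroid(right[0]),
            ap=contour_centroid(ap[0]),
            ap_surface=ApSurface.POSTERIOR if posterior else ApSurface.ANTERIOR,
        )
    if len(ap) == 2:
        post = [s for s in ap if _matches(s.roi_name, _POSTERIOR_HINTS)]
        ante = [s for s in ap if not _matches(s.roi_name, _POSTERIOR_HINTS)]
        if len(post) == 1 and len(ante) == 1:
            return MarkerSet(
                left=contour_centroid(left[0]),
                right=contour_centroid(right[0]),
                ap=contour_centroid(ante[0]),
                ap_surface=ApSurface.BOTH,
                ap_secondary=contour_centroid(post[0]),
            )
    raise AmbiguousMarkerError(
        "ambiguous anterior/posterior marker: "
        + ", ".join(repr(s.roi_name) for s in ap)
    )


def classify_fallback(centroids: Sequence[Vector3]) -> MarkerSet:
    """Assign roles geometrically when contour names are uninformative.

    The two centroids with extreme x are the lateral pair (smaller x is the
    patient-right marker, larger x the patient-left marker, per LPS); the
    remaining one is the surface marker, anterior when its y is below the
    lateral mean, posterior when above. The surface marker's x must lie in
    the middle half of the lateral x-interval, otherwise roles are ambiguous.
    """
    if len(centroids) != 3:
        raise ValueError(f"expected exactly 3 centroids, got {len(centroids)}")
    for c in centroids:
        c.require_frame(Frame.DICOM_PATIENT)

    ordered = sorted(centroids, key=lambda c: c.x)
    right, ap, left = ordered
    span = left.x - right.x
    if span <= 0:
        raise MarkerRoleError("degenerate marker configuration: collinear in x")
    center = (left.x + right.x) / 2.0
    if abs(ap.x - center) > span / 4.0:
        raise MarkerRoleError(
            "degenerate marker configuration: surface marker x is not between "
            "the lateral markers"
        )
    lateral_y = (left.y + right.y) / 2.0
    surface = ApSurface.ANTERIOR if ap.y - lateral_y < 0 else ApSurface.POSTERIOR
    return MarkerSet(left=left, right=right, ap=ap, ap_surface=surface)


def expected_user_origin(markers: MarkerSet) -> Vector3:
    """The point where the user origin should have been placed.

    y and z are the lateral-marker averages; x comes from the surface
    marker (averaged over both when anterior and posterior markers coexist).
    """
    if markers.ap_surface is ApSurface.BOTH:
        x = (markers.ap.x + markers.ap_secondary.x) / 2.0
    else:
        x = markers.ap.x
    y = (markers.left.y + markers.right.y) / 2.0
    z = (markers.left.z + markers.right.z) / 2.0
    return Vector3(x, y, z, Frame.DICOM_PATIENT)


def check_user_origin(
    expected: Vector3, actual: Vector3, tolerance_mm: float = DEFAULT_TOLERANCE_MM
) -> OriginCheckResult:
    """Compare expected vs. actual user origin; FLAG when the Euclidean
    deviation exceeds the tolerance."""
    expected.require_frame(Frame.DICOM_PATIENT)
    actual.require_frame(Frame.DICOM_PATIENT)
    if not tolerance_mm > 0:
        raise ValueError(f"tolerance must be > 0, got {tolerance_mm}")
    delta = expected - actual
    magnitude = delta.norm()
    verdict = Verdict.FLAG if magnitude > tolerance_mm else Verdict.PASS
    return OriginCheckResult(
        expected_origin=expected,
        actual_origin=actual,
        per_axis_delta=delta,
        magnitude_mm=magnitude,
        tolerance_mm=tolerance_mm,
        verdict=verdict,
    )


def run_origin_check(
    structures: Sequence[StructureContour],
    actual_origin: Vector3,
    cfg: Optional[NamingConfig] = None,
) -> OriginCheckResult:
    """Full check on a parsed structure set: find markers, derive the
    expected origin, compare. Raises :class:`MarkerRoleError` when the
    marker set cannot be assembled (NOT-EVALUABLE, never PASS)."""
    cfg = cfg or NamingConfig()
    markers = find_marker_contours(structures, cfg)
    expected = expected_user_origin(markers)
    return check_user_origin(expected, actual_origin, cfg.tolerance_mm)
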