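"""Alpins-style doubled-angle astigmatism vector analysis.

An astigmatism of magnitude C at axis theta is represented as the plane
vector (C*cos(2*theta), C*sin(2*theta)).  Doubling the angle makes the
representation continuous across the 0/180 wrap and turns clinically
"opposite" axes (90 degrees apart) into antipodal vectors, so astigmatic
changes add and subtract as ordinary vectors.

The target-induced astigmatism (TIA) is the intended astigmatic change,
target minus preop; the surgically-induced astigmatism (SIA) is the
achieved change, postop minus preop.  Their comparison yields the
correction index CI = |SIA|/|TIA| (1 = perfect magnitude, >1
overcorrection) and the angle of error, the signed single-angle offset of
the achieved correction axis from the intended one (positive =
counterclockwise).  Both are undefined for eyes with no intended
correction (|TIA| = 0); such eyes are excluded from the CI/AoE panels and
their count reported separately.

All vector inputs must be referenced to the corneal plane (vertex 0 mm);
magnitudes use the positive-cylinder convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .refraction import Refraction, convert_cyl_sign

__all__ = [
    "AstigVector",
    "VectorOutcome",
    "to_double_angle",
    "tia",
    "sia",
    "correction_index",
    "angle_of_error",
    "vector_outcome",
]


@dataclass(frozen=True)
class AstigVector:
    """A doubled-angle astigmatism vector (x = C*cos 2a, y = C*sin 2a)."""

    x: float
    y: float

    @property
    def magnitude(self) -> float:
        return math.hypot(self.x, self.y)

    @property
    def axis(self) -> float:
        """Single-angle axis in (0, 180]; 180 by convention at magnitude 0."""
        a = math.degrees(math.atan2(self.y, self.x)) / 2.0
        a %= 180.0
        return 180.0 if a == 0 else a

    def __sub__(self, other: "AstigVector") -> "AstigVector":
        return AstigVector(self.x - other.x, self.y - other.y)

    def __add__(self, other: "AstigVector") -> "AstigVector":
        return AstigVector(self.x + other.x, self.y + other.y)


@dataclass(frozen=True)
class VectorOutcome:
    """Per-eye vector summary: TIA, SIA, correction index, angle of error.

    ``correction_index`` and ``angle_of_error`` are None when undefined
    (zero intended correction, or a zero vector for the angle).
    """

    tia: AstigVector
    sia: AstigVector
    correction_index: float | None
    angle_of_error: float | None


def to_double_angle(magnitude: float, axis: float) -> AstigVector:
    """Doubled-angle vector of a cylinder of given magnitude and axis.

    The magnitude must be non-negative (positive-cylinder convention);
    callers transpose notation first.
    """
    if magnitude < 0:
        raise ValueError(
            f"astigmatism magnitude must be >= 0 (positive-cylinder form), "
            f"got {magnitude}"
        )
    rad = math.radians(2.0 * axis)
    return AstigVector(magnitude * math.cos(rad), magnitude * math.sin(rad))


def _astig_vector_of(r: Refraction, role: str) -> AstigVector:
    if r.vertex != 0.0:
        raise ValueError(
            f"{role} refraction is referenced to {r.vertex} mm; propagate it "
            "to the corneal plane (vertex 0) before vector analysis"
        )
    if r.cylinder < 0:
        r = convert_cyl_sign(r)
    return to_double_angle(r.cylinder, r.axis)


def tia(preop_corneal: Refraction, target_corneal: Refraction) -> AstigVector:
    """Target-induced astigmatism: the intended change, target - preop."""
    return _astig_vector_of(target_corneal, "target") - _astig_vector_of(
        preop_corneal, "preop"
    )


def sia(preop_corneal: Refraction, postop_corneal: Refraction) -> AstigVector:
    """Surgically-induced astigmatism: the achieved change, postop - preop."""
    return _astig_vector_of(postop_corneal, "postop") - _astig_vector_of(
        preop_corneal, "preop"
    )


def correction_index(out: AstigVector, achieved: AstigVector) -> float | None:
    """|SIA|/|TIA|, or None when there was no intended correction."""
    t = out.magnitude
    if t == 0.0:
        return None
    return achieved.magnitude / t


def angle_of_error(out: AstigVector, achieved: AstigVector) -> float | None:
    """Signed single-angle offset of SIA from TIA, in (-90, 90] degrees.

    Half the signed doubled-angle between the two vectors; positive when
    the achieved correction axis lies counterclockwise of the intended
    axis.  None when either vector has zero magnitude.
    """
    if out.magnitude == 0.0 or achieved.magnitude == 0.0:
        return None
    cross = out.x * achieved.y - out.y * achieved.x
    dot = out.x * achieved.x + out.y * achieved.y
    half = math.degrees(math.atan2(cross, dot)) / 2.0
    if half <= -90.0:
        half += 180.0
    return half


def vector_outcome(
    preop_corneal: Refraction,
    target_corneal: Refraction,
    postop_corneal: Refraction,
) -> VectorOutcome:
    """Full per-eye vector analysis from corneal-plane refractions."""
    t = tia(preop_corneal, target_corneal)
    s = sia(preop_corneal, postop_corneal)
    return VectorOutcome(
        tia=t,
        sia=s,
        correction_index=correction_index(t, s),
        angle_of_error=angle_of_error(t, s),
    )
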