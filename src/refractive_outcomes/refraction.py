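"""Pure optical algebra on sphero-cylindrical refractions.

A refraction is the quadruple (sphere, cylinder, axis, vertex).  Sphere and
cylinder are signed dioptric powers; the sign of the cylinder encodes the
notation (negative-cylinder is the clinical default, positive-cylinder is
used internally for vector analysis).  The axis is the cylinder meridian in
degrees, kept in the half-open interval (0, 180].  The vertex distance is
the distance in millimetres from the corneal apex to the plane at which the
refraction was measured (0 = corneal plane, 12 = typical spectacle plane).

All functions here are total and side-effect free; dioptre values are never
rounded internally — display rounding to 0.01 D belongs to the rendering
layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "Refraction",
    "convert_cyl_sign",
    "propagate_vertex",
    "seq",
    "deq",
    "seq_error",
    "DegeneratePowerError",
]


class DegeneratePowerError(ValueError):
    """Vertex propagation hit a meridian whose power diverges (1 - d*F ~ 0)."""


def _normalize_axis(axis: float) -> float:
    """Map any axis in degrees onto (0, 180]; a stored 0 becomes 180."""
    a = math.fmod(axis, 180.0)
    if a < 0:
        a += 180.0
    return 180.0 if a == 0 else a


@dataclass(frozen=True)
class Refraction:
    """One sphero-cylindrical refraction referenced to a measurement plane.

    Parameters
    ----------
    sphere : float
        Spherical power in dioptres (signed).
    cylinder : float
        Cylindrical power in dioptres (signed; the sign carries the
        notation).
    axis : float, optional
        Cylinder axis in degrees.  Normalised into (0, 180]; an axis of 0
        — accepted because plano targets are conventionally written
        "0, 0, 0" — is stored as 180.  Semantically inert when
        ``cylinder == 0``.
    vertex : float, optional
        Vertex distance in millimetres, >= 0.  Defaults to the 12 mm
        spectacle plane.
    """

    sphere: float
    cylinder: float
    axis: float = 180.0
    vertex: float = 12.0

    def __post_init__(self) -> None:
        for name in ("sphere", "cylinder", "axis", "vertex"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.vertex < 0:
            raise ValueError(f"vertex distance must be >= 0 mm, got {self.vertex}")
        object.__setattr__(self, "axis", _normalize_axis(float(self.axis)))
        object.__setattr__(self, "sphere", float(self.sphere))
        object.__setattr__(self, "cylinder", float(self.cylinder))
        object.__setattr__(self, "vertex", float(self.vertex))

    @property
    def is_plano(self) -> bool:
        return self.sphere == 0.0 and self.cylinder == 0.0


def convert_cyl_sign(r: Refraction) -> Refraction:
    """Transpose a refraction into the opposite cylinder-sign notation.

    The same optical correction rewritten with the cylinder sign flipped:
    sphere' = sphere + cylinder, cylinder' = -cylinder, axis rotated 90
    degrees (kept in (0, 180]).  Applying the function twice returns the
    input — it is an involution — and the spherical equivalent is invariant
    under it.
    """
    # r.axis is already in (0, 180], so the 90-degree rotation stays exact
    new_axis = r.axis - 90.0 if r.axis > 90.0 else r.axis + 90.0
    return replace(
        r,
        sphere=r.sphere + r.cylinder,
        cylinder=-r.cylinder,
        axis=new_axis,
    )


def propagate_vertex(r: Refraction, target_vertex: float) -> Refraction:
    """Re-reference a refraction to another vertex plane.

    Each principal meridian is propagated independently with the standard
    effectivity relation ``F' = F / (1 - d*F)`` where ``d`` is the signed
    plane shift ``(r.vertex - target_vertex) / 1000`` in metres.  Moving a
    spectacle refraction (12 mm) to the corneal plane (0 mm) therefore uses
    d = +0.012 m: a -10.00 D spectacle lens becomes -10/1.12 = -8.93 D at
    the cornea.

    Raises
    ------
    DegeneratePowerError
        If a meridian power sits at the pole of the effectivity relation
        (``1 - d*F`` within 1e-9 of zero).
    """
    if target_vertex < 0:
        raise ValueError(f"target vertex must be >= 0 mm, got {target_vertex}")
    d = (r.vertex - target_vertex) / 1000.0  # metres, signed
    if d == 0.0:
        return replace(r, vertex=float(target_vertex))

    def _propagate(power: float, which: str) -> float:
        denom = 1.0 - d * power
        if abs(denom) < 1e-9:
            raise DegeneratePowerError(
                f"{which} meridian power {power:+.2f} D diverges when moved "
                f"{d * 1000.0:+.1f} mm (1 - d*F ~ 0)"
            )
        return power / denom

    f1 = _propagate(r.sphere, "sphere")
    f2 = _propagate(r.sphere + r.cylinder, "sphere+cylinder")
    return replace(r, sphere=f1, cylinder=f2 - f1, vertex=float(target_vertex))


def seq(r: Refraction) -> float:
    """Spherical equivalent: sphere + cylinder/2, in dioptres (signed).

    Invariant under cylinder-sign transposition.
    """
    return r.sphere + r.cylinder / 2.0


def deq(r: Refraction) -> float:
    """Defocus equivalent: |SEQ| + |cylinder|/2, a non-negative blur burden.

    Always >= |SEQ|, with equality exactly when the cylinder is zero.
    """
    return abs(seq(r)) + abs(r.cylinder) / 2.0


def seq_error(postop: Refraction, target: Refraction) -> float:
    """Achieved-minus-intended spherical equivalent, in dioptres.

    Positive values mean the eye ended more hyperopic (overcorrected)
    than intended; the sign is preserved for the accuracy histogram.
    """
    return seq(postop) - seq(target)
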