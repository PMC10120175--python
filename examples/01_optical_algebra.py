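"""Sphero-cylindrical refraction algebra: notation, vertex, SEQ and DEQ.

Takes a typical myopic-astigmatism spectacle refraction, transposes the
cylinder notation, moves it to the corneal plane, and summarises it as
spherical and defocus equivalents.
"""

from refractive_outcomes import (
    Refraction,
    convert_cyl_sign,
    deq,
    propagate_vertex,
    seq,
)

spectacle = Refraction(sphere=-4.50, cylinder=-1.50, axis=175, vertex=12)
print(f"spectacle refraction : {spectacle.sphere:+.2f} {spectacle.cylinder:+.2f} x {spectacle.axis:g} @ {spectacle.vertex:g} mm")

positive = convert_cyl_sign(spectacle)
print(f"positive-cyl notation: {positive.sphere:+.2f} {positive.cylinder:+.2f} x {positive.axis:g}")

corneal = propagate_vertex(spectacle, 0)
print(f"at the corneal plane : {corneal.sphere:+.2f} {corneal.cylinder:+.2f} x {corneal.axis:g}")

print(f"SEQ (spectacle)      : {seq(spectacle):+.2f} D")
print(f"DEQ (spectacle)      : {deq(spectacle):.2f} D")

# The SEQ is the blur-equivalent sphere (sphere + cyl/2); the DEQ adds the
# astigmatic blur back as a positive burden, so DEQ >= |SEQ| always.  A
# minus lens gains effective power moving toward the eye, so the corneal
# sphere is slightly weaker in magnitude than the spectacle sphere.
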