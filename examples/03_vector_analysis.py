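"""Doubled-angle astigmatism vector analysis of a single toric treatment.

Computes the target-induced (TIA) and surgically-induced (SIA)
astigmatism vectors for one eye, then the correction index and angle of
error that quantify how the achieved correction compares with the
intended one.
"""

from refractive_outcomes import (
    Refraction,
    propagate_vertex,
    vector_outcome,
)

# spectacle-plane data: 2.0 D of cylinder at 10 degrees, aiming for plano
preop = propagate_vertex(Refraction(-1.00, -2.00, 10, vertex=12), 0)
target = Refraction(0, 0, 180, vertex=0)
# the surgeon removed slightly too little cylinder, slightly off-axis
postop = propagate_vertex(Refraction(-0.25, -0.50, 5, vertex=12), 0)

out = vector_outcome(preop, target, postop)
print(f"TIA: {out.tia.magnitude:.2f} D x {out.tia.axis:.1f}")
print(f"SIA: {out.sia.magnitude:.2f} D x {out.sia.axis:.1f}")
print(f"correction index: {out.correction_index:.2f}")
print(f"angle of error  : {out.angle_of_error:+.1f} deg")

# CI < 1 is an undercorrection of astigmatic magnitude (CI = |SIA|/|TIA|);
# the angle of error is the off-axis component of the achieved correction,
# positive when the achieved axis sits counterclockwise of the intended.
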