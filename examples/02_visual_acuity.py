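"""Snellen parsing, LogMAR conversion and the efficacy/safety indices.

Parses clinical 20/XX tokens (including letter suffixes), converts them to
LogMAR and decimal acuity, and computes the two summary indices for a toy
five-eye cohort.
"""

from refractive_outcomes import (
    AcuityConfig,
    efficacy_index,
    line_change,
    parse_snellen,
    safety_index,
    to_decimal,
    to_logmar,
)

cfg = AcuityConfig()  # 0.02 logMAR per letter, standard chart lines

for token in ("20", "20-1", "25+2", "40"):
    va = parse_snellen(token)
    print(
        f"20/{token:<5} -> logMAR {to_logmar(va, cfg):+.3f}, "
        f"decimal {to_decimal(va, cfg):.2f}"
    )

pre = parse_snellen("25")
post = parse_snellen("20")
print(f"20/25 -> 20/20 is a change of {line_change(pre, post, cfg):+d} line(s)")

# five eyes: preop corrected, postop uncorrected and corrected acuities
preop_cdva = [parse_snellen(t) for t in ("20", "20", "25", "20", "20-1")]
postop_udva = [parse_snellen(t) for t in ("20", "25", "25", "20+1", "20")]
postop_cdva = [parse_snellen(t) for t in ("20", "20", "20", "16", "20")]

eff = efficacy_index(postop_udva, preop_cdva, cfg)
saf = safety_index(postop_cdva, preop_cdva, cfg)
print(f"efficacy index: {eff:.2f}   (mean decimal postop UDVA / mean decimal preop CDVA)")
print(f"safety index  : {saf:.2f}   (mean decimal postop CDVA / mean decimal preop CDVA)")
# An efficacy index near 1 means uncorrected vision after surgery matches
# the best-corrected vision before it; a safety index above 1 means
# corrected vision actually improved.
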