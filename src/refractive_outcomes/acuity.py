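"""Snellen visual-acuity parsing, LogMAR/decimal conversion and indices.

Distance acuities arrive as 20/XX Snellen denominators with an optional
signed letter suffix ("20-1" = one letter short of the 20/20 line,
"25+2" = two letters beyond 20/25).  On the LogMAR scale a full acuity line
is 0.1 and a letter defaults to 0.02 (five-letter lines):

    logMAR = log10(denominator / 20) - letter_offset * per_letter_increment

Decimal acuity is ``10 ** (-logMAR)``; 20/20 is decimal 1.0 by definition.
The efficacy index is the ratio of mean decimal postoperative uncorrected
acuity to mean decimal baseline corrected acuity; the safety index uses
postoperative corrected acuity in the numerator.
"""

from __future__ import annotations

import csv
import datetime as _dt
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "VAMeasure",
    "AcuityConfig",
    "SnellenParseError",
    "DateCoercedCellError",
    "parse_snellen",
    "format_snellen",
    "to_logmar",
    "to_decimal",
    "logmar_to_snellen",
    "line_change",
    "efficacy_index",
    "safety_index",
    "load_conversion_table",
]

#: Geometric Snellen chart progression (denominators of 20/XX lines).
FULL_CHART: tuple[float, ...] = (
    10, 12.5, 16, 20, 25, 32, 40, 50, 63, 80, 100, 125, 160, 200, 400,
)

#: Lines shown on the cumulative acuity graph by default.
DEFAULT_DISPLAY_LINES: tuple[float, ...] = (16, 20, 25, 32, 40, 50, 63, 80, 100)


class SnellenParseError(ValueError):
    """An acuity token could not be interpreted as 20/XX[-+letters]."""


class DateCoercedCellError(SnellenParseError):
    """A spreadsheet cell holds a date where an acuity token was expected.

    Spreadsheet software silently turns tokens like "25-2" into dates; the
    remedy is to prefix the entry with an apostrophe ('25-2) or set the
    column number format to Text before re-entering the value.
    """


@dataclass(frozen=True)
class VAMeasure:
    """One Snellen acuity: 20/denominator plus a signed letter offset."""

    denominator: float
    letter_offset: int = 0

    def __post_init__(self) -> None:
        if not (self.denominator > 0 and math.isfinite(self.denominator)):
            raise ValueError(f"Snellen denominator must be > 0, got {self.denominator}")
        if abs(self.letter_offset) > 4:
            raise ValueError(
                f"letter offset must be within +/-4 letters, got {self.letter_offset}"
            )
        object.__setattr__(self, "denominator", float(self.denominator))
        object.__setattr__(self, "letter_offset", int(self.letter_offset))


@dataclass(frozen=True)
class AcuityConfig:
    """Tunable acuity conventions.

    per_letter_increment
        LogMAR units per letter read beyond/short of a line (0.02 for
        five-letter charts).
    snellen_lines
        Denominators displayed on cumulative graphs and used when snapping
        a LogMAR value back onto the chart.
    index_decimals
        Display precision for efficacy/safety indices.
    per_eye_ratios
        If True, the efficacy/safety indices average per-eye ratios instead
        of taking the ratio of group means.
    """

    per_letter_increment: float = 0.02
    snellen_lines: tuple[float, ...] = FULL_CHART
    display_lines: tuple[float, ...] = DEFAULT_DISPLAY_LINES
    index_decimals: int = 2
    per_eye_ratios: bool = False

    def __post_init__(self) -> None:
        if self.per_letter_increment <= 0:
            raise ValueError("per_letter_increment must be > 0")
        for name in ("snellen_lines", "display_lines"):
            lines = tuple(float(x) for x in getattr(self, name))
            if any(b <= a for a, b in zip(lines, lines[1:])):
                raise ValueError(f"{name} must be strictly increasing")
            object.__setattr__(self, name, lines)


_TOKEN_RE = re.compile(
    r"^\s*'?\s*(\d+(?:[.,]\d+)?)\s*(?:([+\-])\s*(\d+))?\s*$"
)


def parse_snellen(token: object) -> VAMeasure:
    """Parse a 20/XX Snellen token such as "20-1", "15", "20 + 2" or "'25-2".

    Accepts numbers (a bare denominator), tolerates a leading apostrophe
    (the spreadsheet text-entry escape), surrounding whitespace, and
    en/em-dash or minus-sign variants of the hyphen.

    Raises
    ------
    DateCoercedCellError
        If the value is a date/datetime — the spreadsheet coerced a token
        like "25-2" into a date.
    SnellenParseError
        For any other unparseable token.
    """
    if isinstance(token, (_dt.datetime, _dt.date)):
        raise DateCoercedCellError(
            f"acuity cell holds the date {token!r} instead of a 20/XX token; "
            "the spreadsheet auto-converted the entry — type it with a "
            "leading apostrophe (e.g. '25-2) or set the column number "
            "format to \"Text\" and re-enter the value"
        )
    if isinstance(token, bool):
        raise SnellenParseError(f"not a Snellen token: {token!r}")
    if isinstance(token, (int, float)):
        if not (math.isfinite(token) and token > 0):
            raise SnellenParseError(f"not a Snellen denominator: {token!r}")
        return VAMeasure(float(token), 0)
    if not isinstance(token, str):
        raise SnellenParseError(f"not a Snellen token: {token!r}")
    # normalise unicode dash/minus variants to ASCII
    text = (
        token.replace("–", "-")
        .replace("—", "-")
        .replace("−", "-")
    )
    m = _TOKEN_RE.match(text)
    if m is None:
        raise SnellenParseError(f"cannot parse Snellen token {token!r}")
    denom = float(m.group(1).replace(",", "."))
    offset = 0
    if m.group(2) is not None:
        offset = int(m.group(3))
        if m.group(2) == "-":
            offset = -offset
    try:
        return VAMeasure(denom, offset)
    except ValueError as exc:
        raise SnellenParseError(f"invalid Snellen token {token!r}: {exc}") from exc


def format_snellen(va: VAMeasure) -> str:
    """Render a VAMeasure back into its compact token form ("25-1")."""
    d = va.denominator
    denom = f"{d:g}"
    if va.letter_offset == 0:
        return denom
    sign = "+" if va.letter_offset > 0 else "-"
    return f"{denom}{sign}{abs(va.letter_offset)}"


def to_logmar(va: VAMeasure, cfg: AcuityConfig = AcuityConfig()) -> float:
    """LogMAR value of a Snellen measure (20/20 -> 0.00, 20/40 -> 0.301)."""
    return math.log10(va.denominator / 20.0) - va.letter_offset * cfg.per_letter_increment


def to_decimal(va: VAMeasure, cfg: AcuityConfig = AcuityConfig()) -> float:
    """Decimal acuity, 10**(-logMAR); 20/20 -> 1.0, 20/40 -> 0.5."""
    return 10.0 ** (-to_logmar(va, cfg))


def logmar_to_snellen(
    value: float, cfg: AcuityConfig = AcuityConfig()
) -> VAMeasure:
    """Snap a LogMAR value to the nearest (line, letter offset) on the chart.

    The candidate set is every configured line combined with letter offsets
    in [-4, +4]; ties prefer the smaller absolute offset so that exactly
    representable values round-trip through :func:`to_logmar`.
    """
    if not math.isfinite(value):
        raise ValueError(f"LogMAR value must be finite, got {value}")
    best: VAMeasure | None = None
    best_key: tuple[float, int] | None = None
    for denom in cfg.snellen_lines:
        base = math.log10(denom / 20.0)
        for offset in range(-4, 5):
            lm = base - offset * cfg.per_letter_increment
            key = (abs(lm - value), abs(offset))
            if best_key is None or key < best_key:
                best_key = key
                best = VAMeasure(denom, offset)
    assert best is not None
    return best


def line_change(
    pre: VAMeasure, post: VAMeasure, cfg: AcuityConfig = AcuityConfig()
) -> int:
    """Whole lines of acuity gained (+) or lost (-) from pre to post.

    Computed as (logMAR_pre - logMAR_post)/0.1 rounded half away from zero,
    so a gain and a loss of the same size always bin symmetrically.
    """
    x = (to_logmar(pre, cfg) - to_logmar(post, cfg)) / 0.1
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def _mean_decimal(vas: Sequence[VAMeasure], cfg: AcuityConfig) -> float:
    if not vas:
        raise ValueError("cannot average an empty acuity list")
    return sum(to_decimal(v, cfg) for v in vas) / len(vas)


def efficacy_index(
    cohort_post_udva: Sequence[VAMeasure],
    baseline_cdva: Sequence[VAMeasure],
    cfg: AcuityConfig = AcuityConfig(),
) -> float:
    """Mean decimal postop UDVA over mean decimal baseline CDVA.

    The baseline is the preoperative corrected acuity for corneal and
    phakic/clear-lens procedures and the postoperative corrected acuity for
    cataract surgery (the caller selects which list to pass).  With
    ``cfg.per_eye_ratios`` the index becomes the mean of per-eye ratios,
    which requires the two lists to be aligned per eye.
    """
    if not cohort_post_udva or not baseline_cdva:
        raise ValueError("efficacy index needs non-empty acuity lists")
    if cfg.per_eye_ratios:
        if len(cohort_post_udva) != len(baseline_cdva):
            raise ValueError("per-eye ratios require aligned lists")
        return sum(
            to_decimal(u, cfg) / to_decimal(c, cfg)
            for u, c in zip(cohort_post_udva, baseline_cdva)
        ) / len(cohort_post_udva)
    return _mean_decimal(cohort_post_udva, cfg) / _mean_decimal(baseline_cdva, cfg)


def safety_index(
    cohort_post_cdva: Sequence[VAMeasure],
    baseline_cdva: Sequence[VAMeasure],
    cfg: AcuityConfig = AcuityConfig(),
) -> float:
    """Mean decimal postop CDVA over mean decimal baseline CDVA."""
    return efficacy_index(cohort_post_cdva, baseline_cdva, cfg)


def load_conversion_table(path: str | Path | None = None) -> list[tuple[float, str]]:
    """Load the LogMAR -> Snellen-token conversion table.

    The bundled two-column CSV (logmar, snellen) covers every chart line
    with letter offsets -2..+2 at the default 0.02 LogMAR per letter.  A
    custom table in the same layout can be supplied via ``path``.
    """
    if path is None:
        ref = resources.files("refractive_outcomes").joinpath(
            "data/logmar_snellen.csv"
        )
        text = ref.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    rows: list[tuple[float, str]] = []
    reader = csv.reader(text.splitlines())
    header = next(reader)
    if len(header) < 2:
        raise ValueError("conversion table must have two columns: logmar, snellen")
    for row in reader:
        if not row or not row[0].strip():
            continue
        rows.append((float(row[0]), row[1].strip()))
    return rows
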