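"""Reading, validating and writing the 20-column per-eye data files.

One spreadsheet per group, one row per eye, one header row.  Column
identity is positional; header text is advisory.  Columns 1-15 are
mandatory: preoperative refraction (sphere, cylinder, axis, vertex) and
corrected acuity; intended target refraction (sphere, cylinder, axis,
vertex); postoperative refraction (sphere, cylinder, axis, vertex),
corrected acuity and uncorrected acuity.  Columns 16-20 optionally hold
the postoperative spherical equivalent at up to five time points for the
stability analysis.

Refractions are entered in decimal dioptres in negative-cylinder notation;
acuities as 20/XX Snellen denominator tokens ("20-1", "25", "30-1").  A
plano target is written as 0, 0, 0.  Both .xlsx (first worksheet) and a
.csv dialect with identical columns are accepted.
"""

from __future__ import annotations

import csv
import datetime as _dt
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .acuity import (
    DateCoercedCellError,
    SnellenParseError,
    VAMeasure,
    format_snellen,
    parse_snellen,
)
from .refraction import Refraction

__all__ = [
    "COLUMN_NAMES",
    "EyeRecord",
    "Cohort",
    "ValidationReport",
    "SchemaError",
    "CohortValidationError",
    "PairingError",
    "read_group_file",
    "write_group_file",
    "validate_cohorts",
]

N_TIMEPOINTS = 5

#: Canonical (advisory) header for the 20 positional columns.
COLUMN_NAMES: tuple[str, ...] = (
    "preop_sphere",
    "preop_cylinder",
    "preop_axis",
    "preop_vertex",
    "preop_cdva",
    "target_sphere",
    "target_cylinder",
    "target_axis",
    "target_vertex",
    "postop_sphere",
    "postop_cylinder",
    "postop_axis",
    "postop_vertex",
    "postop_cdva",
    "postop_udva",
    "seq_t1",
    "seq_t2",
    "seq_t3",
    "seq_t4",
    "seq_t5",
)

N_MANDATORY = 15


class SchemaError(ValueError):
    """The file does not present the expected 20-column layout."""


class CohortValidationError(ValueError):
    """The file parsed but holds no usable rows, or a fatal cell error."""


class PairingError(ValueError):
    """A paired design was requested with misaligned group files."""


@dataclass(frozen=True)
class EyeRecord:
    """One eye: preop and postop state, intended target, optional SEQ series."""

    preop: Refraction
    preop_cdva: VAMeasure
    target: Refraction
    postop: Refraction
    postop_cdva: VAMeasure
    postop_udva: VAMeasure
    seq_series: tuple[float | None, ...] = (None,) * N_TIMEPOINTS

    def __post_init__(self) -> None:
        series = tuple(self.seq_series)
        if len(series) != N_TIMEPOINTS:
            raise ValueError(f"seq_series must hold {N_TIMEPOINTS} slots")
        for v in series:
            if v is not None and not math.isfinite(v):
                raise ValueError(f"SEQ time-point values must be finite, got {v}")
        object.__setattr__(self, "seq_series", series)

    @property
    def has_stability(self) -> bool:
        return any(v is not None for v in self.seq_series)


@dataclass(frozen=True)
class Cohort:
    """A named, validated group of eye records read from one data file."""

    name: str
    records: tuple[EyeRecord, ...]
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        if not self.records:
            raise CohortValidationError(f"cohort {self.name!r} holds no records")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_stability_timepoints(self) -> int:
        """Number of trailing SEQ columns populated for at least one eye."""
        n = 0
        for t in range(N_TIMEPOINTS):
            if any(r.seq_series[t] is not None for r in self.records):
                n = t + 1
        return n


@dataclass
class ValidationReport:
    """Row-level findings from reading/validating cohorts.

    Dropped rows are never silent: ``n_input_rows`` equals
    ``n_kept + len(row_errors)`` for a single-file report.
    """

    n_input_rows: int = 0
    n_kept: int = 0
    row_errors: list[tuple[int, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    info: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.row_errors

    def to_text(self) -> str:
        lines = [f"rows read: {self.n_input_rows}, rows kept: {self.n_kept}"]
        lines += [f"row {row}: ERROR: {msg}" for row, msg in self.row_errors]
        lines += [f"WARNING: {msg}" for msg in self.warnings]
        lines += [f"INFO: {msg}" for msg in self.info]
        return "\n".join(lines)


def _cell_float(value: object, colname: str) -> float:
    if value is None:
        raise ValueError(f"mandatory column {colname!r} is blank")
    if isinstance(value, str):
        text = value.strip().replace(",", ".")
        if not text:
            raise ValueError(f"mandatory column {colname!r} is blank")
        value = float(text)
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ValueError(f"column {colname!r} holds non-numeric value {value!r}")
    v = float(value)
    if not math.isfinite(v):
        raise ValueError(f"column {colname!r} holds non-finite value {value!r}")
    return v


def _cell_optional_float(value: object, colname: str) -> float | None:
    if value is None or (isinstance(value, str) and not value.strip()):
        return None
    return _cell_float(value, colname)


def _cell_acuity(value: object, colname: str) -> VAMeasure:
    if value is None or (isinstance(value, str) and not value.strip()):
        raise ValueError(f"mandatory column {colname!r} is blank")
    return parse_snellen(value)


def _parse_row(cells: Sequence[object]) -> EyeRecord:
    def refraction(base: int) -> Refraction:
        return Refraction(
            sphere=_cell_float(cells[base], COLUMN_NAMES[base]),
            cylinder=_cell_float(cells[base + 1], COLUMN_NAMES[base + 1]),
            axis=_cell_float(cells[base + 2], COLUMN_NAMES[base + 2]),
            vertex=_cell_float(cells[base + 3], COLUMN_NAMES[base + 3]),
        )

    seq_series = tuple(
        _cell_optional_float(cells[15 + t], COLUMN_NAMES[15 + t])
        for t in range(N_TIMEPOINTS)
    )
    return EyeRecord(
        preop=refraction(0),
        preop_cdva=_cell_acuity(cells[4], COLUMN_NAMES[4]),
        target=refraction(5),
        postop=refraction(9),
        postop_cdva=_cell_acuity(cells[13], COLUMN_NAMES[13]),
        postop_udva=_cell_acuity(cells[14], COLUMN_NAMES[14]),
        seq_series=seq_series,
    )


def _load_raw_rows(path: Path) -> list[list[object]]:
    if path.suffix.lower() in {".xlsx", ".xlsm"}:
        from openpyxl import load_workbook

        wb = load_workbook(path, read_only=True, data_only=True)
        try:
            ws = wb.worksheets[0]
            rows = [list(row) for row in ws.iter_rows(values_only=True)]
        finally:
            wb.close()
        return rows
    # CSV dialect: identical positional columns, blank cell = empty string
    with path.open(newline="", encoding="utf-8") as fh:
        return [list(row) for row in csv.reader(fh)]


def read_group_file(
    path: str | Path, name: str | None = None
) -> tuple[Cohort, ValidationReport]:
    """Read one group data file into a validated :class:`Cohort`.

    Returns the cohort and a validation report.  Rows that fail to parse
    are dropped, counted and itemised in the report (1-based spreadsheet
    row numbers).  A date-coerced acuity cell is a fatal error because it
    indicates the whole column lost its text format.

    Raises
    ------
    SchemaError
        Fewer than the 15 mandatory columns, or no header row.
    CohortValidationError
        Empty file, fatal cell error, or no parseable rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = _load_raw_rows(path)
    # drop fully blank trailing rows
    raw = [
        row
        for row in raw
        if any(c is not None and str(c).strip() != "" for c in row)
    ]
    if not raw:
        raise CohortValidationError(f"{path}: file is empty")
    header, data = raw[0], raw[1:]
    if len(header) < N_MANDATORY:
        missing = range(len(header) + 1, N_MANDATORY + 1)
        names = ", ".join(f"{i} ({COLUMN_NAMES[i - 1]})" for i in missing)
        raise SchemaError(
            f"{path}: expected at least {N_MANDATORY} mandatory columns, "
            f"found {len(header)}; missing columns {names}"
        )
    if not data:
        raise CohortValidationError(f"{path}: no data rows below the header")

    report = ValidationReport(n_input_rows=len(data))
    records: list[EyeRecord] = []
    for i, row in enumerate(data):
        rownum = i + 2  # 1-based, after header
        cells = list(row) + [None] * (len(COLUMN_NAMES) - len(row))
        try:
            records.append(_parse_row(cells[: len(COLUMN_NAMES)]))
        except DateCoercedCellError as exc:
            raise CohortValidationError(f"{path} row {rownum}: {exc}") from exc
        except (ValueError, SnellenParseError) as exc:
            report.row_errors.append((rownum, str(exc)))
    report.n_kept = len(records)
    if not records:
        raise CohortValidationError(
            f"{path}: no usable rows\n{report.to_text()}"
        )
    cohort = Cohort(
        name=name or path.stem, records=tuple(records), source=str(path)
    )
    n_tp = cohort.n_stability_timepoints
    if n_tp:
        for t in range(n_tp):
            n_t = sum(1 for r in records if r.seq_series[t] is not None)
            report.info.append(f"stability time point {t + 1}: N={n_t}")
    else:
        report.info.append(
            "no stability columns populated; the stability panel is "
            "replaced by the defocus-equivalent accuracy panel"
        )
    return cohort, report


def _format_cell(value: object) -> object:
    if value is None:
        return ""
    if isinstance(value, VAMeasure):
        return format_snellen(value)
    return value


def _record_row(r: EyeRecord) -> list[object]:
    return [
        r.preop.sphere,
        r.preop.cylinder,
        r.preop.axis,
        r.preop.vertex,
        r.preop_cdva,
        r.target.sphere,
        r.target.cylinder,
        r.target.axis,
        r.target.vertex,
        r.postop.sphere,
        r.postop.cylinder,
        r.postop.axis,
        r.postop.vertex,
        r.postop_cdva,
        r.postop_udva,
        *r.seq_series,
    ]


def write_group_file(records: Iterable[EyeRecord], path: str | Path) -> Path:
    """Write eye records in the exact 20-column layout (.xlsx or .csv).

    Values are written at full precision so that reading the file back
    reproduces the in-memory records exactly.  The output is deterministic:
    the same records produce the same file bytes.
    """
    path = Path(path)
    rows = [_record_row(r) for r in records]
    if path.suffix.lower() == ".csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(COLUMN_NAMES)
            for row in rows:
                writer.writerow(
                    [
                        _format_cell(c) if not isinstance(c, float) else repr(c)
                        for c in row
                    ]
                )
        return path
    if path.suffix.lower() != ".xlsx":
        raise ValueError(f"unsupported output format: {path.suffix!r}")
    from openpyxl import Workbook

    wb = Workbook()
    ws = wb.active
    ws.title = "data"
    ws.append(COLUMN_NAMES)
    for row in rows:
        ws.append(
            [
                _format_cell(c)
                for c in row
            ]
        )
        # acuity columns must stay text so tokens like 25-2 survive
        for col in (5, 14, 15):
            ws.cell(row=ws.max_row, column=col).number_format = "@"
    # pin document metadata so repeated writes are reproducible
    epoch = _dt.datetime(2000, 1, 1)
    wb.properties.created = epoch
    wb.properties.modified = epoch
    wb.save(path)
    return path


def validate_cohorts(
    a: Cohort, b: Cohort | None, design: str
) -> ValidationReport:
    """Cross-cohort validation for the chosen study design.

    ``design`` is one of ``single``, ``unpaired``, ``paired``.  A paired
    design requires the two files to have equal record counts in aligned
    row order (row i of group A is the fellow eye of row i of group B).
    The report always carries the one-eye-per-patient recommendation as a
    warning, never an error — the choice is the analyst's.
    """
    if design not in {"single", "unpaired", "paired"}:
        raise ValueError(f"unknown design {design!r}")
    if design == "single" and b is not None:
        raise ValueError("single-group design admits exactly one cohort")
    if design != "single" and b is None:
        raise ValueError(f"{design} design requires two cohorts")

    report = ValidationReport(
        n_input_rows=len(a) + (len(b) if b else 0),
        n_kept=len(a) + (len(b) if b else 0),
    )
    if design == "paired" and b is not None and len(a) != len(b):
        raise PairingError(
            f"paired design requires aligned groups: {a.name!r} has "
            f"{len(a)} eyes but {b.name!r} has {len(b)}"
        )
    report.warnings.append(
        "for greater statistical validity, include the outcome of one eye "
        "per patient (e.g. the dominant or a randomly selected eye)"
    )
    for cohort in (a, b) if b is not None else (a,):
        n_tp = cohort.n_stability_timepoints
        for t in range(n_tp):
            n_t = sum(1 for r in cohort.records if r.seq_series[t] is not None)
            report.info.append(
                f"{cohort.name}: stability time point {t + 1} N={n_t}"
            )
    return report
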