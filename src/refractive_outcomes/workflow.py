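"""End-to-end orchestration: configuration, cohort reading, panels, export.

A run is described by a :class:`StudyConfig` (procedure, design, input
files, group names/colours, acuity and threshold settings) and produces a
:class:`RunManifest`: the TIFF files written, a machine-readable stats
summary (also exported as CSV), and the validation report.  Runs are
deterministic — identical configuration and inputs yield identical panel
content and summary.
"""

from __future__ import annotations

import csv
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from .acuity import AcuityConfig
from .cohorts import Cohort, ValidationReport, read_group_file, validate_cohorts
from .panels import AnalysisConfig, PanelData, compute_all_panels
from .render import RenderStyle, render_and_export

__all__ = ["StudyConfig", "RunManifest", "load_config", "run"]

PROCEDURES = ("LVC", "RLE", "ICL", "CAT")
DESIGNS = ("single", "unpaired", "paired")


@dataclass(frozen=True)
class StudyConfig:
    """Complete description of one analysis run.

    ``group_a``/``group_b`` are paths to 20-column data files; ``group_b``
    is required exactly when the design compares two groups.  The
    remaining fields mirror the analysis and rendering knobs documented in
    :class:`~.panels.AnalysisConfig` and :class:`~.render.RenderStyle`.
    """

    procedure: str = "LVC"
    design: str = "single"
    group_a: str = ""
    group_b: str | None = None
    group_names: tuple[str, ...] = ()
    group_colors: tuple[str, ...] = ("#1f77b4", "#d62728")
    output_dir: str | None = None
    acuity: AcuityConfig = field(default_factory=AcuityConfig)
    seq_thresholds: tuple[float, ...] = (0.25, 0.50, 0.75, 1.00)
    deq_thresholds: tuple[float, ...] = (0.25, 0.50, 0.75, 1.00, 2.00)
    astig_thresholds: tuple[float, ...] = (0.50, 0.75, 1.00)
    stability_threshold: float = 0.50
    stability_pair: tuple[int, int] | None = None
    seq_plane: str = "entered"
    dpi_panel: int = 400
    dpi_composite: int = 1200
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.procedure not in PROCEDURES:
            raise ValueError(
                f"unknown procedure {self.procedure!r}; valid: {PROCEDURES}"
            )
        if self.design not in DESIGNS:
            raise ValueError(
                f"unknown design {self.design!r}; valid: {DESIGNS}"
            )
        if not self.group_a:
            raise ValueError("group_a data file is required")
        if self.design == "single" and self.group_b:
            raise ValueError("single-group design admits exactly one input file")
        if self.design != "single" and not self.group_b:
            raise ValueError(f"{self.design} design requires two input files")

    def analysis_config(self) -> AnalysisConfig:
        return AnalysisConfig(
            procedure=self.procedure,
            design=self.design,
            acuity=self.acuity,
            seq_thresholds=self.seq_thresholds,
            deq_thresholds=self.deq_thresholds,
            astig_thresholds=self.astig_thresholds,
            stability_threshold=self.stability_threshold,
            stability_pair=self.stability_pair,
            seq_plane=self.seq_plane,
            alpha=self.alpha,
        )


@dataclass
class RunManifest:
    """Everything one run produced."""

    files: dict
    stats_rows: list[dict]
    stats_csv: str
    validation: ValidationReport
    panels: dict[str, PanelData]
    log: list[str]


_CONFIG_KEYS = {f.name for f in dataclasses.fields(StudyConfig)}
_ACUITY_KEYS = {f.name for f in dataclasses.fields(AcuityConfig)}


def load_config(path: str | Path | None = None, **overrides) -> StudyConfig:
    """Build a StudyConfig from an optional YAML mapping plus overrides.

    The file is a flat key/value mapping using StudyConfig field names; an
    ``acuity:`` sub-mapping configures the acuity conventions.  Unknown
    keys are rejected with the list of valid ones.
    """
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a key/value mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})

    unknown = set(data) - _CONFIG_KEYS
    if unknown:
        raise ValueError(
            f"unknown config keys {sorted(unknown)}; valid keys: "
            f"{sorted(_CONFIG_KEYS)}"
        )
    acuity_raw = data.pop("acuity", None)
    if isinstance(acuity_raw, dict):
        bad = set(acuity_raw) - _ACUITY_KEYS
        if bad:
            raise ValueError(
                f"unknown acuity keys {sorted(bad)}; valid keys: "
                f"{sorted(_ACUITY_KEYS)}"
            )
        for key in ("snellen_lines", "display_lines"):
            if key in acuity_raw:
                acuity_raw[key] = tuple(acuity_raw[key])
        data["acuity"] = AcuityConfig(**acuity_raw)
    elif acuity_raw is not None:
        data["acuity"] = acuity_raw
    for key in ("group_names", "group_colors", "seq_thresholds",
                "deq_thresholds", "astig_thresholds"):
        if key in data:
            data[key] = tuple(data[key])
    if data.get("stability_pair") is not None:
        pair = tuple(int(x) for x in data["stability_pair"])
        if len(pair) != 2:
            raise ValueError("stability_pair must hold exactly two time points")
        data["stability_pair"] = pair
    return StudyConfig(**data)


def _stats_rows(panels: dict[str, PanelData]) -> list[dict]:
    variable = {
        "A": "postop UDVA (logMAR)",
        "B": "postop UDVA (logMAR)",
        "C": "CDVA line change",
        "D": "SEQ error to target (D)",
        "F_stability": "selected-pair SEQ change (D)",
        "F_deq": "postop DEQ (D)",
        "G": "postop astigmatism magnitude (D)",
        "I": "correction index",
        "J": "angle of error (deg)",
    }
    rows = []
    for pid, panel in panels.items():
        cmp_ = panel.annotations.get("comparison")
        key = pid
        if pid == "F":
            key = "F_stability" if panel.kind == "stability" else "F_deq"
        if cmp_ is None:
            continue
        rows.append(
            {
                "panel": pid,
                "variable": variable.get(key, ""),
                "test": cmp_["test"],
                "statistic": cmp_["statistic"],
                "p": cmp_["p"],
                "d": cmp_["d"],
                "n_a": cmp_["n_a"],
                "n_b": cmp_["n_b"],
            }
        )
    return rows


def run(config: StudyConfig) -> RunManifest:
    """Execute the full analysis and export described by ``config``."""
    log: list[str] = []
    names = list(config.group_names)
    cohort_a, report_a = read_group_file(
        config.group_a, names[0] if names else None
    )
    log.append(f"read {config.group_a}: {report_a.to_text()}")
    cohort_b: Cohort | None = None
    if config.group_b:
        cohort_b, report_b = read_group_file(
            config.group_b, names[1] if len(names) > 1 else None
        )
        log.append(f"read {config.group_b}: {report_b.to_text()}")
    report = validate_cohorts(cohort_a, cohort_b, config.design)
    for w in report.warnings:
        log.append(f"WARNING: {w}")

    cohorts = [cohort_a] + ([cohort_b] if cohort_b else [])
    acfg = config.analysis_config()
    if config.procedure == "CAT":
        log.append(
            "cataract procedure: panels A/B and the efficacy index use the "
            "postoperative CDVA as baseline"
        )
    panels = compute_all_panels(cohorts, acfg)
    for pid, panel in panels.items():
        cmp_ = panel.annotations.get("comparison")
        if cmp_:
            log.append(
                f"panel {pid}: {cmp_['test']} p={cmp_['p']:.4g} d="
                f"{'n/a' if cmp_['d'] is None else format(cmp_['d'], '.3f')}"
            )

    out_dir = Path(
        config.output_dir
        if config.output_dir
        else Path(config.group_a).parent / "standard_graphs"
    )
    style = RenderStyle(
        group_names=tuple(c.name for c in cohorts),
        group_colors=config.group_colors,
        dpi_panel=config.dpi_panel,
        dpi_composite=config.dpi_composite,
        output_dir=out_dir,
    )
    files = render_and_export(panels, style)

    rows = _stats_rows(panels)
    stats_csv = out_dir / "stats_summary.csv"
    with stats_csv.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(
            fh,
            fieldnames=["panel", "variable", "test", "statistic", "p", "d",
                        "n_a", "n_b"],
        )
        writer.writeheader()
        writer.writerows(rows)
    files["stats_csv"] = str(stats_csv)

    log_path = out_dir / "run_log.txt"
    log_path.write_text("\n".join(log) + "\n", encoding="utf-8")
    files["log"] = str(log_path)

    return RunManifest(
        files=files,
        stats_rows=rows,
        stats_csv=str(stats_csv),
        validation=report,
        panels=panels,
        log=log,
    )
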