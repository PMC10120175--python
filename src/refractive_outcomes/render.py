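"""Rendering of computed panels into TIFF figures.

One TIFF per panel at ``dpi_panel`` (default 400, suitable for slides and
article figures) and one composite one-page figure holding all ten panels
in a fixed 2 x 5 grid at ``dpi_composite`` (default 1200, for journals
with stricter image-quality requirements).  The resolution is embedded in
the TIFF metadata.  The visual styling is deliberately plain; the
scientific content of each figure lives in :class:`~.panels.PanelData`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .panels import LINE_BINS, PANEL_IDS, PanelData

__all__ = ["RenderStyle", "render_panel", "render_and_export"]

_DEFAULT_COLORS = ("#1f77b4", "#d62728")


@dataclass(frozen=True)
class RenderStyle:
    """Group naming, colours, resolution and destination for the export."""

    group_names: tuple[str, ...] = ()
    group_colors: tuple[str, ...] = _DEFAULT_COLORS
    dpi_panel: int = 400
    dpi_composite: int = 1200
    output_dir: str | Path = "."
    panel_size: tuple[float, float] = (4.0, 3.0)
    composite_size: tuple[float, float] = (5.0, 8.0)

    def __post_init__(self) -> None:
        if self.dpi_panel <= 0 or self.dpi_composite <= 0:
            raise ValueError("dpi values must be > 0")


def _color(style: RenderStyle, i: int) -> str:
    colors = style.group_colors or _DEFAULT_COLORS
    return colors[i % len(colors)]


def _stat_text(ann: Mapping) -> str:
    cmp_ = ann.get("comparison")
    if not cmp_:
        return ""
    d = cmp_.get("d")
    d_txt = "n/a" if d is None else f"{d:.2f}"
    return f"{cmp_['test']}: p={cmp_['p']:.3g}, d={d_txt}"


def _draw_grouped_bars(ax, labels: Sequence[str], groups: dict, style: RenderStyle):
    x = np.arange(len(labels))
    n_groups = max(len(groups), 1)
    width = 0.8 / n_groups
    for i, (name, values) in enumerate(groups.items()):
        ax.bar(
            x + (i - (n_groups - 1) / 2) * width,
            values,
            width=width,
            label=name,
            color=_color(style, i),
        )
    ax.set_xticks(x)
    ax.set_xticklabels(labels, fontsize=7)
    ax.set_ylim(0, 105)
    ax.set_ylabel("% of eyes", fontsize=8)


def _render_into(ax, panel: PanelData, style: RenderStyle) -> None:
    ann = panel.annotations
    if panel.kind == "cumulative_va":
        styles = {"postop_udva": "-o", "postop_cdva": "-s", "baseline_cdva": "--^"}
        for i, (name, s) in enumerate(panel.series.items()):
            for key, ls in styles.items():
                ax.plot(
                    range(len(s["lines"])),
                    s[key],
                    ls,
                    markersize=3,
                    linewidth=1,
                    color=_color(style, i),
                    alpha=0.6 if key == "baseline_cdva" else 1.0,
                    label=f"{name} {key}",
                )
        ax.set_xticks(range(len(next(iter(panel.series.values()))["lines"])))
        ax.set_xticklabels(
            [f"20/{d:g}" for d in next(iter(panel.series.values()))["lines"]],
            fontsize=6, rotation=45,
        )
        ax.set_ylim(0, 105)
        ax.set_ylabel("cumulative % of eyes", fontsize=8)
        ax.legend(fontsize=4, loc="lower right")
    elif panel.kind == "line_histogram":
        groups = {name: [s[b] for b in LINE_BINS] for name, s in panel.series.items()}
        _draw_grouped_bars(ax, list(LINE_BINS), groups, style)
        key = "efficacy_index" if panel.panel_id == "B" else "safety_index"
        txt = ", ".join(
            f"{name}: N={ann[name]['n']}, {key.split('_')[0]}={ann[name][key]:.2f}"
            for name in panel.series
        )
        ax.set_title(f"{panel.title}\n{txt}", fontsize=7)
        ax.set_xlabel("lines difference", fontsize=8)
    elif panel.kind in {"threshold_histogram", "deq_histogram"}:
        labels = [f"≤{t:.2f}" for t in next(iter(panel.series.values()))["thresholds"]]
        groups = {name: s["within"] for name, s in panel.series.items()}
        _draw_grouped_bars(ax, labels, groups, style)
        ax.set_xlabel("D of target", fontsize=8)
        ax.legend(fontsize=5)
    elif panel.kind == "scatter":
        lo, hi = math.inf, -math.inf
        for i, (name, s) in enumerate(panel.series.items()):
            x = np.asarray(s["x"]); y = np.asarray(s["y"])
            ax.plot(x, y, "o", markersize=2.5, color=_color(style, i), label=name)
            if x.size:
                lo = min(lo, x.min(), y.min())
                hi = max(hi, x.max(), y.max())
            fit = ann[name].get("fit")
            if fit and x.size:
                xs = np.linspace(x.min(), x.max(), 2)
                ax.plot(
                    xs, fit["intercept"] + fit["slope"] * xs,
                    "-", linewidth=1, color=_color(style, i),
                )
        if not math.isfinite(lo):
            lo, hi = 0.0, 1.0
        pad = 0.1 * max(hi - lo, 1e-6)
        lo, hi = lo - pad, hi + pad
        ax.plot([lo, hi], [lo, hi], ":", color="gray", linewidth=0.8)
        ax.set_xlim(lo, hi)
        ax.set_ylim(lo, hi)
        ax.set_xlabel("attempted (D)" if panel.panel_id == "E" else "TIA (D)",
                      fontsize=8)
        ax.set_ylabel("achieved (D)" if panel.panel_id == "E" else "SIA (D)",
                      fontsize=8)
        txts = []
        for name in panel.series:
            fit = ann[name].get("fit")
            if fit:
                txts.append(f"{name}: R²={fit['r_squared']:.3f}")
        ax.legend(fontsize=5)
        if txts:
            ax.set_title(f"{panel.title}\n{'; '.join(txts)}", fontsize=7)
    elif panel.kind == "histogram":
        for i, (name, s) in enumerate(panel.series.items()):
            edges = np.asarray(s["edges"], dtype=float)
            if edges.size < 2:
                continue
            centers = (edges[:-1] + edges[1:]) / 2
            width = (edges[1] - edges[0]) * 0.8 / max(len(panel.series), 1)
            offset = (i - (len(panel.series) - 1) / 2) * width
            ax.bar(centers + offset, s["percent"], width=width,
                   color=_color(style, i), label=name)
        ax.set_ylabel("% of eyes", fontsize=8)
        ax.legend(fontsize=5)
    elif panel.kind == "stability":
        for i, (name, s) in enumerate(panel.series.items()):
            ts = [p["t"] for p in s["series"]]
            means = [p["mean"] for p in s["series"]]
            sds = [p["sd"] for p in s["series"]]
            ax.errorbar(ts, means, yerr=sds, fmt="-o", markersize=3,
                        linewidth=1, capsize=2, color=_color(style, i),
                        label=name)
        ns = " | ".join(
            f"{name}: N=" + ",".join(str(p["n"]) for p in s["series"])
            for name, s in panel.series.items()
        )
        ax.set_xlabel(f"time point (0 = preop)\n{ns}", fontsize=6)
        ax.set_ylabel("SEQ (D)", fontsize=8)
        ax.legend(fontsize=5)
    if not ax.get_title():
        ax.set_title(panel.title, fontsize=7)
    stat = _stat_text(ann)
    if stat:
        ax.annotate(stat, xy=(0.02, 0.98), xycoords="axes fraction",
                    fontsize=5, va="top")
    ax.tick_params(labelsize=6)


def render_panel(panel: PanelData, style: RenderStyle, path: str | Path) -> Path:
    """Render one panel to a TIFF with the panel dpi in its metadata."""
    fig, ax = plt.subplots(figsize=style.panel_size)
    try:
        _render_into(ax, panel, style)
        fig.tight_layout()
        fig.savefig(path, dpi=style.dpi_panel, format="tiff")
    finally:
        plt.close(fig)
    return Path(path)


def render_and_export(
    panels: Mapping[str, PanelData], style: RenderStyle
) -> dict:
    """Write one TIFF per panel plus the composite one-page figure.

    Returns a manifest: panel files, the composite file, and the dpi each
    was written at.  The composite is a fixed 2 x 5 grid in panel order
    A-J.
    """
    out_dir = Path(style.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    groups = "_".join(style.group_names) if style.group_names else "group"
    groups = groups.replace(" ", "-").replace("/", "-")
    manifest: dict = {
        "panel_files": {},
        "dpi_panel": style.dpi_panel,
        "dpi_composite": style.dpi_composite,
    }
    for pid in PANEL_IDS:
        if pid not in panels:
            continue
        path = out_dir / f"panel_{pid}_{groups}.tiff"
        render_panel(panels[pid], style, path)
        manifest["panel_files"][pid] = str(path)

    fig, axes = plt.subplots(5, 2, figsize=style.composite_size)
    try:
        for ax, pid in zip(axes.ravel(order="C"), PANEL_IDS):
            if pid in panels:
                _render_into(ax, panels[pid], style)
                ax.set_title(f"{pid}. {panels[pid].title}", fontsize=6)
            else:
                ax.axis("off")
        fig.tight_layout()
        composite = out_dir / f"standard_graphs_{groups}.tiff"
        fig.savefig(composite, dpi=style.dpi_composite, format="tiff")
    finally:
        plt.close(fig)
    manifest["composite_file"] = str(composite)
    return manifest
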