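"""Computation of the standard outcome panels A-J, decoupled from rendering.

Each panel is computed into a :class:`PanelData` value — binned series,
annotations (Ns, means +/- SD, indices, regression text, p-value and
Cohen's d where applicable) — which the rendering layer turns into a
figure.  The panel set:

    A  cumulative Snellen UDVA/CDVA distribution
    B  postop UDVA vs baseline CDVA line difference (+ efficacy index)
    C  CDVA line change, preop to postop (+ safety index)
    D  SEQ accuracy to intended target (within-threshold percentages)
    E  attempted vs achieved SEQ scattergram with linear regression
    F  SEQ stability over time, or DEQ accuracy when no stability data
    G  postop refractive astigmatism magnitude accuracy
    H  TIA vs SIA scattergram with linear regression
    I  correction-index histogram
    J  angle-of-error histogram

The baseline corrected acuity for panels A/B and the efficacy index is the
preoperative CDVA, except for cataract surgery where journal standards
compare against the postoperative CDVA (pseudophakic eyes have no
meaningful preoperative best-corrected reference).

Astigmatism vector analysis is always performed on corneal-plane (0 mm),
positive-cylinder refractions; SEQ/DEQ analyses use the plane the data
were entered at unless ``seq_plane='corneal'`` is configured.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import stats as _stats
from .acuity import (
    AcuityConfig,
    VAMeasure,
    efficacy_index,
    line_change,
    safety_index,
    to_logmar,
)
from .cohorts import Cohort, EyeRecord, N_TIMEPOINTS
from .refraction import Refraction, deq, propagate_vertex, seq, seq_error
from .vectors import vector_outcome

__all__ = [
    "PANEL_IDS",
    "AnalysisConfig",
    "PanelData",
    "CohortAnalysis",
    "within_thresholds",
    "cumulative_va",
    "line_change_histogram",
    "stability_series",
    "compute_panel",
    "compute_all_panels",
]

PANEL_IDS = tuple("ABCDEFGHIJ")

#: Exhaustive line-difference bins used by panels B and C.
LINE_BINS = ("<=-2", "-1", "0", "+1", ">=+2")


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything the panel computations need beyond the cohorts.

    procedure
        LVC, RLE, ICL or CAT.  Only CAT changes behaviour: panels A/B and
        the efficacy index use the postoperative CDVA as baseline.
    design
        single, unpaired or paired; decides whether and how two-group
        statistics are attached.
    seq_plane
        'entered' (default) analyses SEQ/DEQ at the plane the refractions
        were recorded at; 'corneal' converts to 0 mm first.  Astigmatism
        vectors always use the corneal plane.
    stability_pair
        1-based indices of the two postoperative SEQ time points whose
        change feeds the stability percentage (default: first and last
        populated).
    """

    procedure: str = "LVC"
    design: str = "single"
    acuity: AcuityConfig = field(default_factory=AcuityConfig)
    seq_thresholds: tuple[float, ...] = (0.25, 0.50, 0.75, 1.00)
    deq_thresholds: tuple[float, ...] = (0.25, 0.50, 0.75, 1.00, 2.00)
    astig_thresholds: tuple[float, ...] = (0.50, 0.75, 1.00)
    stability_threshold: float = 0.50
    stability_pair: tuple[int, int] | None = None
    seq_plane: str = "entered"
    seq_bin_width: float = 0.25
    ci_bin_width: float = 0.1
    aoe_bin_width: float = 5.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.procedure not in {"LVC", "RLE", "ICL", "CAT"}:
            raise ValueError(f"unknown procedure {self.procedure!r}")
        if self.design not in {"single", "unpaired", "paired"}:
            raise ValueError(f"unknown design {self.design!r}")
        if self.seq_plane not in {"entered", "corneal"}:
            raise ValueError(f"seq_plane must be 'entered' or 'corneal'")


@dataclass(frozen=True)
class PanelData:
    """The computed content of one standard graph.

    series maps group name -> plain-python series payload (bin labels and
    percentages, scatter point lists, or per-timepoint summaries);
    annotations maps group name (or 'comparison') -> displayed numbers.
    """

    panel_id: str
    kind: str
    title: str
    y_axis: str
    series: dict
    annotations: dict


class CohortAnalysis:
    """Per-eye derived quantities for one cohort under one configuration."""

    def __init__(self, cohort: Cohort, cfg: AnalysisConfig):
        self.cohort = cohort
        self.cfg = cfg
        acu = cfg.acuity
        recs = cohort.records
        self.n = len(recs)

        def seq_ref(r: Refraction) -> Refraction:
            return propagate_vertex(r, 0.0) if cfg.seq_plane == "corneal" else r

        self.preop_corneal = [propagate_vertex(r.preop, 0.0) for r in recs]
        self.target_corneal = [propagate_vertex(r.target, 0.0) for r in recs]
        self.postop_corneal = [propagate_vertex(r.postop, 0.0) for r in recs]

        self.seq_preop = np.array([seq(seq_ref(r.preop)) for r in recs])
        self.seq_target = np.array([seq(seq_ref(r.target)) for r in recs])
        self.seq_postop = np.array([seq(seq_ref(r.postop)) for r in recs])
        self.seq_err = np.array(
            [seq_error(seq_ref(r.postop), seq_ref(r.target)) for r in recs]
        )
        self.attempted = self.seq_target - self.seq_preop
        self.achieved = self.seq_postop - self.seq_preop
        self.deq_post = np.array([deq(seq_ref(r.postop)) for r in recs])
        self.astig_post = np.array(
            [abs(r.cylinder) for r in self.postop_corneal]
        )

        self.preop_cdva = [r.preop_cdva for r in recs]
        self.postop_cdva = [r.postop_cdva for r in recs]
        self.postop_udva = [r.postop_udva for r in recs]
        self.baseline_cdva = (
            self.postop_cdva if cfg.procedure == "CAT" else self.preop_cdva
        )
        self.preop_cdva_lm = np.array([to_logmar(v, acu) for v in self.preop_cdva])
        self.postop_cdva_lm = np.array([to_logmar(v, acu) for v in self.postop_cdva])
        self.postop_udva_lm = np.array([to_logmar(v, acu) for v in self.postop_udva])

        self.cdva_change = np.array(
            [line_change(r.preop_cdva, r.postop_cdva, acu) for r in recs]
        )
        self.udva_vs_baseline = np.array(
            [
                line_change(base, r.postop_udva, acu)
                for base, r in zip(self.baseline_cdva, recs)
            ]
        )

        outcomes = [
            vector_outcome(p, t, q)
            for p, t, q in zip(
                self.preop_corneal, self.target_corneal, self.postop_corneal
            )
        ]
        self.tia_mag = np.array([o.tia.magnitude for o in outcomes])
        self.sia_mag = np.array([o.sia.magnitude for o in outcomes])
        self.ci = np.array(
            [math.nan if o.correction_index is None else o.correction_index
             for o in outcomes]
        )
        self.aoe = np.array(
            [math.nan if o.angle_of_error is None else o.angle_of_error
             for o in outcomes]
        )

        # SEQ time series: column t (0-based) of the optional stability data
        self.seq_series = [
            np.array(
                [math.nan if r.seq_series[t] is None else r.seq_series[t]
                 for r in recs]
            )
            for t in range(N_TIMEPOINTS)
        ]
        self.populated_timepoints = [
            t + 1 for t in range(N_TIMEPOINTS)
            if np.any(np.isfinite(self.seq_series[t]))
        ]


# ---------------------------------------------------------------------------
# elemental panel computations


def within_thresholds(
    values: Sequence[float], thresholds: Sequence[float]
) -> list[float]:
    """Percentage of |value| <= t for each threshold t (inclusive boundary)."""
    v = np.abs(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("within_thresholds needs a non-empty sample")
    ts = list(thresholds)
    if any(t <= 0 for t in ts) or any(b <= a for a, b in zip(ts, ts[1:])):
        raise ValueError("thresholds must be positive and ascending")
    return [float(100.0 * np.count_nonzero(v <= t) / v.size) for t in ts]


def cumulative_va(
    logmars: Sequence[float],
    lines: Sequence[float],
    cfg: AcuityConfig = AcuityConfig(),
) -> list[float]:
    """Cumulative % of eyes seeing each configured Snellen line or better.

    An eye counts at line 20/XX when its logMAR is at or below the line's
    threshold (a 1e-9 tolerance absorbs floating-point representation of
    letter offsets).  The series is monotone non-decreasing by
    construction.
    """
    lm = np.asarray(logmars, dtype=float)
    if lm.size == 0:
        raise ValueError("cumulative_va needs a non-empty sample")
    ls = list(lines)
    if any(b <= a for a, b in zip(ls, ls[1:])):
        raise ValueError("Snellen lines must be ascending")
    out = []
    for denom in ls:
        thr = math.log10(denom / 20.0) + 1e-9
        out.append(float(100.0 * np.count_nonzero(lm <= thr) / lm.size))
    return out


def line_change_histogram(changes: Sequence[int]) -> dict[str, float]:
    """Bin whole-line acuity changes into {<=-2, -1, 0, +1, >=+2} percentages.

    The extreme bins are open-ended so the partition is exhaustive; the
    five percentages always sum to 100.
    """
    c = np.asarray(changes, dtype=int)
    if c.size == 0:
        raise ValueError("line_change_histogram needs a non-empty sample")
    counts = [
        np.count_nonzero(c <= -2),
        np.count_nonzero(c == -1),
        np.count_nonzero(c == 0),
        np.count_nonzero(c == 1),
        np.count_nonzero(c >= 2),
    ]
    return {
        label: float(100.0 * k / c.size) for label, k in zip(LINE_BINS, counts)
    }


def stability_series(
    analyses: Sequence[CohortAnalysis],
    pair: tuple[int, int] | None = None,
    threshold: float = 0.50,
) -> dict:
    """Per-timepoint SEQ summaries plus the selected-pair change fraction.

    Time point 0 is the preoperative SEQ; 1..5 are the optional
    postoperative columns.  Eyes missing a time point are excluded at that
    time point only.  The change percentage counts eyes, present at both
    selected points, whose SEQ moved strictly more than ``threshold``
    dioptres (a change of exactly the threshold does not count).
    """
    populated = sorted(
        set().union(*(a.populated_timepoints for a in analyses))
    )
    if len(populated) < 2:
        raise ValueError(
            "stability analysis needs at least two populated postoperative "
            "time points"
        )
    if pair is None:
        pair = (populated[0], populated[-1])
    t1, t2 = pair
    if t1 not in populated or t2 not in populated or t1 == t2:
        raise ValueError(
            f"selected stability pair {pair} is not among the populated "
            f"time points {populated}"
        )
    out: dict = {"timepoints": [0] + populated, "pair": (t1, t2), "groups": {}}
    for a in analyses:
        per_tp = []
        for t in [0] + populated:
            vals = a.seq_preop if t == 0 else a.seq_series[t - 1]
            vals = vals[np.isfinite(vals)]
            if vals.size:
                s = _stats.summarize(vals)
                per_tp.append({"t": t, "mean": s.mean, "sd": s.sd, "n": s.n})
            else:
                per_tp.append({"t": t, "mean": math.nan, "sd": math.nan, "n": 0})
        v1 = a.seq_series[t1 - 1]
        v2 = a.seq_series[t2 - 1]
        both = np.isfinite(v1) & np.isfinite(v2)
        n_both = int(np.count_nonzero(both))
        if n_both == 0:
            pct = math.nan
            deltas = np.array([])
        else:
            deltas = v2[both] - v1[both]
            pct = float(100.0 * np.count_nonzero(np.abs(deltas) > threshold) / n_both)
        out["groups"][a.cohort.name] = {
            "series": per_tp,
            "pct_changed": pct,
            "n_pair": n_both,
            "pair_deltas": [float(d) for d in deltas],
        }
    return out


# ---------------------------------------------------------------------------
# panel assembly


def _attach_comparison(
    cfg: AnalysisConfig,
    a_vals: np.ndarray,
    b_vals: np.ndarray | None,
) -> _stats.StatResult | None:
    """Run the design-appropriate two-group test on a panel's variable."""
    if cfg.design == "single" or b_vals is None:
        return None
    xa = np.asarray(a_vals, dtype=float)
    xb = np.asarray(b_vals, dtype=float)
    if cfg.design == "paired":
        # paired analyses require both members of a pair to be defined
        if xa.size == xb.size:
            mask = np.isfinite(xa) & np.isfinite(xb)
            xa, xb = xa[mask], xb[mask]
        else:  # defensive: fall back to unpaired on misalignment
            xa, xb = xa[np.isfinite(xa)], xb[np.isfinite(xb)]
            return _stats.compare(xa, xb, "unpaired", cfg.alpha)
        if xa.size < 2:
            return None
        return _stats.compare(xa, xb, "paired", cfg.alpha)
    xa = xa[np.isfinite(xa)]
    xb = xb[np.isfinite(xb)]
    if xa.size < 2 or xb.size < 2:
        return None
    return _stats.compare(xa, xb, "unpaired", cfg.alpha)


def _histogram(values: np.ndarray, width: float, center: float = 0.0) -> dict:
    """Equal-width exhaustive histogram as {label: percent} plus bin edges."""
    v = values[np.isfinite(values)]
    if v.size == 0:
        return {"labels": [], "percent": [], "edges": []}
    lo = math.floor((v.min() - center) / width)
    hi = math.ceil((v.max() - center) / width)
    if hi == lo:
        hi = lo + 1
    edges = center + width * np.arange(lo, hi + 1)
    counts, _ = np.histogram(v, bins=edges)
    # np.histogram's last bin is closed, so the partition is exhaustive
    pct = 100.0 * counts / v.size
    labels = [
        f"[{edges[i]:g}, {edges[i + 1]:g})" if i < len(counts) - 1
        else f"[{edges[i]:g}, {edges[i + 1]:g}]"
        for i in range(len(counts))
    ]
    return {
        "labels": labels,
        "percent": [float(p) for p in pct],
        "edges": [float(e) for e in edges],
    }


def _summary_dict(values: np.ndarray) -> dict:
    v = values[np.isfinite(values)]
    if v.size == 0:
        return {"mean": math.nan, "sd": math.nan, "n": 0}
    s = _stats.summarize(v)
    return {"mean": s.mean, "sd": s.sd, "n": s.n}


def _stat_dict(res: _stats.StatResult | None) -> dict | None:
    if res is None:
        return None
    return {
        "test": res.test_name,
        "statistic": res.statistic,
        "p": res.p_value,
        "d": res.effect_size_d,
        "n_a": res.n_a,
        "n_b": res.n_b,
    }


def compute_panel(
    panel_id: str,
    cohorts: Sequence[Cohort],
    cfg: AnalysisConfig,
    _analyses: Sequence[CohortAnalysis] | None = None,
) -> PanelData:
    """Compute one standard panel for one or two cohorts.

    Deterministic: identical cohorts and configuration yield identical
    PanelData.  Unknown panel ids raise ValueError.
    """
    if panel_id not in PANEL_IDS:
        raise ValueError(f"unknown panel id {panel_id!r}; expected one of A..J")
    analyses = (
        list(_analyses)
        if _analyses is not None
        else [CohortAnalysis(c, cfg) for c in cohorts]
    )
    a0 = analyses[0]
    b0 = analyses[1] if len(analyses) > 1 else None
    acu = cfg.acuity
    lines = acu.display_lines
    series: dict = {}
    ann: dict = {}

    if panel_id == "A":
        for an in analyses:
            series[an.cohort.name] = {
                "lines": [float(x) for x in lines],
                "postop_udva": cumulative_va(an.postop_udva_lm, lines, acu),
                "postop_cdva": cumulative_va(an.postop_cdva_lm, lines, acu),
                "baseline_cdva": cumulative_va(
                    [to_logmar(v, acu) for v in an.baseline_cdva], lines, acu
                ),
            }
            ann[an.cohort.name] = {
                "n": an.n,
                "postop_udva_logmar": _summary_dict(an.postop_udva_lm),
                "postop_cdva_logmar": _summary_dict(an.postop_cdva_lm),
                "preop_cdva_logmar": _summary_dict(an.preop_cdva_lm),
            }
        ann["comparison"] = _stat_dict(
            _attach_comparison(
                cfg, a0.postop_udva_lm, b0.postop_udva_lm if b0 else None
            )
        )
        return PanelData(
            "A", "cumulative_va", "Cumulative Snellen visual acuity",
            "percent", series, ann,
        )

    if panel_id == "B":
        baseline_name = "postop CDVA" if cfg.procedure == "CAT" else "preop CDVA"
        for an in analyses:
            series[an.cohort.name] = line_change_histogram(an.udva_vs_baseline)
            ann[an.cohort.name] = {
                "n": an.n,
                "efficacy_index": efficacy_index(
                    an.postop_udva, an.baseline_cdva, acu
                ),
            }
        ann["baseline"] = baseline_name
        ann["comparison"] = _stat_dict(
            _attach_comparison(
                cfg, a0.postop_udva_lm, b0.postop_udva_lm if b0 else None
            )
        )
        return PanelData(
            "B", "line_histogram",
            f"Postop UDVA vs {baseline_name} (lines difference)",
            "percent", series, ann,
        )

    if panel_id == "C":
        for an in analyses:
            series[an.cohort.name] = line_change_histogram(an.cdva_change)
            ann[an.cohort.name] = {
                "n": an.n,
                "safety_index": safety_index(an.postop_cdva, an.preop_cdva, acu),
            }
        ann["comparison"] = _stat_dict(
            _attach_comparison(
                cfg,
                a0.cdva_change.astype(float),
                b0.cdva_change.astype(float) if b0 else None,
            )
        )
        return PanelData(
            "C", "line_histogram", "Change in lines of CDVA (preop to postop)",
            "percent", series, ann,
        )

    if panel_id == "D":
        for an in analyses:
            series[an.cohort.name] = {
                "thresholds": list(cfg.seq_thresholds),
                "within": within_thresholds(an.seq_err, cfg.seq_thresholds),
                "hist": _histogram(an.seq_err, cfg.seq_bin_width),
            }
            ann[an.cohort.name] = {
                "n": an.n,
                "seq_error": _summary_dict(an.seq_err),
            }
        ann["comparison"] = _stat_dict(
            _attach_comparison(cfg, a0.seq_err, b0.seq_err if b0 else None)
        )
        return PanelData(
            "D", "threshold_histogram", "SEQ accuracy to intended target",
            "percent", series, ann,
        )

    if panel_id == "E":
        for an in analyses:
            fit = _stats.linfit(an.attempted, an.achieved)
            series[an.cohort.name] = {
                "x": [float(v) for v in an.attempted],
                "y": [float(v) for v in an.achieved],
            }
            ann[an.cohort.name] = {
                "n": an.n,
                "fit": {
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                    "r_squared": fit.r_squared,
                    "equation": fit.equation("achieved", "·attempted"),
                },
                "attempted": _summary_dict(an.attempted),
                "attempted_range": [
                    float(an.attempted.min()), float(an.attempted.max())
                ],
            }
        ann["comparison"] = None  # regression panel carries no hypothesis test
        return PanelData(
            "E", "scatter", "Attempted vs achieved SEQ (D)",
            "diopters", series, ann,
        )

    if panel_id == "F":
        n_tp = min(
            (len(an.populated_timepoints) for an in analyses), default=0
        )
        if n_tp >= 2:
            stab = stability_series(
                analyses, cfg.stability_pair, cfg.stability_threshold
            )
            for an in analyses:
                series[an.cohort.name] = stab["groups"][an.cohort.name]
                ann[an.cohort.name] = {
                    "n": an.n,
                    "pct_changed": stab["groups"][an.cohort.name]["pct_changed"],
                    "pair": stab["pair"],
                    "threshold": cfg.stability_threshold,
                }
            pair_a = np.asarray(
                stab["groups"][a0.cohort.name]["pair_deltas"], dtype=float
            )
            pair_b = (
                np.asarray(
                    stab["groups"][b0.cohort.name]["pair_deltas"], dtype=float
                )
                if b0
                else None
            )
            ann["comparison"] = _stat_dict(
                _attach_comparison(cfg, pair_a, pair_b)
            )
            return PanelData(
                "F", "stability", "SEQ stability over time",
                "diopters", series, ann,
            )
        for an in analyses:
            series[an.cohort.name] = {
                "thresholds": list(cfg.deq_thresholds),
                "within": within_thresholds(an.deq_post, cfg.deq_thresholds),
            }
            ann[an.cohort.name] = {
                "n": an.n,
                "deq": _summary_dict(an.deq_post),
            }
        ann["comparison"] = _stat_dict(
            _attach_comparison(cfg, a0.deq_post, b0.deq_post if b0 else None)
        )
        return PanelData(
            "F", "deq_histogram", "Postoperative defocus equivalent accuracy",
            "percent", series, ann,
        )

    if panel_id == "G":
        for an in analyses:
            series[an.cohort.name] = {
                "thresholds": list(cfg.astig_thresholds),
                "within": within_thresholds(an.astig_post, cfg.astig_thresholds),
            }
            ann[an.cohort.name] = {
                "n": an.n,
                "astig": _summary_dict(an.astig_post),
            }
        ann["comparison"] = _stat_dict(
            _attach_comparison(cfg, a0.astig_post, b0.astig_post if b0 else None)
        )
        return PanelData(
            "G", "threshold_histogram",
            "Postoperative refractive astigmatism accuracy",
            "percent", series, ann,
        )

    if panel_id == "H":
        for an in analyses:
            mask = an.tia_mag > 0
            x = an.tia_mag[mask]
            y = an.sia_mag[mask]
            fit = None
            if x.size >= 3 and float(np.std(x)) > 0:
                f = _stats.linfit(x, y)
                fit = {
                    "slope": f.slope,
                    "intercept": f.intercept,
                    "r_squared": f.r_squared,
                    "equation": f.equation("SIA", "·TIA"),
                }
            series[an.cohort.name] = {
                "x": [float(v) for v in x],
                "y": [float(v) for v in y],
            }
            ann[an.cohort.name] = {
                "n": int(x.size),
                "n_excluded": int(an.n - x.size),
                "tia": _summary_dict(x),
                "sia": _summary_dict(y),
                "fit": fit,
            }
        ann["comparison"] = None
        return PanelData(
            "H", "scatter", "TIA vs SIA magnitude (D)", "diopters", series, ann,
        )

    if panel_id == "I":
        for an in analyses:
            series[an.cohort.name] = _histogram(an.ci, cfg.ci_bin_width)
            ann[an.cohort.name] = {
                "n": int(np.count_nonzero(np.isfinite(an.ci))),
                "n_excluded": int(np.count_nonzero(~np.isfinite(an.ci))),
                "ci": _summary_dict(an.ci),
            }
        ann["comparison"] = _stat_dict(
            _attach_comparison(cfg, a0.ci, b0.ci if b0 else None)
        )
        return PanelData(
            "I", "histogram", "Correction index", "percent", series, ann,
        )

    # panel J
    for an in analyses:
        series[an.cohort.name] = _histogram(
            an.aoe, cfg.aoe_bin_width, center=-cfg.aoe_bin_width / 2.0
        )
        ann[an.cohort.name] = {
            "n": int(np.count_nonzero(np.isfinite(an.aoe))),
            "n_excluded": int(np.count_nonzero(~np.isfinite(an.aoe))),
            "aoe": _summary_dict(an.aoe),
        }
    ann["comparison"] = _stat_dict(
        _attach_comparison(cfg, a0.aoe, b0.aoe if b0 else None)
    )
    return PanelData(
        "J", "histogram", "Angle of error (degrees)", "percent", series, ann,
    )


def compute_all_panels(
    cohorts: Sequence[Cohort], cfg: AnalysisConfig
) -> dict[str, PanelData]:
    """Compute every panel A-J, sharing the per-cohort derivations."""
    analyses = [CohortAnalysis(c, cfg) for c in cohorts]
    return {
        pid: compute_panel(pid, cohorts, cfg, _analyses=analyses)
        for pid in PANEL_IDS
    }
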