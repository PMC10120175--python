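"""Synthetic refractive-surgery cohorts with controllable outcome structure.

The generator draws a preoperative population (sphere, cylinder magnitude,
axis), fixes an intended target, and applies a treatment model expressed
in exactly the quantities the analysis estimates: the target-induced
astigmatism vector is scaled by a sampled correction index and rotated by
a sampled axis error in doubled-angle space, and the achieved spherical
equivalent is the intended one plus a systematic bias and noise.  Because
the treatment acts on the analysis's own vector decomposition, recovering
the generator parameters from the standard panels is a closed loop: the
mean panel-I correction index estimates ``ci_mean``, the mean panel-D SEQ
error estimates ``seq_bias``, and an injected stability shift reappears
as exactly the injected fraction.

Visual acuities follow a simple monotone defocus-acuity link: uncorrected
logMAR = max(0, k * defocus equivalent) + noise, snapped to Snellen chart
tokens; corrected acuity moves by a sampled whole-line change.

Three presets emulate typical demonstration studies: a paired
(contralateral-eye) hyperopic-astigmatism laser vision correction
comparison, a single-group toric phakic IOL cohort with moderate-to-high
astigmatism, and a two-group myopic-astigmatism cataract comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .acuity import AcuityConfig, VAMeasure, logmar_to_snellen, to_logmar
from .cohorts import Cohort, EyeRecord, N_TIMEPOINTS, write_group_file
from .refraction import Refraction, convert_cyl_sign, propagate_vertex, seq, deq
from .vectors import AstigVector, tia, to_double_angle

__all__ = ["Scenario", "generate", "preset", "PRESET_NAMES"]

PRESET_NAMES = ("trial1", "trial2", "trial3")


@dataclass(frozen=True)
class Scenario:
    """Population, treatment and response model for one simulated study.

    All dispersion parameters are standard deviations (>= 0).  For a
    paired design the preoperative draws are shared between the two
    groups (fellow eyes) and ``group_b`` holds the parameter overrides of
    the second treatment arm.
    """

    name: str = "group"
    n_eyes: int = 100
    design: str = "single"  # single | unpaired | paired
    seed: int = 0

    # preop population (spectacle plane, negative-cylinder notation)
    sphere_mean: float = -3.0
    sphere_sd: float = 1.0
    cyl_mean: float = 1.0  # magnitude of the (negative) cylinder
    cyl_sd: float = 0.5
    axis_mode: str = "uniform"  # uniform | wtr (with-the-rule bias)
    vertex: float = 12.0

    # intended target (spectacle plane)
    target_sphere: float = 0.0

    # treatment model (doubled-angle space, corneal plane)
    seq_bias: float = 0.0
    seq_noise_sd: float = 0.15
    ci_mean: float = 1.0
    ci_sd: float = 0.0
    axis_error_sd: float = 0.0

    # visual-acuity response
    k_defocus: float = 0.3  # logMAR per dioptre of defocus equivalent
    udva_noise_sd: float = 0.02
    cdva_line_probs: tuple[tuple[int, float], ...] = (
        (-2, 0.01), (-1, 0.05), (0, 0.82), (1, 0.10), (2, 0.02),
    )
    preop_cdva_line_probs: tuple[tuple[float, float], ...] = (
        (16.0, 0.15), (20.0, 0.75), (25.0, 0.10),
    )

    # stability: SEQ at n_timepoints postop visits
    n_timepoints: int = 0
    drift_per_timepoint: float = 0.0
    drift_noise_sd: float = 0.0
    shift_fraction: float = 0.0  # fraction of eyes shifted between the pair
    shift_magnitude: float = 0.0
    shift_pair: tuple[int, int] = (1, 2)

    # second arm (paired/unpaired designs): field overrides for group B
    group_b: tuple[tuple[str, object], ...] = ()

    def __post_init__(self) -> None:
        if self.n_eyes < 1:
            raise ValueError("n_eyes must be >= 1")
        if self.design not in {"single", "unpaired", "paired"}:
            raise ValueError(f"unknown design {self.design!r}")
        for f in ("sphere_sd", "cyl_sd", "seq_noise_sd", "ci_sd",
                  "axis_error_sd", "udva_noise_sd", "drift_noise_sd"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        if not 0.0 <= self.shift_fraction <= 1.0:
            raise ValueError("shift_fraction must be in [0, 1]")
        if self.n_timepoints > N_TIMEPOINTS:
            raise ValueError(f"at most {N_TIMEPOINTS} time points supported")
        probs = [p for _, p in self.cdva_line_probs]
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("cdva_line_probs must sum to 1")
        probs = [p for _, p in self.preop_cdva_line_probs]
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("preop_cdva_line_probs must sum to 1")

    def arm_b(self) -> "Scenario":
        """The second treatment arm: this scenario with group-B overrides."""
        overrides = dict(self.group_b)
        overrides.setdefault("name", f"{self.name}_B")
        return replace(self, group_b=(), **overrides)


def _quantize(r: Refraction) -> Refraction:
    """Snap a refraction to clinical resolution (0.01 D, 0.1 degree).

    Data files carry clinically meaningful precision; quantizing here also
    keeps the written files exact round-trips of the in-memory records.
    """
    return Refraction(
        round(r.sphere, 2), round(r.cylinder, 2), round(r.axis, 1), r.vertex
    )


def _sample_preop(s: Scenario, rng: np.random.Generator) -> list[Refraction]:
    spheres = rng.normal(s.sphere_mean, s.sphere_sd, s.n_eyes)
    cyls = np.abs(rng.normal(s.cyl_mean, s.cyl_sd, s.n_eyes))
    if s.axis_mode == "wtr":
        axes = np.mod(rng.normal(180.0, 20.0, s.n_eyes), 180.0)
    else:
        axes = rng.uniform(0.0, 180.0, s.n_eyes)
    axes[axes == 0.0] = 180.0
    return [
        _quantize(Refraction(float(sp), -float(cy), float(ax), s.vertex))
        for sp, cy, ax in zip(spheres, cyls, axes)
    ]


def _refraction_from(seq_value: float, astig: AstigVector) -> Refraction:
    """Corneal-plane refraction with a given SEQ and doubled-angle astigmatism.

    Built in positive-cylinder form (sphere = SEQ - C/2) and converted to
    the negative-cylinder notation used in data files.
    """
    mag = astig.magnitude
    axis = astig.axis
    pos = Refraction(seq_value - mag / 2.0, mag, axis, 0.0)
    return convert_cyl_sign(pos) if mag > 0 else pos


def _pick_line(probs: Sequence[tuple[float, float]],
               rng: np.random.Generator) -> float:
    values = [v for v, _ in probs]
    p = [q for _, q in probs]
    return float(rng.choice(values, p=p))


def _shift_line(va: VAMeasure, lines: int, chart: tuple[float, ...]) -> VAMeasure:
    """Move an acuity by whole chart lines (positive = worse denominator)."""
    try:
        i = chart.index(va.denominator)
    except ValueError:
        i = min(range(len(chart)), key=lambda j: abs(chart[j] - va.denominator))
    j = min(max(i + lines, 0), len(chart) - 1)
    return VAMeasure(chart[j], va.letter_offset if j == i else 0)


def _simulate_arm(
    s: Scenario,
    preop: list[Refraction],
    rng: np.random.Generator,
    acu: AcuityConfig,
) -> list[EyeRecord]:
    records: list[EyeRecord] = []
    chart = acu.snellen_lines
    n_shifted = int(round(s.shift_fraction * s.n_eyes))
    target = Refraction(s.target_sphere, 0.0, 180.0, 0.0)
    for i, pre in enumerate(preop):
        pre_corneal = propagate_vertex(pre, 0.0)
        intended = tia(pre_corneal, target)
        ci = rng.normal(s.ci_mean, s.ci_sd) if s.ci_sd > 0 else s.ci_mean
        ci = max(ci, 0.0)
        axis_err = (
            rng.normal(0.0, s.axis_error_sd) if s.axis_error_sd > 0 else 0.0
        )
        achieved = _rotate_scale(intended, ci, axis_err)
        pre_vec = to_double_angle(
            -pre_corneal.cylinder, convert_cyl_sign(pre_corneal).axis
        ) if pre_corneal.cylinder < 0 else to_double_angle(
            pre_corneal.cylinder, pre_corneal.axis
        )
        post_vec = pre_vec + achieved
        seq_noise = rng.normal(0.0, s.seq_noise_sd) if s.seq_noise_sd > 0 else 0.0
        post_seq = seq(target) + s.seq_bias + seq_noise
        postop = _quantize(_refraction_from(post_seq, post_vec))

        preop_cdva = VAMeasure(_pick_line(s.preop_cdva_line_probs, rng), 0)
        udva_noise = (
            rng.normal(0.0, s.udva_noise_sd) if s.udva_noise_sd > 0 else 0.0
        )
        udva_lm = max(
            to_logmar(preop_cdva, acu), s.k_defocus * deq(postop)
        ) + udva_noise
        postop_udva = logmar_to_snellen(max(udva_lm, -0.3), acu)
        lines_change = int(_pick_line(
            tuple((float(k), p) for k, p in s.cdva_line_probs), rng
        ))
        # a CDVA gain of one line moves one chart step toward 20/16
        postop_cdva = _shift_line(preop_cdva, -lines_change, chart)

        seq_series: list[float | None] = [None] * N_TIMEPOINTS
        if s.n_timepoints:
            value = post_seq
            for t in range(s.n_timepoints):
                if t > 0:
                    value = value + s.drift_per_timepoint
                    if s.drift_noise_sd > 0:
                        value = value + rng.normal(0.0, s.drift_noise_sd)
                seq_series[t] = value
            if i < n_shifted and s.shift_magnitude != 0.0:
                t_from, t_to = s.shift_pair
                base = seq_series[t_from - 1]
                assert base is not None
                for t in range(t_to - 1, s.n_timepoints):
                    seq_series[t] = seq_series[t] + s.shift_magnitude  # type: ignore[operator]
            seq_series = [
                None if v is None else round(v, 4) for v in seq_series
            ]

        records.append(
            EyeRecord(
                preop=pre,
                preop_cdva=preop_cdva,
                target=Refraction(s.target_sphere, 0.0, 180.0, 0.0),
                postop=postop,
                postop_cdva=postop_cdva,
                postop_udva=postop_udva,
                seq_series=tuple(seq_series),
            )
        )
    return records


def _rotate_scale(v: AstigVector, scale: float, axis_err_deg: float) -> AstigVector:
    """Scale a doubled-angle vector and rotate it by a single-angle error."""
    rad = math.radians(2.0 * axis_err_deg)
    c, s = math.cos(rad), math.sin(rad)
    return AstigVector(
        scale * (v.x * c - v.y * s),
        scale * (v.x * s + v.y * c),
    )


def generate(
    scenario: Scenario,
    out_dir: str | Path | None = None,
    fmt: str = "csv",
    acuity: AcuityConfig | None = None,
) -> tuple[list[Cohort], list[Path]]:
    """Simulate the study and optionally write its data file(s).

    Returns the cohorts (one for a single-group design, two otherwise)
    and the list of files written (empty when ``out_dir`` is None).
    Reproducible: the same scenario (including its seed) always yields
    the same cohorts and byte-identical CSV files.
    """
    acu = acuity or AcuityConfig()
    rng = np.random.default_rng(scenario.seed)
    preop_a = _sample_preop(scenario, rng)
    records_a = _simulate_arm(scenario, preop_a, rng, acu)
    cohorts = [Cohort(name=scenario.name, records=tuple(records_a))]

    if scenario.design != "single":
        arm_b = scenario.arm_b()
        if scenario.design == "paired":
            # fellow eyes: same patients, mirrored preop draws
            preop_b = preop_a
        else:
            preop_b = _sample_preop(arm_b, rng)
        records_b = _simulate_arm(arm_b, preop_b, rng, acu)
        cohorts.append(Cohort(name=arm_b.name, records=tuple(records_b)))

    paths: list[Path] = []
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for cohort in cohorts:
            path = out / f"{cohort.name}.{fmt}"
            write_group_file(cohort.records, path)
            paths.append(path)
    return cohorts, paths


def preset(name: str, seed: int = 0) -> Scenario:
    """A ready-made scenario emulating one of three demonstration studies.

    trial1
        Paired contralateral-eye laser vision correction comparison of two
        excimer lasers in hyperopic eyes with astigmatism; five stability
        time points.
    trial2
        Single-group toric phakic IOL in hyperopic eyes with moderate to
        high astigmatism (no stability columns: the DEQ panel appears).
    trial3
        Two unpaired cataract-surgery groups (two biometers) in
        myopic-astigmatism eyes.
    """
    if name == "trial1":
        return Scenario(
            name="laser_A",
            n_eyes=100,
            design="paired",
            seed=seed,
            sphere_mean=2.5, sphere_sd=0.8,
            cyl_mean=1.2, cyl_sd=0.5,
            seq_bias=-0.05, seq_noise_sd=0.25,
            ci_mean=0.95, ci_sd=0.10, axis_error_sd=5.0,
            n_timepoints=5,
            drift_per_timepoint=0.02, drift_noise_sd=0.05,
            group_b=(
                ("name", "laser_B"),
                ("seq_bias", -0.15),
                ("ci_mean", 0.90),
                ("axis_error_sd", 8.0),
            ),
        )
    if name == "trial2":
        return Scenario(
            name="toric_piol",
            n_eyes=120,
            design="single",
            seed=seed,
            sphere_mean=4.0, sphere_sd=1.2,
            cyl_mean=2.5, cyl_sd=0.8,
            seq_bias=0.05, seq_noise_sd=0.30,
            ci_mean=0.92, ci_sd=0.12, axis_error_sd=6.0,
        )
    if name == "trial3":
        return Scenario(
            name="biometer_A",
            n_eyes=100,
            design="unpaired",
            seed=seed,
            sphere_mean=-4.0, sphere_sd=1.5,
            cyl_mean=1.0, cyl_sd=0.5,
            seq_bias=-0.10, seq_noise_sd=0.35,
            ci_mean=0.90, ci_sd=0.15, axis_error_sd=10.0,
            cdva_line_probs=((-2, 0.0), (-1, 0.02), (0, 0.68), (1, 0.25), (2, 0.05)),
            group_b=(
                ("name", "biometer_B"),
                ("seq_bias", 0.05),
                ("seq_noise_sd", 0.25),
                ("ci_mean", 0.95),
            ),
        )
    raise ValueError(f"unknown preset {name!r}; expected one of {PRESET_NAMES}")
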