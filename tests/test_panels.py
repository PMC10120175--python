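import math

import numpy as np
import pytest

from refractive_outcomes.cohorts import Cohort
from refractive_outcomes.panels import (
    LINE_BINS,
    PANEL_IDS,
    AnalysisConfig,
    CohortAnalysis,
    compute_all_panels,
    compute_panel,
    cumulative_va,
    line_change_histogram,
    stability_series,
    within_thresholds,
)
from refractive_outcomes.simulate import Scenario, generate

from conftest import make_record

SINGLE = AnalysisConfig(design="single")


class TestWithinThresholds:
    def test_worked_example(self):
        got = within_thresholds([0, 0.25, -0.30, 0.60], [0.25, 0.50, 0.75, 1.00])
        assert got == pytest.approx([50.0, 75.0, 100.0, 100.0])

    def test_all_zero(self):
        assert within_thresholds([0.0] * 7, [0.25, 0.5]) == [100.0, 100.0]

    def test_boundary_inclusive(self):
        assert within_thresholds([0.5, -0.5], [0.5]) == [100.0]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            within_thresholds([], [0.25])


class TestCumulativeVA:
    def test_all_2020(self):
        lines = (16, 20, 25, 32)
        got = cumulative_va([0.0, 0.0], lines)
        assert got == pytest.approx([0.0, 100.0, 100.0, 100.0])

    def test_mixed(self):
        lines = (16, 20, 25)
        lm = [math.log10(16 / 20), math.log10(25 / 20)]
        assert cumulative_va(lm, lines) == pytest.approx([50.0, 50.0, 100.0])

    def test_monotone_on_random_cohorts(self, rng):
        lines = (16, 20, 25, 32, 40, 50)
        for _ in range(20):
            lm = rng.normal(0.1, 0.2, 50)
            series = cumulative_va(lm, lines)
            assert all(b >= a for a, b in zip(series, series[1:]))


class TestLineChangeHistogram:
    def test_all_unchanged(self):
        h = line_change_histogram([0] * 10)
        assert h["0"] == 100.0

    def test_one_eye_per_bin(self):
        h = line_change_histogram([-3, -1, 0, 1, 4])
        assert all(h[b] == pytest.approx(20.0) for b in LINE_BINS)

    def test_partition_sums_to_100(self, rng):
        h = line_change_histogram(rng.integers(-4, 5, 200))
        assert sum(h.values()) == pytest.approx(100.0, abs=0.01)


def _stability_cohort(n=10, shifted=0, delta=0.75):
    records = []
    for i in range(n):
        series = (0.0, 0.0, (delta if i < shifted else 0.0), None, None)
        records.append(make_record(seq_series=series))
    return Cohort(name="s", records=tuple(records))


class TestStability:
    def test_constant_series_zero_changed(self):
        an = CohortAnalysis(_stability_cohort(), SINGLE)
        out = stability_series([an], pair=(1, 3))
        assert out["groups"]["s"]["pct_changed"] == 0.0

    def test_injected_shift_fraction_recovered(self):
        an = CohortAnalysis(_stability_cohort(n=10, shifted=3), SINGLE)
        out = stability_series([an], pair=(1, 3))
        assert out["groups"]["s"]["pct_changed"] == pytest.approx(30.0)

    def test_exact_threshold_change_not_counted(self):
        an = CohortAnalysis(_stability_cohort(n=4, shifted=2, delta=0.50), SINGLE)
        out = stability_series([an], pair=(1, 3))
        assert out["groups"]["s"]["pct_changed"] == 0.0

    def test_per_timepoint_n_shrinks(self):
        records = [
            make_record(seq_series=(0.1, 0.2, None, None, None)),
            make_record(seq_series=(0.1, None, None, None, None)),
        ]
        an = CohortAnalysis(Cohort(name="s", records=tuple(records)), SINGLE)
        out = stability_series([an], pair=(1, 2))
        ns = {p["t"]: p["n"] for p in out["groups"]["s"]["series"]}
        assert ns[1] == 2 and ns[2] == 1
        assert out["groups"]["s"]["n_pair"] == 1

    def test_invalid_pair_rejected(self):
        an = CohortAnalysis(_stability_cohort(), SINGLE)
        with pytest.raises(ValueError, match="populated"):
            stability_series([an], pair=(3, 5))


class TestComputePanel:
    def test_unknown_panel_rejected(self, perfect_cohort):
        with pytest.raises(ValueError, match="unknown panel"):
            compute_panel("K", [perfect_cohort], SINGLE)

    def test_perfect_cohort_identities(self, perfect_cohort):
        panels = compute_all_panels([perfect_cohort], SINGLE)
        name = perfect_cohort.name
        assert panels["B"].annotations[name]["efficacy_index"] == pytest.approx(1.0)
        assert panels["C"].annotations[name]["safety_index"] == pytest.approx(1.0)
        assert panels["D"].series[name]["within"][0] == 100.0
        assert panels["G"].series[name]["within"][0] == 100.0
        fit = panels["E"].annotations[name]["fit"]
        assert fit["slope"] == pytest.approx(1.0)
        assert fit["r_squared"] == pytest.approx(1.0)
        assert panels["I"].annotations[name]["ci"]["mean"] == pytest.approx(1.0)
        assert panels["J"].annotations[name]["aoe"]["mean"] == pytest.approx(0.0)
        assert panels["J"].annotations[name]["aoe"]["sd"] == pytest.approx(0.0)
        assert panels["F"].kind == "deq_histogram"  # no stability columns

    def test_panel_thresholds(self, perfect_cohort):
        panels = compute_all_panels([perfect_cohort], SINGLE)
        name = perfect_cohort.name
        assert panels["D"].series[name]["thresholds"] == [0.25, 0.50, 0.75, 1.00]
        assert panels["F"].series[name]["thresholds"] == [0.25, 0.50, 0.75, 1.00, 2.00]
        assert panels["G"].series[name]["thresholds"] == [0.50, 0.75, 1.00]

    def test_single_group_has_no_comparisons(self, perfect_cohort):
        panels = compute_all_panels([perfect_cohort], SINGLE)
        assert all(p.annotations.get("comparison") is None for p in panels.values())

    def test_two_group_comparisons_attached(self):
        cfg = AnalysisConfig(design="unpaired")
        cohorts, _ = generate(
            Scenario(n_eyes=40, seed=11, design="unpaired", seq_noise_sd=0.3,
                     ci_mean=0.9, ci_sd=0.1, axis_error_sd=6.0)
        )
        panels = compute_all_panels(cohorts, cfg)
        for pid in ("A", "B", "C", "D", "F", "G", "I", "J"):
            cmp_ = panels[pid].annotations["comparison"]
            assert cmp_ is not None and 0 <= cmp_["p"] <= 1
        assert panels["E"].annotations["comparison"] is None
        assert panels["H"].annotations["comparison"] is None

    def test_histogram_partitions_sum_to_100(self):
        cohorts, _ = generate(
            Scenario(n_eyes=60, seed=13, seq_noise_sd=0.4, ci_mean=0.85,
                     ci_sd=0.2, axis_error_sd=12.0)
        )
        panels = compute_all_panels(cohorts, SINGLE)
        name = cohorts[0].name
        for pid in ("B", "C"):
            assert sum(panels[pid].series[name].values()) == pytest.approx(
                100.0, abs=0.01
            )
        for pid in ("I", "J"):
            assert sum(panels[pid].series[name]["percent"]) == pytest.approx(
                100.0, abs=0.01
            )

    def test_cumulative_curves_monotone_and_cdva_dominates(self):
        cohorts, _ = generate(Scenario(n_eyes=80, seed=17, seq_noise_sd=0.4))
        panels = compute_all_panels(cohorts, SINGLE)
        s = panels["A"].series[cohorts[0].name]
        for key in ("postop_udva", "postop_cdva", "baseline_cdva"):
            assert all(b >= a for a, b in zip(s[key], s[key][1:]))
        an = CohortAnalysis(cohorts[0], SINGLE)
        if np.all(an.postop_cdva_lm <= an.postop_udva_lm):
            assert all(
                c >= u for c, u in zip(s["postop_cdva"], s["postop_udva"])
            )

    def test_cat_baseline_switch(self):
        records = tuple(
            make_record(preop_cdva=(40, 0), postop_cdva=(20, 0),
                        postop_udva=(20, 0), preop=(-2.0 - 0.1 * i, -1.0, 90, 12))
            for i in range(8)
        )
        cohort = Cohort(name="cat", records=records)
        lvc = compute_panel("B", [cohort], AnalysisConfig(procedure="LVC"))
        cat = compute_panel("B", [cohort], AnalysisConfig(procedure="CAT"))
        # LVC baseline is the (worse) preop CDVA: UDVA beats it by 2 lines
        assert lvc.annotations["cat"]["efficacy_index"] == pytest.approx(2.0)
        assert cat.annotations["cat"]["efficacy_index"] == pytest.approx(1.0)
        assert lvc.series["cat"][">=+2"] == 100.0
        assert cat.series["cat"]["0"] == 100.0

    def test_deterministic_recomputation(self, perfect_cohort):
        p1 = compute_all_panels([perfect_cohort], SINGLE)
        p2 = compute_all_panels([perfect_cohort], SINGLE)
        assert p1 == p2

    def test_stability_variant_selected_when_populated(self):
        cohorts, _ = generate(
            Scenario(n_eyes=30, seed=19, n_timepoints=3, drift_noise_sd=0.05)
        )
        panels = compute_all_panels(cohorts, SINGLE)
        assert panels["F"].kind == "stability"
        assert set(panels) == set(PANEL_IDS)
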