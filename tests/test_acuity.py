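import datetime
import math

import pytest
from hypothesis import given, settings, strategies as st

from refractive_outcomes.acuity import (
    FULL_CHART,
    AcuityConfig,
    DateCoercedCellError,
    SnellenParseError,
    VAMeasure,
    efficacy_index,
    format_snellen,
    line_change,
    load_conversion_table,
    logmar_to_snellen,
    parse_snellen,
    safety_index,
    to_decimal,
    to_logmar,
)

CFG = AcuityConfig()


class TestParsing:
    @pytest.mark.parametrize(
        "token,expected",
        [
            ("20-1", (20.0, -1)),
            ("15", (15.0, 0)),
            ("20 + 2", (20.0, 2)),
            ("25", (25.0, 0)),
            ("30-1", (30.0, -1)),
            ("'25-2", (25.0, -2)),     # spreadsheet text-entry escape
            ("20–1", (20.0, -1)),  # en-dash
            ("  40  ", (40.0, 0)),
            (25, (25.0, 0)),            # numeric cell
            (12.5, (12.5, 0)),
        ],
    )
    def test_tokens(self, token, expected):
        va = parse_snellen(token)
        assert (va.denominator, va.letter_offset) == expected

    def test_date_cell_raises_with_remedial_instruction(self):
        with pytest.raises(DateCoercedCellError, match="Text"):
            parse_snellen(datetime.datetime(2023, 2, 25))

    @pytest.mark.parametrize("bad", ["", "abc", "20/40", "-5", "20-9", 0, -3])
    def test_unparseable(self, bad):
        with pytest.raises(SnellenParseError):
            parse_snellen(bad)

    def test_format_round_trip(self):
        for va in (VAMeasure(20, 0), VAMeasure(25, -2), VAMeasure(16, 1)):
            assert parse_snellen(format_snellen(va)) == va


class TestConversion:
    @pytest.mark.parametrize(
        "va,logmar",
        [
            (VAMeasure(20, 0), 0.0),
            (VAMeasure(40, 0), math.log10(2)),
            (VAMeasure(20, -1), 0.02),
        ],
    )
    def test_to_logmar(self, va, logmar):
        assert to_logmar(va, CFG) == pytest.approx(logmar, abs=1e-12)

    @pytest.mark.parametrize(
        "va,decimal",
        [(VAMeasure(20, 0), 1.0), (VAMeasure(40, 0), 0.5), (VAMeasure(10, 0), 2.0)],
    )
    def test_to_decimal(self, va, decimal):
        assert to_decimal(va, CFG) == pytest.approx(decimal, abs=1e-12)

    @settings(max_examples=200, derandomize=True)
    @given(
        st.sampled_from(FULL_CHART),
        st.integers(-4, 4),
    )
    def test_decimal_logmar_consistency(self, denom, offset):
        va = VAMeasure(denom, offset)
        assert to_decimal(va, CFG) == pytest.approx(
            10 ** (-to_logmar(va, CFG)), abs=1e-12
        )

    @pytest.mark.parametrize(
        "value,expected",
        [(0.0, VAMeasure(20, 0)), (math.log10(2), VAMeasure(40, 0))],
    )
    def test_logmar_to_snellen(self, value, expected):
        assert logmar_to_snellen(value, CFG) == expected

    @settings(max_examples=200, derandomize=True)
    @given(st.sampled_from(FULL_CHART), st.integers(-2, 2))
    def test_snap_round_trip(self, denom, offset):
        va = VAMeasure(denom, offset)
        assert logmar_to_snellen(to_logmar(va, CFG), CFG) == va


class TestLineChange:
    @pytest.mark.parametrize(
        "pre,post,expected",
        [
            ((20, 0), (20, 0), 0),
            ((25, 0), (20, 0), +1),
            ((20, 0), (32, 0), -2),
        ],
    )
    def test_examples(self, pre, post, expected):
        assert line_change(VAMeasure(*pre), VAMeasure(*post), CFG) == expected

    @settings(max_examples=200, derandomize=True)
    @given(
        st.sampled_from(FULL_CHART), st.integers(-2, 2),
        st.sampled_from(FULL_CHART), st.integers(-2, 2),
    )
    def test_antisymmetry(self, d1, o1, d2, o2):
        a, b = VAMeasure(d1, o1), VAMeasure(d2, o2)
        assert line_change(a, b, CFG) == -line_change(b, a, CFG)


class TestIndices:
    def test_identity_ratio(self):
        vas = [VAMeasure(20, 0)] * 10
        assert efficacy_index(vas, vas, CFG) == pytest.approx(1.0)
        assert safety_index(vas, vas, CFG) == pytest.approx(1.0)

    def test_half_and_gain(self):
        udva = [VAMeasure(40, 0)] * 5
        cdva = [VAMeasure(20, 0)] * 5
        assert efficacy_index(udva, cdva, CFG) == pytest.approx(0.5)
        better = [VAMeasure(16, 0)] * 5
        assert safety_index(better, cdva, CFG) == pytest.approx(1.25)
        worse = [VAMeasure(25, 0)] * 5
        assert safety_index(worse, cdva, CFG) == pytest.approx(0.8)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            efficacy_index([], [VAMeasure(20, 0)], CFG)

    def test_efficacy_bounded_by_safety_when_udva_worse(self, rng):
        chart = list(FULL_CHART)
        cdva = [VAMeasure(chart[int(i)], 0) for i in rng.integers(1, 5, 30)]
        # UDVA one chart step worse than CDVA for every eye
        udva = [VAMeasure(chart[chart.index(v.denominator) + 1], 0) for v in cdva]
        base = [VAMeasure(20, 0)] * 30
        assert efficacy_index(udva, base, CFG) <= safety_index(cdva, base, CFG)

    def test_per_eye_ratio_variant(self):
        cfg = AcuityConfig(per_eye_ratios=True)
        udva = [VAMeasure(40, 0), VAMeasure(20, 0)]
        cdva = [VAMeasure(20, 0), VAMeasure(20, 0)]
        assert efficacy_index(udva, cdva, cfg) == pytest.approx(0.75)


def test_conversion_table_is_consistent_with_formula():
    rows = load_conversion_table()
    assert len(rows) > 50
    for logmar, token in rows:
        va = parse_snellen(token)
        assert to_logmar(va, CFG) == pytest.approx(logmar, abs=5e-4)
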