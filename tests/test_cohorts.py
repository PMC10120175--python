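import csv
import datetime

import pytest
from openpyxl import Workbook

from refractive_outcomes.cohorts import (
    COLUMN_NAMES,
    Cohort,
    CohortValidationError,
    PairingError,
    SchemaError,
    read_group_file,
    validate_cohorts,
    write_group_file,
)
from refractive_outcomes.simulate import Scenario, generate

from conftest import make_record


ROW = [
    -2.0, -1.0, 90, 12, "20",        # preop
    0, 0, 0, 12,                      # target (plano "0, 0, 0")
    0.25, -0.5, 45, 12, "20", "20-1", # postop
    "", "", "", "", "",               # optional SEQ columns blank
]


def write_csv(path, rows, header=COLUMN_NAMES):
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        if header is not None:
            w.writerow(header)
        w.writerows(rows)


class TestReadGroupFile:
    def test_csv_happy_path(self, tmp_path):
        p = tmp_path / "g.csv"
        write_csv(p, [ROW, ROW])
        cohort, report = read_group_file(p)
        assert len(cohort) == 2
        assert report.ok and report.n_kept == 2
        rec = cohort.records[0]
        assert rec.preop.sphere == -2.0
        assert rec.target.is_plano
        assert rec.target.axis == 180.0  # "0" axis accepted and normalised
        assert rec.postop_udva.letter_offset == -1
        assert not rec.has_stability

    def test_blank_optional_columns_mean_absent(self, tmp_path):
        p = tmp_path / "g.csv"
        write_csv(p, [ROW])
        cohort, _ = read_group_file(p)
        assert cohort.n_stability_timepoints == 0

    def test_optional_columns_parsed_when_present(self, tmp_path):
        row = ROW[:15] + [-0.25, -0.30, "", "", ""]
        p = tmp_path / "g.csv"
        write_csv(p, [row])
        cohort, report = read_group_file(p)
        assert cohort.records[0].seq_series[:2] == (-0.25, -0.30)
        assert cohort.n_stability_timepoints == 2
        assert any("time point" in i for i in report.info)

    def test_xlsx_round_trip_reproduces_records(self, tmp_path):
        cohorts, _ = generate(Scenario(n_eyes=15, seed=7, n_timepoints=3,
                                       seq_noise_sd=0.2, ci_mean=0.9, ci_sd=0.1))
        path = write_group_file(cohorts[0].records, tmp_path / "g.xlsx")
        back, report = read_group_file(path)
        assert report.ok
        assert back.records == cohorts[0].records

    def test_csv_round_trip_reproduces_records(self, tmp_path):
        cohorts, _ = generate(Scenario(n_eyes=15, seed=7, n_timepoints=2))
        path = write_group_file(cohorts[0].records, tmp_path / "g.csv")
        back, _ = read_group_file(path)
        assert back.records == cohorts[0].records

    def test_date_coerced_acuity_cell_is_fatal_with_remedy(self, tmp_path):
        wb = Workbook()
        ws = wb.active
        ws.append(COLUMN_NAMES)
        row = list(ROW)
        row[4] = datetime.datetime(2023, 2, 25)  # "25-2" mangled into a date
        ws.append(row)
        p = tmp_path / "g.xlsx"
        wb.save(p)
        with pytest.raises(CohortValidationError, match='format to "Text"'):
            read_group_file(p)

    def test_missing_mandatory_columns_schema_error(self, tmp_path):
        p = tmp_path / "g.csv"
        write_csv(p, [ROW[:10]], header=COLUMN_NAMES[:10])
        with pytest.raises(SchemaError, match="postop_udva"):
            read_group_file(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "g.csv"
        p.write_text("")
        with pytest.raises(CohortValidationError, match="empty"):
            read_group_file(p)

    def test_row_errors_counted_never_silent(self, tmp_path):
        bad = list(ROW)
        bad[0] = "not-a-number"
        p = tmp_path / "g.csv"
        write_csv(p, [ROW, bad, ROW])
        cohort, report = read_group_file(p)
        assert len(cohort) == 2
        assert report.n_input_rows == report.n_kept + len(report.row_errors)
        assert report.row_errors[0][0] == 3  # 1-based spreadsheet row

    def test_mandatory_blank_is_row_error(self, tmp_path):
        bad = list(ROW)
        bad[1] = ""
        p = tmp_path / "g.csv"
        write_csv(p, [ROW, bad])
        cohort, report = read_group_file(p)
        assert len(cohort) == 1
        assert "preop_cylinder" in report.row_errors[0][1]


class TestValidateCohorts:
    def make(self, n, name="g"):
        return Cohort(name=name, records=tuple(make_record() for _ in range(n)))

    def test_paired_equal_ns_pass_with_warning(self):
        report = validate_cohorts(self.make(5, "a"), self.make(5, "b"), "paired")
        assert any("one eye" in w for w in report.warnings)

    def test_paired_unequal_ns_error(self):
        with pytest.raises(PairingError):
            validate_cohorts(self.make(5, "a"), self.make(4, "b"), "paired")

    def test_single_group(self):
        assert validate_cohorts(self.make(3), None, "single").n_kept == 3
        with pytest.raises(ValueError):
            validate_cohorts(self.make(3), None, "unpaired")
        with pytest.raises(ValueError):
            validate_cohorts(self.make(3), self.make(3), "single")


def test_generator_file_round_trip_is_exact(tmp_path):
    cohorts, paths = generate(
        Scenario(n_eyes=25, seed=3, design="unpaired", n_timepoints=4,
                 ci_mean=0.9, ci_sd=0.1, axis_error_sd=5.0),
        out_dir=tmp_path, fmt="csv",
    )
    for cohort, path in zip(cohorts, paths):
        back, report = read_group_file(path, cohort.name)
        assert report.ok
        assert back.records == cohort.records
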