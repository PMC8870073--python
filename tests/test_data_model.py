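"""Parsing, validation, round-trip and report-writing contracts."""

import pytest

from lbconcord import (Analyte, CondelLabel, PatientCohort, PP2Category,
                       RowError, SchemaError, normalize_chrom,
                       read_variant_table, validate_cohort, write_report,
                       write_variant_table)
from lbconcord.data_model import parse_location, parse_polyphen

from conftest import make_variant

HEADER = ("Location\tAllele\tSYMBOL\tFeature\tConsequence\tIMPACT\tBIOTYPE\t"
          "Protein_position\tAmino_acids\tAF\tPolyPhen\tCondel\n")


def write_table(tmp_path, rows, header=HEADER):
    path = tmp_path / "variants.tsv"
    path.write_text(header + "".join(rows))
    return path


class TestReader:
    def test_parses_af_and_polyphen_fields(self, tmp_path):
        path = write_table(tmp_path, [
            "6:152098\tA\tKMT2C\tENST1\tmissense_variant\tMODERATE\t"
            "protein_coding\t747\tP/L\t0.0001\tprobably_damaging(0.98)\t"
            "deleterious(0.9)\n"])
        (rec,) = read_variant_table(path, Analyte.TUMOR, "p1")
        assert rec.population_af == pytest.approx(0.0001)
        assert rec.pp2_category is PP2Category.PROBABLY_DAMAGING
        assert rec.pp2_score == pytest.approx(0.98)
        assert rec.condel_label is CondelLabel.DELETERIOUS
        assert rec.chrom == "6" and rec.pos == 152098
        assert rec.protein_position == 747
        assert rec.consequence_terms == ("missense_variant",)

    def test_missing_cells_parse_as_missing_not_zero(self, tmp_path):
        path = write_table(tmp_path, [
            "1:100\tG\tTP53\tENST1\tintron_variant\tMODIFIER\t"
            "protein_coding\t-\t-\t-\t-\t-\n"])
        (rec,) = read_variant_table(path, "cf", "p1")
        assert rec.population_af is None
        assert rec.pp2_score is None
        assert rec.pp2_category is PP2Category.UNKNOWN
        assert rec.condel_label is CondelLabel.MISSING

    def test_multi_term_consequence_split_on_ampersand(self, tmp_path):
        path = write_table(tmp_path, [
            "1:100\tG\tTP53\tENST1\tmissense_variant&NMD_transcript_variant\t"
            "MODERATE\tnonsense_mediated_decay\t10\tR/H\t-\t-\t-\n"])
        (rec,) = read_variant_table(path, "ev", "p1")
        assert rec.consequence_terms == ("missense_variant",
                                         "NMD_transcript_variant")

    def test_row_count_matches_data_rows(self, tmp_path):
        row = ("1:{pos}\tG\tTP53\tENST1\tmissense_variant\tMODERATE\t"
               "protein_coding\t10\tR/H\t-\t-\t-\n")
        path = write_table(tmp_path, [row.format(pos=p) for p in (1, 2, 3)])
        assert len(read_variant_table(path, "tumor", "p1")) == 3

    def test_missing_required_column_names_the_column(self, tmp_path):
        bad_header = HEADER.replace("\tAF", "")
        path = write_table(tmp_path, [], header=bad_header)
        with pytest.raises(SchemaError, match="AF"):
            read_variant_table(path, "tumor", "p1")

    def test_unparseable_af_reports_line_number(self, tmp_path):
        rows = [
            "1:1\tG\tTP53\tENST1\tmissense_variant\tMODERATE\t"
            "protein_coding\t10\tR/H\t-\t-\t-\n",
            "1:2\tG\tTP53\tENST1\tmissense_variant\tMODERATE\t"
            "protein_coding\t10\tR/H\tnot_a_number\t-\t-\n"]
        path = write_table(tmp_path, rows)
        with pytest.raises(RowError, match="line 3"):
            read_variant_table(path, "tumor", "p1")
        # collect mode: rows are never silently dropped
        errors = []
        records = read_variant_table(path, "tumor", "p1", errors=errors)
        assert len(records) + len(errors) == 2
        assert errors[0].line_number == 3

    @pytest.mark.parametrize("raw,expected", [
        ("chr6", "6"), ("6", "6"), ("ChrX", "x"), ("MT", "mt")])
    def test_chrom_normalization(self, raw, expected):
        assert normalize_chrom(raw) == expected

    def test_location_range_uses_start(self):
        assert parse_location("chr17:7675-7677") == ("17", 7675)

    def test_bare_polyphen_category_keeps_category(self):
        category, score = parse_polyphen("benign")
        assert category is PP2Category.BENIGN and score is not None


class TestRoundTrip:
    def test_write_read_reproduces_all_fields(self, tmp_path):
        records = [
            make_variant(pos=1, af=0.0001,
                         pp2=(PP2Category.POSSIBLY_DAMAGING, 0.61),
                         condel=CondelLabel.NEUTRAL),
            make_variant(pos=2, af=None, pp2=(PP2Category.UNKNOWN, None)),
            make_variant(pos=3, ref="-", alt="AT", protein_position=None,
                         aa="", consequences=("frameshift_variant",)),
            make_variant(pos=4, ref="NN", alt="-",
                         consequences=("inframe_deletion",),
                         protein_position=None, aa=""),
        ]
        path = tmp_path / "out.tsv"
        write_variant_table(records, path)
        back = read_variant_table(path, "tumor", "p1")
        assert back == records

    def test_written_twice_is_byte_identical(self, tmp_path):
        records = [make_variant(pos=p) for p in range(1, 6)]
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_variant_table(records, a)
        write_variant_table(records, b)
        assert a.read_bytes() == b.read_bytes()


class TestCohortValidation:
    def test_patient_without_tumor_flagged_for_exclusion(self):
        cohort = PatientCohort()
        cohort.add_variants("p2", "ev", [make_variant(patient_id="p2",
                                                      analyte="ev")])
        cohort.add_variants("p2", "cf", [make_variant(patient_id="p2",
                                                      analyte="cf")])
        issues = validate_cohort(cohort)
        assert any(i.kind == "no_tumor" and "exclude" in i.message
                   for i in issues)
        assert cohort.comparative_patients() == []

    def test_complete_cohort_has_no_issues(self):
        cohort = PatientCohort()
        for analyte in ("tumor", "ev", "cf"):
            cohort.add_variants("p1", analyte,
                                [make_variant(analyte=analyte)])
        assert validate_cohort(cohort) == []

    def test_duplicate_slot_reported(self):
        cohort = PatientCohort()
        cohort.add_variants("p1", "tumor", [make_variant()])
        cohort.add_variants("p1", "tumor", [make_variant(pos=5)])
        issues = validate_cohort(cohort)
        assert any(i.kind == "duplicate_slot" for i in issues)


class TestWriteReport:
    def test_schema_and_two_decimal_percentages(self, tmp_path):
        path = tmp_path / "report.tsv"
        write_report([{"patient_id": "p1", "analyte": "ev", "n_tumor": 7,
                       "n_matched": 3, "percent": 42.857142}], path)
        header, row = path.read_text().splitlines()
        assert header.split("\t") == ["patient_id", "analyte", "n_tumor",
                                      "n_matched", "percent"]
        assert row.split("\t")[-1] == "42.86"

    def test_empty_bundle_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_report([], path, columns=["patient_id", "percent"])
        assert path.read_text() == "patient_id\tpercent\n"

    def test_deterministic_bytes(self, tmp_path):
        bundle = [{"patient_id": "p1", "percent": 12.5},
                  {"patient_id": "p2", "percent": 99.99999}]
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_report(bundle, a)
        write_report(bundle, b)
        assert a.read_bytes() == b.read_bytes()
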