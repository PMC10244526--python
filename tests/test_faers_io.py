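"""Quarterly-table readers/writers and the two auxiliary dictionaries."""

from __future__ import annotations

import pandas as pd
import pytest

from cardiopv import faers_io
from cardiopv.faers_io import DataError, FaersFormatError
from cardiopv.model import DrugClass


def sorted_frame(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(list(df.columns), kind="mergesort").reset_index(drop=True)


class TestReadReports:
    def test_round_trip_is_identity(self, batch, report_set, small_config, tmp_path):
        """write -> read -> write reproduces the same tables for the generator output."""
        outdir, truth = batch
        assert report_set.n_reports == truth.n_reports_written
        again = tmp_path / "again"
        faers_io.write_reports(report_set, again)
        reread = faers_io.read_reports(again)
        for name in ("demo", "drugs", "reactions", "outcomes", "indications"):
            a = sorted_frame(getattr(report_set, name))
            b = sorted_frame(getattr(reread, name))
            pd.testing.assert_frame_equal(a, b)

    def test_report_without_reactions_is_kept(self, tmp_path):
        d = tmp_path
        (d / "demo.txt").write_text(
            "primaryid$caseid$fda_dt$age$sex$occp_cod$occr_country\n"
            "101$C1$20200101$60$M$MD$US\n102$C2$20200102$55$F$CN$JP\n"
        )
        (d / "drug.txt").write_text(
            "primaryid$drugname$role_cod\n101$pembrolizumab$PS\n102$aspirin$PS\n"
        )
        (d / "reac.txt").write_text("primaryid$pt\n101$Myocarditis\n")
        (d / "outc.txt").write_text("primaryid$outc_cod\n101$DE\n")
        (d / "indi.txt").write_text("primaryid$indi_pt\n101$Melanoma\n")
        rs = faers_io.read_reports(d)
        assert rs.n_reports == 2  # the reaction-less report passes through
        assert set(rs.reactions["report_id"]) == {"101"}

    def test_orphan_child_rows_are_dropped(self, tmp_path, caplog):
        d = tmp_path
        (d / "demo.txt").write_text(
            "primaryid$caseid$fda_dt$age$sex$occp_cod$occr_country\n101$C1$20200101$60$M$MD$US\n"
        )
        (d / "drug.txt").write_text("primaryid$drugname$role_cod\n101$nivolumab$PS\n999$ghost$PS\n")
        (d / "reac.txt").write_text("primaryid$pt\n101$Rash\n")
        (d / "outc.txt").write_text("primaryid$outc_cod\n")
        (d / "indi.txt").write_text("primaryid$indi_pt\n")
        with caplog.at_level("WARNING"):
            rs = faers_io.read_reports(d)
        assert len(rs.drugs) == 1
        assert any("no matching demographics" in r.message for r in caplog.records)

    def test_duplicate_report_id_is_a_format_error(self, tmp_path):
        d = tmp_path
        (d / "demo.txt").write_text(
            "primaryid$caseid$fda_dt$age$sex$occp_cod$occr_country\n"
            "101$C1$20200101$60$M$MD$US\n101$C1$20200101$60$M$MD$US\n"
        )
        for name, head in [
            ("drug.txt", "primaryid$drugname$role_cod"),
            ("reac.txt", "primaryid$pt"),
            ("outc.txt", "primaryid$outc_cod"),
            ("indi.txt", "primaryid$indi_pt"),
        ]:
            (d / name).write_text(head + "\n")
        with pytest.raises(FaersFormatError, match="duplicate report_id"):
            faers_io.read_reports(d)

    def test_missing_column_names_file(self, tmp_path):
        d = tmp_path
        (d / "demo.txt").write_text("primaryid$caseid\n101$C1\n")
        for name, head in [
            ("drug.txt", "primaryid$drugname$role_cod"),
            ("reac.txt", "primaryid$pt"),
            ("outc.txt", "primaryid$outc_cod"),
            ("indi.txt", "primaryid$indi_pt"),
        ]:
            (d / name).write_text(head + "\n")
        with pytest.raises(FaersFormatError, match="demo.txt"):
            faers_io.read_reports(d)


class TestDrugArchive:
    def test_case_folding_resolves_brand_and_generic(self, tmp_path):
        p = tmp_path / "archive.tsv"
        p.write_text(
            "name_variant\tdrug_class\tcanonical_name\n"
            "Pembrolizumab\tICI\tpembrolizumab\nKEYTRUDA\tICI\tpembrolizumab\n"
        )
        arch = faers_io.read_drug_archive(p)
        assert arch.classify("  keytruda ") == DrugClass.ICI
        assert arch.canonical("PEMBROLIZUMAB") == "pembrolizumab"

    def test_conflicting_duplicate_is_a_data_error(self, tmp_path):
        p = tmp_path / "archive.tsv"
        p.write_text(
            "name_variant\tdrug_class\tcanonical_name\n"
            "bevacizumab\tAGI\tbevacizumab\nBEVACIZUMAB \tICI\tbevacizumab\n"
        )
        with pytest.raises(DataError, match="conflicting"):
            faers_io.read_drug_archive(p)

    def test_unknown_class_rejected(self, tmp_path):
        p = tmp_path / "archive.tsv"
        p.write_text("name_variant\tdrug_class\tcanonical_name\nfoo\tPPI\tfoo\n")
        with pytest.raises(DataError, match="unknown drug_class"):
            faers_io.read_drug_archive(p)

    def test_reads_back_all_entries_with_both_classes(self, tmp_path):
        rows = [
            ("pembrolizumab", "ICI"), ("keytruda", "ICI"), ("nivolumab", "ICI"),
            ("opdivo", "ICI"), ("atezolizumab", "ICI"), ("bevacizumab", "AGI"),
            ("avastin", "AGI"), ("axitinib", "AGI"), ("lenvatinib", "AGI"), ("inlyta", "AGI"),
        ]
        p = tmp_path / "archive.tsv"
        p.write_text(
            "name_variant\tdrug_class\tcanonical_name\n"
            + "".join(f"{v}\t{c}\t{v}\n" for v, c in rows)
        )
        arch = faers_io.read_drug_archive(p)
        assert len(arch) == 10
        assert set(arch.entries["drug_class"]) == {"ICI", "AGI"}


class TestSmqMapReader:
    def test_narrow_scope_filter(self, tmp_path, caplog):
        p = tmp_path / "smq.tsv"
        p.write_text(
            "pt\tsmq_code\tsmq_name\tscope\n"
            "Myocarditis\t20000239\tNoninfectious myocarditis/pericarditis\tNarrow\n"
            "Some PT\t20000239\tNoninfectious myocarditis/pericarditis\tBroad\n"
        )
        with caplog.at_level("WARNING"):
            smq = faers_io.read_smq_map(p)
        assert smq.is_cardiovascular("Myocarditis")
        assert not smq.is_cardiovascular("Some PT")
        assert any("non-narrow" in r.message for r in caplog.records)

    def test_unknown_smq_code_skipped(self, tmp_path, caplog):
        p = tmp_path / "smq.tsv"
        p.write_text(
            "pt\tsmq_code\tsmq_name\tscope\n"
            "Hepatitis\t99999999\tNot cardiovascular\tNarrow\n"
            "Hypertension\t20000147\tHypertension\tNarrow\n"
        )
        with caplog.at_level("WARNING"):
            smq = faers_io.read_smq_map(p)
        assert smq.codes == frozenset({20000147})
        assert any("outside the 9" in r.message for r in caplog.records)

    def test_empty_file_warns_about_all_nine(self, tmp_path, caplog):
        p = tmp_path / "smq.tsv"
        p.write_text("pt\tsmq_code\tsmq_name\tscope\n")
        with caplog.at_level("WARNING"):
            smq = faers_io.read_smq_map(p)
        assert not smq.codes
        assert any("missing 9" in r.message for r in caplog.records)
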