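import pytest

from finet import maf_io
from finet.maf_io import (
    DEFAULT_EFFECT_DICTIONARY,
    EffectDictionary,
    EffectDictionaryError,
    FISTableError,
    MafFormatError,
    MutationRecord,
    load_fis_table,
    load_gene_list,
    normalize_chrom,
    read_maf,
    write_maf,
)

from conftest import MAF_HEADER, make_record, write_maf as write_maf_file


class TestReadMaf:
    def test_attaches_effects_from_default_dictionary(self, toy_maf):
        records, skipped = read_maf(toy_maf)
        assert skipped == 0
        assert [r.effect for r in records] == ["silent", "non-silent", "null"]
        assert records[0].gene == "TP53"
        assert records[1].sample == "S2"

    def test_header_only_file_yields_empty_list(self, tmp_path):
        path = write_maf_file(tmp_path / "empty.maf", [])
        records, skipped = read_maf(path)
        assert records == [] and skipped == 0

    def test_missing_essential_column_is_fatal(self, tmp_path):
        path = tmp_path / "bad.maf"
        path.write_text(MAF_HEADER.replace("\tTumor_Sample_Barcode", ""))
        with pytest.raises(MafFormatError, match="Tumor_Sample_Barcode"):
            read_maf(path)

    def test_header_match_is_case_insensitive(self, tmp_path):
        path = tmp_path / "case.maf"
        path.write_text(MAF_HEADER.lower())
        records, skipped = read_maf(path)
        assert records == [] and skipped == 0

    def test_rows_with_empty_fields_are_skipped_and_counted(self, tmp_path):
        rows = [
            ("TP53", "17", 1, 1, "Silent", "C", "T", "S1"),
            ("", "17", 2, 2, "Silent", "C", "T", "S1"),  # empty gene
            ("KRAS", "12", 3, 3, "Silent", "C", "T", ""),  # empty sample
        ]
        path = write_maf_file(tmp_path / "gaps.maf", rows)
        records, skipped = read_maf(path)
        assert len(records) + skipped == 3
        assert skipped == 2

    def test_unmapped_classification_is_fatal_and_named(self, tmp_path):
        path = write_maf_file(
            tmp_path / "odd.maf",
            [("TP53", "17", 1, 1, "Weird_Class", "C", "T", "S1")],
        )
        with pytest.raises(EffectDictionaryError, match="Weird_Class"):
            read_maf(path)

    def test_comment_lines_are_skipped(self, tmp_path):
        path = tmp_path / "c.maf"
        path.write_text("#version 2.4\n" + MAF_HEADER
                        + "TP53\t17\t1\t1\tSilent\tC\tT\tS1\n")
        records, _ = read_maf(path)
        assert len(records) == 1

    def test_roundtrip_write_read_identity(self, toy_maf, tmp_path):
        records, _ = read_maf(toy_maf)
        out = tmp_path / "round.maf"
        write_maf(records, out)
        records2, skipped2 = read_maf(out)
        assert skipped2 == 0
        assert records == records2


class TestChromosomeNormalization:
    @pytest.mark.parametrize("label,expected", [
        ("chr7", "7"), ("7", "7"), ("chrX", "X"), ("x", "X"), ("ChrY", "Y"),
        ("22", "22"),
    ])
    def test_prefix_and_case(self, label, expected):
        assert normalize_chrom(label) == expected

    def test_chr_prefixed_record_hits_plain_table_key(self):
        rec = make_record(chrom="chr7", start=140453136, end=140453136,
                          ref="A", alt="T")
        table = maf_io.FISTable({("7", 140453136, "A", "T"): 2.5})
        assert table.lookup_record(rec) == 2.5


class TestMutationRecord:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            make_record(start=10, end=5)
        with pytest.raises(ValueError):
            make_record(gene="")
        with pytest.raises(ValueError):
            make_record(sample="")


class TestFISTable:
    def _write(self, tmp_path, lines, header=True):
        path = tmp_path / "fis.tsv"
        text = "chrom\tpos\tref\talt\tscore\n" if header else ""
        path.write_text(text + "".join(lines))
        return path

    def test_lookup_identity(self, tmp_path):
        path = self._write(tmp_path, ["7\t140453136\tA\tT\t3.14\n",
                                      "12\t25398284\tC\tA\t1.5\n"])
        table = load_fis_table(path)
        assert len(table) == 2
        assert table.lookup("7", 140453136, "A", "T") == 3.14

    def test_headerless_table_is_accepted(self, tmp_path):
        path = self._write(tmp_path, ["7\t1\tA\tT\t1.0\n"], header=False)
        assert len(load_fis_table(path)) == 1

    def test_duplicate_key_keeps_first_and_warns(self, tmp_path, caplog):
        path = self._write(tmp_path, ["7\t1\tA\tT\t1.0\n", "7\t1\tA\tT\t2.0\n"])
        with caplog.at_level("WARNING"):
            table = load_fis_table(path)
        assert table.lookup("7", 1, "A", "T") == 1.0
        assert any("duplicate" in r.message for r in caplog.records)

    def test_non_numeric_score_is_fatal_with_line_number(self, tmp_path):
        path = self._write(tmp_path, ["7\t1\tA\tT\tNA\n"])
        with pytest.raises(FISTableError, match="line 2"):
            load_fis_table(path)

    def test_allele_match_is_case_insensitive(self, tmp_path):
        path = self._write(tmp_path, ["7\t1\ta\tt\t1.0\n"])
        table = load_fis_table(path)
        assert table.lookup("7", 1, "A", "T") == 1.0


class TestGeneList:
    def test_deduplicates_and_strips(self, tmp_path):
        path = tmp_path / "genes.txt"
        path.write_text("TP53\nKRAS\n TP53 \n\n\n")
        assert load_gene_list(path) == {"TP53", "KRAS"}

    def test_empty_file_gives_empty_set(self, tmp_path):
        path = tmp_path / "empty.txt"
        path.write_text("")
        assert load_gene_list(path) == set()


class TestEffectDictionary:
    def test_default_covers_standard_tcga_vocabulary(self):
        assert DEFAULT_EFFECT_DICTIONARY["Silent"] == "silent"
        assert DEFAULT_EFFECT_DICTIONARY["Missense_Mutation"] == "non-silent"
        assert DEFAULT_EFFECT_DICTIONARY["Frame_Shift_Ins"] == "null"
        assert DEFAULT_EFFECT_DICTIONARY["3'UTR"] == "non-coding"

    def test_unknown_classification_raises(self):
        with pytest.raises(EffectDictionaryError):
            DEFAULT_EFFECT_DICTIONARY["Made_Up"]

    def test_invalid_effect_label_rejected_at_construction(self):
        with pytest.raises(ValueError):
            EffectDictionary({"Silent": "quiet"})

    def test_override_from_tsv(self, tmp_path):
        path = tmp_path / "dict.tsv"
        path.write_text("Silent\tsilent\nMyClass\tnull\n")
        d = maf_io.load_effect_dictionary(path)
        assert d["MyClass"] == "null"
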