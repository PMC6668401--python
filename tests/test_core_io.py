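"""Genotype encoding, matrix validation, and VCF/CSV round-trips."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from clonotracer import (
    ConfigError,
    FormatError,
    Genotype,
    GenotypeMatrix,
    MISSING,
    PanelOverlapError,
    PanelVariant,
    consensus_genotypes,
    read_matrix_csv,
    read_matrix_dir,
    read_panel,
    read_vcf_to_matrix,
    write_matrix_csv,
    write_panel,
    write_vcf,
)

from conftest import make_matrix, make_small_panel, random_matrix

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=chr1>
##contig=<ID=chr2>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
"""


def write_toy_vcf(path, body_lines, cells=("cellA", "cellB", "cellC")):
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"
    header = VCF_HEADER + cols + "\t" + "\t".join(cells) + "\n"
    path.write_text(header + "".join(line + "\n" for line in body_lines))
    return path


@pytest.fixture
def toy_panel():
    return [
        PanelVariant("chr1", 100, "A", "C", gene="G1", category="common"),
        PanelVariant("chr1", 200, "G", "T", gene="G2", category="common"),
    ]


class TestVcfReader:
    def test_basic_encoding_and_depth(self, tmp_path, toy_panel):
        vcf = write_toy_vcf(tmp_path / "t.vcf", [
            "chr1\t100\t.\tA\tC\t.\t.\t.\tGT:DP:GQ\t0/0:15:60\t0/1:15:60\t1/1:15:60",
            "chr1\t200\t.\tG\tT\t.\t.\t.\tGT:DP:GQ\t0/0:15:60\t0/0:15:60\t0/1:15:60",
        ])
        mat = read_vcf_to_matrix(vcf, toy_panel)
        assert mat.cell_ids == ["cellA", "cellB", "cellC"]
        assert [v.id for v in mat.variants] == [v.id for v in toy_panel]
        np.testing.assert_array_equal(
            mat.genotypes, [[0, 0], [1, 0], [2, 1]]
        )
        assert (mat.depth == 15).all()
        assert (mat.quality == 60).all()

    def test_missing_call_and_phased_separator(self, tmp_path, toy_panel):
        vcf = write_toy_vcf(tmp_path / "t.vcf", [
            "chr1\t100\t.\tA\tC\t.\t.\t.\tGT\t./.\t0|1\t1|0",
        ])
        mat = read_vcf_to_matrix(vcf, toy_panel)
        assert mat.genotypes[0, 0] == MISSING
        assert mat.genotypes[1, 0] == Genotype.HET
        assert mat.genotypes[2, 0] == Genotype.HET
        # DP/GQ absent -> recorded as 0
        assert (mat.depth == 0).all() and (mat.quality == 0).all()

    def test_empty_vcf_keeps_cells(self, tmp_path, toy_panel):
        vcf = write_toy_vcf(tmp_path / "t.vcf", [],
                            cells=tuple(f"c{i}" for i in range(5)))
        mat = read_vcf_to_matrix(vcf, toy_panel)
        assert mat.n_cells == 5 and mat.n_variants == 0

    def test_off_panel_records_skipped(self, tmp_path, toy_panel, caplog):
        vcf = write_toy_vcf(tmp_path / "t.vcf", [
            "chr1\t100\t.\tA\tC\t.\t.\t.\tGT\t0/0\t0/1\t1/1",
            "chr2\t999\t.\tA\tG\t.\t.\t.\tGT\t0/0\t0/0\t0/0",
        ])
        with caplog.at_level("WARNING"):
            mat = read_vcf_to_matrix(vcf, toy_panel)
        assert mat.n_variants == 1
        assert "not in panel" in caplog.text

    def test_multiallelic_uses_first_alt(self, tmp_path, toy_panel):
        vcf = write_toy_vcf(tmp_path / "t.vcf", [
            "chr1\t100\t.\tA\tC,G\t.\t.\t.\tGT\t0/0\t0/1\t1/1",
        ])
        mat = read_vcf_to_matrix(vcf, toy_panel)
        assert mat.n_variants == 1
        np.testing.assert_array_equal(mat.genotypes[:, 0], [0, 1, 2])

    def test_zero_panel_overlap_is_explicit_error(self, tmp_path):
        panel = [PanelVariant("chr2", 777, "A", "C")]
        vcf = write_toy_vcf(tmp_path / "t.vcf", [
            "chr1\t100\t.\tA\tC\t.\t.\t.\tGT\t0/0\t0/1\t1/1",
        ])
        with pytest.raises(PanelOverlapError):
            read_vcf_to_matrix(vcf, panel)

    def test_defective_vcf_is_format_error(self, tmp_path, toy_panel):
        bad = tmp_path / "bad.vcf"
        bad.write_text("this is not a VCF\n")
        with pytest.raises(FormatError):
            read_vcf_to_matrix(bad, toy_panel)

    def test_reader_never_invents_calls(self, tmp_path, toy_panel):
        """Non-MISSING entry count equals fully specified GT count in source."""
        body = [
            "chr1\t100\t.\tA\tC\t.\t.\t.\tGT\t0/0\t./.\t1/1",
            "chr1\t200\t.\tG\tT\t.\t.\t.\tGT\t./1\t0/1\t./.",
        ]
        vcf = write_toy_vcf(tmp_path / "t.vcf", body)
        mat = read_vcf_to_matrix(vcf, toy_panel)
        fully_specified = sum(
            gt.count(".") == 0
            for line in body
            for gt in line.split("\t")[9:]
        )
        assert mat.n_called() == fully_specified == 3


class TestVcfWriter:
    def test_vcf_round_trip(self, rng):
        panel = make_small_panel()
        mat = random_matrix(rng, 20, len(panel), panel=panel)
        import tempfile, os
        with tempfile.TemporaryDirectory() as d:
            path = os.path.join(d, "cells.vcf")
            write_vcf(mat, path)
            back = read_vcf_to_matrix(path, panel, sample_id=mat.sample_id,
                                      timepoint=mat.timepoint)
        assert back == mat


class TestCsvRoundTrip:
    def test_round_trip_exact(self, tmp_path, rng):
        panel = make_small_panel()
        mat = random_matrix(rng, 50, len(panel), panel=panel)
        write_matrix_csv(mat, tmp_path)
        back = read_matrix_dir(tmp_path)
        assert back == mat

    def test_na_token_round_trip(self, tmp_path):
        mat = make_matrix([[0, MISSING], [1, 2]])
        write_matrix_csv(mat, tmp_path)
        text = (tmp_path / "genotypes.csv").read_text()
        assert "NA" in text
        back = read_matrix_dir(tmp_path)
        assert back.genotypes[0, 1] == MISSING

    def test_empty_matrix_writes_headers(self, tmp_path):
        panel = make_small_panel()
        mat = make_matrix(np.zeros((0, len(panel)), dtype=np.int8), panel=panel)
        write_matrix_csv(mat, tmp_path)
        back = read_matrix_dir(tmp_path)
        assert back.n_cells == 0 and back.n_variants == len(panel)

    def test_header_mismatch_rejected(self, tmp_path, rng):
        panel = make_small_panel()
        mat = random_matrix(rng, 5, len(panel), panel=panel)
        paths = write_matrix_csv(mat, tmp_path)
        other = tmp_path / "other.csv"
        lines = paths["depth"].read_text().splitlines()
        other.write_text("\n".join([lines[0]] + lines[2:]) + "\n")
        with pytest.raises(FormatError):
            read_matrix_csv(paths["genotypes"], other, paths["quality"],
                            paths["panel"])

    def test_negative_depth_rejected(self, tmp_path, rng):
        panel = make_small_panel()
        mat = random_matrix(rng, 5, len(panel), panel=panel)
        paths = write_matrix_csv(mat, tmp_path)
        text = paths["depth"].read_text().replace(",0", ",-3", 1)
        paths["depth"].write_text(text)
        with pytest.raises(ConfigError):
            read_matrix_csv(paths["genotypes"], paths["depth"],
                            paths["quality"], paths["panel"])

    @given(st.integers(0, 2**31 - 1))
    def test_round_trip_property(self, seed):
        rng = np.random.default_rng(seed)
        panel = make_small_panel()
        mat = random_matrix(rng, int(rng.integers(1, 15)), len(panel),
                            panel=panel)
        import tempfile
        with tempfile.TemporaryDirectory() as d:
            write_matrix_csv(mat, d)
            back = read_matrix_dir(d)
        assert back == mat


class TestPanel:
    def test_panel_round_trip(self, tmp_path):
        panel = make_small_panel()
        write_panel(panel, tmp_path / "panel.tsv")
        assert read_panel(tmp_path / "panel.tsv") == panel

    def test_duplicate_variant_rejected(self):
        v = PanelVariant("chr1", 100, "A", "C")
        with pytest.raises(ConfigError):
            make_matrix([[0, 0]], panel=[v, v])

    def test_unknown_category_rejected(self):
        with pytest.raises(ConfigError):
            PanelVariant("chr1", 100, "A", "C", category="bogus")


class TestGenotypeMatrix:
    def test_grid_shape_mismatch_rejected(self):
        with pytest.raises(ConfigError):
            GenotypeMatrix(
                cell_ids=["a"], variants=[PanelVariant("chr1", 1, "A", "C")],
                genotypes=np.zeros((1, 1), dtype=np.int8),
                depth=np.zeros((2, 1)), quality=np.zeros((1, 1)),
            )

    def test_invalid_code_rejected(self):
        with pytest.raises(ConfigError):
            make_matrix([[5]])

    def test_missing_fractions(self):
        mat = make_matrix([[0, MISSING], [MISSING, MISSING]])
        np.testing.assert_allclose(mat.missing_fraction_per_cell(), [0.5, 1.0])
        np.testing.assert_allclose(mat.missing_fraction_per_variant(), [0.5, 1.0])


class TestConsensus:
    def test_majority_ignores_missing(self):
        codes = np.array([[1, MISSING], [1, 2], [0, 2]])
        np.testing.assert_array_equal(consensus_genotypes(codes), [1, 2])

    def test_all_missing_locus_stays_missing(self):
        codes = np.full((3, 1), MISSING)
        assert consensus_genotypes(codes)[0] == MISSING

    def test_tie_breaks_to_lower_code(self):
        codes = np.array([[0], [2]])
        assert consensus_genotypes(codes)[0] == 0
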