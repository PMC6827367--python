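"""Genotype I/O, validation, and filtering."""

import numpy as np
import pytest

from shwe import (
    MISSING,
    FormatError,
    GenotypeMatrix,
    GenotypeValidationError,
    filter_completeness,
    filter_maf,
    read_genotypes,
    thin_by_distance,
    write_genotypes,
)

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
"""


def _vcf_line(pos, vid, ref, alt, gts):
    return f"1\t{pos}\t{vid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"


class TestMatrixTSV:
    def test_parse_simple(self, tmp_path):
        f = tmp_path / "g.tsv"
        f.write_text(
            "snp_id\ts1\ts2\ts3\ts4\n"
            "rs1\t0\t1\t2\t1\n"
            "rs2\t0\t0\t1\tNA\n"
            "rs3\t2\t2\t1\t0\n"
        )
        g = read_genotypes(f, "matrix-tsv")
        assert (g.m, g.n) == (3, 4)
        assert g.values[1, 3] == MISSING
        assert list(g.sample_ids) == ["s1", "s2", "s3", "s4"]

    def test_round_trip_bit_exact(self, tmp_path, small_matrix):
        f = tmp_path / "rt.tsv"
        write_genotypes(small_matrix, f)
        g2 = read_genotypes(f, "matrix-tsv")
        np.testing.assert_array_equal(g2.values, small_matrix.values)
        assert list(g2.snp_ids) == list(small_matrix.snp_ids)
        assert list(g2.sample_ids) == list(small_matrix.sample_ids)
        np.testing.assert_array_equal(g2.pos, small_matrix.pos)
        np.testing.assert_array_equal(g2.chrom, small_matrix.chrom)
        # and the written text itself is stable
        f2 = tmp_path / "rt2.tsv"
        write_genotypes(g2, f2)
        assert f.read_text() == f2.read_text()

    def test_out_of_range_value_rejected(self, tmp_path):
        f = tmp_path / "bad.tsv"
        f.write_text("snp_id\ts1\ts2\nrs1\t0\t3\n")
        with pytest.raises(GenotypeValidationError):
            read_genotypes(f, "matrix-tsv")

    def test_unparseable_entry_names_line(self, tmp_path):
        f = tmp_path / "bad.tsv"
        f.write_text("snp_id\ts1\ts2\nrs1\t0\t1\nrs2\tx\t1\n")
        with pytest.raises(FormatError, match="line 3"):
            read_genotypes(f, "matrix-tsv")

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            read_genotypes("/nonexistent/g.tsv")


class TestVCF:
    def test_triallelic_skipped(self, tmp_path):
        lines = [VCF_HEADER]
        for i in range(10):
            alt = "T,G" if i == 4 else "T"
            lines.append(_vcf_line(100 + i, f"rs{i}", "A", alt, ["0/0", "0/1", "1/1"]))
        f = tmp_path / "t.vcf"
        f.write_text("".join(lines))
        g = read_genotypes(f, "vcf")
        assert g.m == 9  # one record skipped
        assert g.n == 3

    def test_alt_dosage_and_missing(self, tmp_path):
        f = tmp_path / "d.vcf"
        f.write_text(VCF_HEADER + _vcf_line(100, "rs1", "A", "T", ["0/0", "0/1", "./."]))
        g = read_genotypes(f, "vcf")
        assert list(g.values[0]) == [0, 1, MISSING]


class TestPlinkText:
    def test_traw_parse(self, tmp_path):
        f = tmp_path / "g.traw"
        f.write_text(
            "CHR\tSNP\t(C)M\tPOS\tCOUNTED\tALT\tf1_s1\tf2_s2\tf3_s3\n"
            "1\trs1\t0\t100\tA\tT\t0\t1\t2\n"
            "1\trs2\t0\t200\tG\tC\tNA\t2\t0\n"
        )
        g = read_genotypes(f, "plink-text")
        assert (g.m, g.n) == (2, 3)
        assert g.values[1, 0] == MISSING
        assert list(g.pos) == [100, 200]


class TestValidation:
    def test_duplicate_snp_ids(self):
        with pytest.raises(GenotypeValidationError):
            GenotypeMatrix(
                np.zeros((2, 2), dtype=np.int8),
                snp_ids=np.array(["a", "a"], dtype=object),
                sample_ids=np.array(["x", "y"], dtype=object),
            )

    def test_too_few_samples(self):
        with pytest.raises(GenotypeValidationError):
            GenotypeMatrix(
                np.zeros((2, 1), dtype=np.int8),
                snp_ids=np.array(["a", "b"], dtype=object),
                sample_ids=np.array(["x"], dtype=object),
            )


class TestMAFFilter:
    def _matrix(self, rows):
        rows = np.asarray(rows, dtype=np.int8)
        return GenotypeMatrix(
            rows,
            snp_ids=np.array([f"s{i}" for i in range(rows.shape[0])], dtype=object),
            sample_ids=np.array([f"i{j}" for j in range(rows.shape[1])], dtype=object),
        )

    def test_threshold_boundary_kept(self):
        # p = 2/8 = 0.25: removed at min_maf=0.3, kept at exactly 0.25
        g = self._matrix([[0, 0, 1, 1]])
        assert filter_maf(g, 0.3).m == 0
        assert filter_maf(g, 0.25).m == 1

    def test_below_min_removed(self):
        # p = 0.04 < 0.05
        row = [1] + [0] * 24  # p = 1/50 = 0.02... use dosage 2: p = 0.04
        g = self._matrix([[2] + [0] * 24])
        assert filter_maf(g, 0.05).m == 0

    def test_zero_threshold_identity(self, small_matrix):
        assert filter_maf(small_matrix, 0.0).m == small_matrix.m

    def test_maf_uses_nonmissing_only(self):
        g = self._matrix([[1, 1, MISSING, MISSING]])
        # p over the 2 observed calls = 2/4 = 0.5
        assert filter_maf(g, 0.4).m == 1

    def test_idempotent(self, admixed_k2):
        g, _ = admixed_k2
        once = filter_maf(g, 0.1)
        twice = filter_maf(once, 0.1)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_all_missing_excluded_with_warning(self, caplog):
        g = self._matrix([[MISSING, MISSING, MISSING], [0, 1, 2]])
        import logging

        with caplog.at_level(logging.WARNING, logger="shwe.genotype_io"):
            out = filter_maf(g, 0.0)
        assert out.m == 1
        assert "all calls missing" in caplog.text


class TestCompletenessFilter:
    def _one_missing(self, n):
        row = np.zeros(n, dtype=np.int8)
        row[-2:] = [1, MISSING]
        return GenotypeMatrix(
            row[None, :],
            snp_ids=np.array(["s"], dtype=object),
            sample_ids=np.array([f"i{j}" for j in range(n)], dtype=object),
        )

    def test_boundary_kept_by_ge(self):
        # 199/200 = 0.995 exactly: kept
        assert filter_completeness(self._one_missing(200), 0.995).m == 1

    def test_below_removed(self):
        # 9/10 = 0.9 < 0.95
        assert filter_completeness(self._one_missing(10), 0.95).m == 0

    def test_zero_identity(self, small_matrix):
        assert filter_completeness(small_matrix, 0.0).m == small_matrix.m


class TestThinning:
    def _positions(self, chrom, pos):
        m = len(pos)
        return GenotypeMatrix(
            np.tile([0, 1, 2], (m, 1)).astype(np.int8),
            snp_ids=np.array([f"s{i}" for i in range(m)], dtype=object),
            sample_ids=np.array(["a", "b", "c"], dtype=object),
            chrom=np.asarray(chrom, dtype=object),
            pos=np.asarray(pos, dtype=np.int64),
        )

    def test_greedy_scan(self):
        g = self._positions(["1"] * 3, [100, 600, 1100])
        out = thin_by_distance(g, 1000)
        assert list(out.pos) == [100, 1100]

    def test_min_bp_one_identity(self):
        g = self._positions(["1"] * 3, [100, 600, 1100])
        assert thin_by_distance(g, 1).m == 3

    def test_chromosomes_independent(self):
        g = self._positions(["1", "1", "2", "2"], [100, 200, 100, 200])
        out = thin_by_distance(g, 1000)
        # first SNP of each chromosome always kept
        assert list(out.chrom) == ["1", "2"]

    def test_requires_positions(self):
        g = GenotypeMatrix(
            np.zeros((1, 3), dtype=np.int8),
            snp_ids=np.array(["s"], dtype=object),
            sample_ids=np.array(["a", "b", "c"], dtype=object),
        )
        with pytest.raises(ValueError, match="positions"):
            thin_by_distance(g, 1000)

    def test_unsorted_positions_rejected(self):
        g = self._positions(["1", "1"], [500, 100])
        with pytest.raises(ValueError, match="sorted"):
            thin_by_distance(g, 10)
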