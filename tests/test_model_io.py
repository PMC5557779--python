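import numpy as np
import pytest

from bsamap import io
from bsamap.association import AssociationResult
from bsamap.model import (
    BaseDepths,
    CandidateRegion,
    ConfigurationError,
    GenotypeMatrix,
    GenotypingError,
    RowParseError,
    SchemaError,
    SnpSite,
    is_unknown_chrom,
)

from conftest import make_site


class TestBaseDepths:
    def test_total_and_tuple(self):
        d = BaseDepths(a=1, c=2, g=3, t=4)
        assert d.total == 10
        assert d.as_tuple() == (1, 2, 3, 4)
        assert d.depth_of("G") == 3

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError, match="depth_C"):
            BaseDepths(a=1, c=-1)

    def test_zero_depth_frequencies_none(self):
        assert BaseDepths().frequencies() is None
        np.testing.assert_allclose(
            BaseDepths(a=1, t=3).frequencies(), [0.25, 0, 0, 0.75]
        )


class TestSnpSite:
    def test_invariants(self):
        with pytest.raises(ValueError, match="pos"):
            make_site(pos=0)
        with pytest.raises(ValueError, match="ref_base"):
            make_site(ref="N")

    def test_biallelic(self):
        assert make_site(alts=("T",)).is_biallelic
        assert not make_site(alts=("T", "G")).is_biallelic


class TestCandidateRegion:
    def test_order_invariant(self):
        with pytest.raises(ValueError):
            CandidateRegion("1H", 10, 5)

    def test_size_mb_rounding_half_up(self):
        assert CandidateRegion("1H", 1, 2_345_001).size_mb == 2.35
        assert CandidateRegion("1H", 1, 1_005_001).size_mb == 1.01  # exact .005 up


def test_is_unknown_chrom():
    assert is_unknown_chrom("chrUn")
    assert is_unknown_chrom("Chr unknown")
    assert not is_unknown_chrom("1H")


class TestDepthTable:
    def test_header_only_gives_empty_list(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text("\t".join(io.DEPTH_COLUMNS) + "\n")
        assert io.read_depth_table(path) == []

    def test_round_trip_three_rows(self, tmp_path):
        sites = [
            make_site(pos=100),
            make_site(chrom="2H", pos=200, ref="C", alts=("G",), p1="C", p2="G",
                      dom=(0, 9, 3, 0), rec=(0, 2, 7, 0),
                      parent1_depth=16, parent2_depth=27),
            make_site(chrom="chrUn", pos=5, alts=("T", "G")),
        ]
        path = tmp_path / "d.tsv"
        io.write_depth_table(sites, path)
        back = io.read_depth_table(path)
        assert back == sites

    def test_negative_depth_names_line(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text(
            "\t".join(io.DEPTH_COLUMNS) + "\n"
            + "1H\t100\tA\tT\tA\tT\t-1\t0\t0\t0\t0\t0\t0\t5\tNA\tNA\n"
        )
        with pytest.raises(RowParseError, match="line 2"):
            io.read_depth_table(path)

    def test_non_integer_depth(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text(
            "\t".join(io.DEPTH_COLUMNS) + "\n"
            + "1H\t100\tA\tT\tA\tT\t1.5\t0\t0\t0\t0\t0\t0\t5\tNA\tNA\n"
        )
        with pytest.raises(RowParseError, match="dom_A"):
            io.read_depth_table(path)

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "d.tsv"
        cols = [c for c in io.DEPTH_COLUMNS if c != "rec_G"]
        path.write_text("\t".join(cols) + "\n")
        with pytest.raises(SchemaError, match="rec_G"):
            io.read_depth_table(path)


VCF_HEADER = """##fileformat=VCFv4.2
##contig=<ID=1H>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tP1\tP2\tBD\tBY
"""


def _write_vcf(tmp_path, records):
    path = tmp_path / "t.vcf"
    path.write_text(VCF_HEADER + "".join(records))
    return path


SAMPLE_MAP = {"parent_dom": "P1", "parent_rec": "P2", "bulk_dom": "BD", "bulk_rec": "BY"}


class TestVcfReader:
    def test_two_records(self, tmp_path):
        path = _write_vcf(tmp_path, [
            "1H\t100\t.\tA\tT\t.\t.\t.\tGT:AD\t0/0:10,0\t1/1:0,12\t0/1:30,15\t1/1:0,40\n",
            "1H\t200\t.\tC\tG\t.\t.\t.\tGT:AD\t0/0:8,0\t1/1:0,9\t0/1:20,10\t1/1:1,25\n",
        ])
        sites, stats = io.read_vcf_bulks(path, SAMPLE_MAP)
        assert stats.n_sites == 2 and stats.n_skipped_indel == 0
        s = sites[0]
        assert (s.chrom, s.pos, s.ref, s.alts) == ("1H", 100, "A", ("T",))
        assert s.parent1_allele == "A" and s.parent2_allele == "T"
        assert s.bulk_dom == BaseDepths(a=30, t=15)
        assert s.bulk_rec == BaseDepths(t=40)
        assert sites[1].bulk_dom == BaseDepths(c=20, g=10)

    def test_indel_skipped(self, tmp_path):
        path = _write_vcf(tmp_path, [
            "1H\t100\t.\tA\tAT\t.\t.\t.\tGT:AD\t0/0:10,0\t1/1:0,12\t0/1:30,15\t1/1:0,40\n",
            "1H\t200\t.\tC\tG\t.\t.\t.\tGT:AD\t0/0:8,0\t1/1:0,9\t0/1:20,10\t1/1:1,25\n",
        ])
        sites, stats = io.read_vcf_bulks(path, SAMPLE_MAP)
        assert stats.n_skipped_indel == 1
        assert len(sites) == 1

    def test_missing_sample_is_config_error(self, tmp_path):
        path = _write_vcf(tmp_path, [])
        bad = dict(SAMPLE_MAP, bulk_dom="NOPE")
        with pytest.raises(ConfigurationError, match="NOPE"):
            io.read_vcf_bulks(path, bad)

    def test_missing_role_is_config_error(self, tmp_path):
        path = _write_vcf(tmp_path, [])
        with pytest.raises(ConfigurationError, match="bulk_rec"):
            io.read_vcf_bulks(path, {k: v for k, v in SAMPLE_MAP.items() if k != "bulk_rec"})

    def test_bulk_without_depths_flagged(self, tmp_path):
        path = _write_vcf(tmp_path, [
            "1H\t100\t.\tA\tT\t.\t.\t.\tGT:AD\t0/0:10,0\t1/1:0,12\t0/1:.,.\t1/1:0,40\n",
        ])
        sites, stats = io.read_vcf_bulks(path, SAMPLE_MAP)
        assert stats.n_flagged_no_depth == 1
        assert sites[0].flagged
        assert sites[0].bulk_dom.total == 0


class TestBedWriter:
    def test_printed_coordinates(self, tmp_path):
        path = tmp_path / "r.bed"
        io.write_regions_bed(
            [CandidateRegion("1H", 427_749_941, 460_155_270, "euclidean")], path
        )
        assert path.read_text() == "1H\t427749940\t460155270\teuclidean\n"

    def test_empty_list(self, tmp_path):
        path = tmp_path / "r.bed"
        io.write_regions_bed([], path)
        assert path.read_text() == ""

    def test_two_regions_order_preserved(self, tmp_path):
        path = tmp_path / "r.bed"
        regions = [
            CandidateRegion("2H", 100, 200, "snp_index"),
            CandidateRegion("1H", 50, 80, "euclidean"),
        ]
        io.write_regions_bed(regions, path)
        lines = path.read_text().splitlines()
        assert lines[0].startswith("2H\t99\t200") and lines[1].startswith("1H\t49\t80")

    def test_round_trip(self, tmp_path):
        path = tmp_path / "r.bed"
        regions = [CandidateRegion("1H", 414_847_463, 464_122_721, "snp_index")]
        io.write_regions_bed(regions, path)
        assert io.read_regions_bed(path) == regions


class TestAssociationTable:
    def test_single_row(self, tmp_path):
        path = tmp_path / "a.tsv"
        io.write_association_table(
            [AssociationResult("1H", 100, 0.5, 0.25, 0.25, 0.4, 0.4**5)], path
        )
        lines = path.read_text().splitlines()
        assert len(lines) == 2
        assert lines[0].split("\t") == io.ASSOC_COLUMNS

    def test_undefined_stat_written_na(self, tmp_path):
        path = tmp_path / "a.tsv"
        io.write_association_table([AssociationResult("1H", 100)], path)
        row = path.read_text().splitlines()[1].split("\t")
        assert row[2:] == ["NA"] * 8

    def test_round_trip_random_rows(self, tmp_path, rng):
        results = [
            AssociationResult(
                chrom="1H", pos=int(p),
                snp_index_dom=round(rng.random(), 6),
                snp_index_rec=round(rng.random(), 6),
                delta=round(rng.random() * 2 - 1, 6),
                ed=round(rng.random(), 6),
                ed5=round(rng.random(), 6),
                window_delta=None,
                loess_delta=round(rng.random(), 6),
                loess_ed5=round(rng.random(), 6),
            )
            for p in rng.integers(1, 10**9, size=10)
        ]
        path = tmp_path / "a.tsv"
        io.write_association_table(results, path)
        df = io.read_association_table(path)
        for i, r in enumerate(results):
            assert df.loc[i, "pos"] == r.pos
            assert df.loc[i, "delta"] == pytest.approx(r.delta, abs=1e-6)
            assert np.isnan(df.loc[i, "window_delta"])
            assert df.loc[i, "loess_ed5"] == pytest.approx(r.loess_ed5, abs=1e-6)


class TestGenotypeMatrixIO:
    def test_round_trip(self, tmp_path, fine_mapping_matrix):
        path = tmp_path / "g.tsv"
        io.write_genotype_matrix(fine_mapping_matrix, path)
        back = io.read_genotype_matrix(path, n_population=172)
        assert back.marker_ids == fine_mapping_matrix.marker_ids
        assert back.plant_ids == fine_mapping_matrix.plant_ids
        assert back.calls == fine_mapping_matrix.calls

    def test_invalid_code_rejected(self):
        with pytest.raises(GenotypingError, match="HZSNP1.*plantX"):
            GenotypeMatrix(["HZSNP1"], ["plantX"], [["2/2"]])
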