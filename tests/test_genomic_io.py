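import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rohkit.genomic_io import (
    FormatError,
    GeneticMap,
    GenotypeMatrix,
    Individual,
    Intervals,
    MapCoverageError,
    Pedigree,
    PedigreeError,
    interpolate_cM,
    read_intervals,
    read_vcf,
    write_vcf,
)


def toy_gm(calls=None, af=None):
    calls = np.array([[0, 1, 2], [0, 0, -1], [2, 2, 2]], dtype=np.int8) if calls is None else calls
    return GenotypeMatrix(
        chrom=np.array(["chr1", "chr1", "chr2"], dtype=object),
        pos=np.array([100, 200, 150]),
        ref=np.array(["A", "C", "G"], dtype=object),
        alt=np.array(["T", "G", "A"], dtype=object),
        calls=calls,
        samples=["s1", "s2", "s3"],
        af=af,
    )


class TestGenotypeMatrix:
    def test_af_from_calls(self):
        gm = toy_gm()
        # site 1: 3 alt alleles / 6; site 2: 0/4 (missing excluded); site 3: 6/6
        assert np.allclose(gm.af, [0.5, 0.0, 1.0])

    def test_missing_excluded_from_af_denominator(self):
        gm = toy_gm(calls=np.array([[2, -1, -1], [0, 0, 0], [1, 1, 1]], dtype=np.int8))
        assert gm.af[0] == pytest.approx(1.0)

    def test_unsorted_positions_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            GenotypeMatrix(
                chrom=np.array(["chr1", "chr1"], dtype=object),
                pos=np.array([200, 100]),
                ref=np.array(["A", "A"], dtype=object),
                alt=np.array(["T", "T"], dtype=object),
                calls=np.zeros((2, 1), dtype=np.int8),
                samples=["s"],
            )

    def test_split_chromosome_blocks_rejected(self):
        with pytest.raises(ValueError, match="non-contiguous"):
            GenotypeMatrix(
                chrom=np.array(["chr1", "chr2", "chr1"], dtype=object),
                pos=np.array([1, 1, 2]),
                ref=np.array(["A"] * 3, dtype=object),
                alt=np.array(["T"] * 3, dtype=object),
                calls=np.zeros((3, 1), dtype=np.int8),
                samples=["s"],
            )

    def test_units_are_chromosomes_without_arm_labels(self):
        gm = toy_gm()
        units = dict(gm.units())
        assert set(units) == {"chr1", "chr2"}
        assert units["chr1"].tolist() == [0, 1]


class TestVcfRoundTrip:
    def test_round_trip_preserves_everything(self, tmp_path):
        gm = toy_gm()
        path = tmp_path / "t.vcf"
        write_vcf(gm, path)
        back = read_vcf(path)
        assert back.samples == gm.samples
        assert np.all(back.calls == gm.calls)
        assert np.all(back.pos == gm.pos)
        assert np.all(back.chrom == gm.chrom)
        assert np.all(back.ref == gm.ref)
        assert np.allclose(back.af, gm.af)

    def test_codes_and_af_from_text(self, tmp_path):
        path = tmp_path / "t.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\tc\n"
            "chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
            "chr1\t200\t.\tC\tG\t.\tPASS\t.\tGT\t./.\t0/0\t1/0\n"
        )
        gm = read_vcf(path)
        assert gm.calls[0].tolist() == [0, 1, 2]
        assert gm.af[0] == pytest.approx(0.5)
        # missing excluded from the denominator: 1 alt / 4 alleles
        assert gm.calls[1].tolist() == [-1, 0, 1]
        assert gm.af[1] == pytest.approx(0.25)

    def test_multiallelic_skip_and_error(self, tmp_path):
        path = tmp_path / "m.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\n"
            "chr1\t100\t.\tA\tT,G\t.\tPASS\t.\tGT\t0/1\n"
            "chr1\t200\t.\tC\tG\t.\tPASS\t.\tGT\t1/1\n"
        )
        gm = read_vcf(path, multiallelic="skip")
        assert gm.n_sites == 1 and gm.pos[0] == 200
        from rohkit.genomic_io import VcfParseError

        with pytest.raises(VcfParseError):
            read_vcf(path, multiallelic="error")


class TestGeneticMap:
    def test_midpoint_interpolation(self):
        gmap = GeneticMap({"chr1": ([1, 1_000_001], [0.0, 1.0])})
        assert interpolate_cM(gmap, "chr1", 500_001) == pytest.approx(0.5)

    def test_anchor_query_exact(self):
        gmap = GeneticMap({"chr1": ([1, 1_000_001], [0.0, 1.0])})
        assert gmap.cm("chr1", 1_000_001) == pytest.approx(1.0)

    def test_extrapolation_beyond_last_anchor(self):
        gmap = GeneticMap({"chr1": ([1, 1_000_001], [0.0, 1.0])}, default_rate=1.0)
        assert gmap.cm("chr1", 2_000_001) == pytest.approx(2.0)

    def test_before_first_anchor_is_constant(self):
        gmap = GeneticMap({"chr1": ([1000, 2000], [0.5, 0.7])})
        assert gmap.cm("chr1", 10) == pytest.approx(0.5)

    def test_unknown_chromosome(self):
        gmap = GeneticMap({"chr1": ([1], [0.0])})
        with pytest.raises(MapCoverageError):
            gmap.cm("chr9", 100)

    @given(
        pos=st.lists(st.integers(1, 10_000_000), min_size=2, max_size=30),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_position(self, pos):
        gmap = GeneticMap(
            {"c": ([1, 500_000, 3_000_000], [0.0, 0.8, 2.5])}, default_rate=1.3
        )
        q = np.sort(np.asarray(pos))
        cm = gmap.cm("c", q)
        assert np.all(np.diff(cm) >= -1e-12)

    def test_tsv_round_trip_with_header(self, tmp_path):
        gmap = GeneticMap({"chr1": ([1, 100, 5000], [0.0, 0.1, 0.9])})
        p = tmp_path / "map.tsv"
        gmap.write_tsv(p)
        back = GeneticMap.read_tsv(p)
        assert back.cm("chr1", 100) == pytest.approx(0.1)
        assert back.cm("chr1", 2550) == pytest.approx(gmap.cm("chr1", 2550))

    def test_tsv_headerless(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("chr1\t1\t0.0\nchr1\t1000001\t1.0\n")
        gmap = GeneticMap.read_tsv(p)
        assert gmap.cm("chr1", 500_001) == pytest.approx(0.5)


class TestIntervals:
    def test_bed_convention_shift(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t99\t200\n")
        iv = read_intervals(p, "bed")
        assert (iv.chrom[0], iv.start[0], iv.end[0]) == ("chr1", 100, 200)

    def test_gff3_gene_record(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t100\t200\t.\t+\t.\tID=g1;gene_name=FOO\n"
            "chr1\tsrc\texon\t120\t150\t.\t+\t.\tID=e1\n"
        )
        iv = read_intervals(p, "gff3")
        assert len(iv) == 1
        assert (iv.start[0], iv.end[0], iv.name[0]) == (100, 200, "FOO")

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.bed"
        p.write_text("")
        assert len(read_intervals(p, "bed")) == 0

    def test_end_before_start_rejected(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t500\t100\n")
        with pytest.raises(FormatError):
            read_intervals(p, "bed")

    def test_covers_inclusive_bounds(self):
        iv = Intervals(np.array(["c"], dtype=object), np.array([100]), np.array([200]))
        chrom = np.array(["c"] * 4, dtype=object)
        pos = np.array([99, 100, 200, 201])
        assert iv.covers(chrom, pos).tolist() == [False, True, True, False]

    def test_bed_round_trip(self, tmp_path):
        iv = Intervals(
            np.array(["c1", "c2"], dtype=object),
            np.array([100, 5]),
            np.array([200, 5]),
            name=np.array(["x", "y"], dtype=object),
        )
        p = tmp_path / "rt.bed"
        iv.write_bed(p)
        back = read_intervals(p, "bed")
        assert np.all(back.start == iv.start) and np.all(back.end == iv.end)


class TestPedigree:
    def _fam(self):
        return [
            Individual("F1", "gf", None, None, 1),
            Individual("F1", "gm", None, None, 2),
            Individual("F1", "fa", "gf", "gm", 1),
            Individual("F1", "mo", None, None, 2),
            Individual("F1", "c1", "fa", "mo", 1),
        ]

    def test_trios_and_founders(self):
        ped = Pedigree(self._fam())
        assert set(ped.trios()) == {("gf", "gm", "fa"), ("fa", "mo", "c1")}
        assert {i.iid for i in ped.founders()} == {"gf", "gm", "mo"}

    def test_topological_order(self):
        ped = Pedigree(self._fam())
        order = [i.iid for i in ped.topological()]
        assert order.index("fa") > order.index("gf")
        assert order.index("c1") > order.index("fa")

    def test_missing_parent_rejected(self):
        with pytest.raises(PedigreeError):
            Pedigree([Individual("F", "kid", "nope", "mo", 1)])

    def test_single_parent_rejected(self):
        with pytest.raises(PedigreeError):
            Pedigree(
                [Individual("F", "pa"), Individual("F", "kid", "pa", None, 1)]
            )

    def test_fam_round_trip(self, tmp_path):
        ped = Pedigree(self._fam())
        p = tmp_path / "a.fam"
        ped.write_fam(p)
        back = Pedigree.read_fam(p)
        assert back.iids == ped.iids
        assert back["c1"].father == "fa" and back["gf"].father is None
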