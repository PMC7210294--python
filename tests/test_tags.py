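import numpy as np
import pytest

from pausescape import annotation as ann
from pausescape import tags
from pausescape.synthetic import generate_null_background

from conftest import make_library


class TestLoading:
    def test_bed6_count_and_total(self, tmp_path):
        p = tmp_path / "t.bed"
        p.write_text(
            "".join(f"chr1\t{i * 100}\t{i * 100 + 36}\tr{i}\t0\t+\n" for i in range(5))
        )
        lib = tags.load_tags(p, "chip")
        assert len(lib) == 5 and lib.total == 5 and lib.state == "raw"

    def test_bad_interval_rejected(self, tmp_path):
        p = tmp_path / "t.bed"
        p.write_text("chr1\t100\t100\tr\t0\t+\n")
        with pytest.raises(ValueError):
            tags.load_tags(p, "chip")

    def test_strandless_proseq_rejected_chip_warned(self, tmp_path):
        p = tmp_path / "t.bed"
        p.write_text("chr1\t0\t36\tr\t0\t.\n")
        with pytest.raises(ValueError):
            tags.load_tags(p, "proseq")
        with pytest.warns(UserWarning):
            lib = tags.load_tags(p, "chip")
        assert lib.strand[0] == "+"

    def test_bam_counts_mapped_primary_only(self, tmp_path):
        pysam = pytest.importorskip("pysam")
        path = str(tmp_path / "t.bam")
        header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 10_000}]}
        with pysam.AlignmentFile(path, "wb", header=header) as bam:
            for i in range(5):
                a = pysam.AlignedSegment()
                a.query_name = f"r{i}"
                a.query_sequence = "A" * 36
                a.query_qualities = pysam.qualitystring_to_array("I" * 36)
                if i < 3:
                    a.reference_id = 0
                    a.reference_start = 100 * i
                    a.cigarstring = "36M"
                    a.is_reverse = i % 2 == 1
                else:
                    a.is_unmapped = True
                bam.write(a)
        lib = tags.load_tags(path, "chip")
        assert lib.total == 3
        assert lib.strand.tolist() == ["+", "-", "+"]


class TestProcessing:
    def test_plus_extension(self):
        lib = make_library([("chr1", 100, 136, "+")])
        out = tags.extend_chip_tags(lib, 150)
        assert (out.start[0], out.end[0]) == (100, 250)

    def test_minus_extension_clipped_at_zero(self):
        lib = make_library([("chr1", 100, 136, "-")])
        out = tags.extend_chip_tags(lib, 150)
        assert (out.start[0], out.end[0]) == (0, 136)

    def test_identity_when_fragment_equals_read(self):
        lib = make_library([("chr1", 100, 136, "+"), ("chr1", 500, 536, "-")])
        out = tags.extend_chip_tags(lib, 36)
        assert out.start.tolist() == [100, 500]
        assert out.end.tolist() == [136, 536]

    def test_layout_clipping(self):
        lib = make_library([("chr1", 950, 986, "+")])
        out = tags.extend_chip_tags(lib, 150, ann.GenomeLayout({"chr1": 1000}))
        assert (out.start[0], out.end[0]) == (950, 1000)

    def test_re_extension_rejected(self):
        lib = make_library([("chr1", 0, 36, "+")])
        out = tags.extend_chip_tags(lib)
        with pytest.raises(tags.TagStateError):
            tags.extend_chip_tags(out)

    def test_proseq_reduction_five_prime(self):
        lib = make_library(
            [("chr1", 200, 275, "+"), ("chr1", 200, 275, "-")], assay="proseq"
        )
        out = tags.reduce_proseq_tags(lib)
        assert (out.start[0], out.end[0]) == (200, 201)
        assert (out.start[1], out.end[1]) == (274, 275)
        with pytest.raises(tags.TagStateError):
            tags.reduce_proseq_tags(out)

    def test_processing_preserves_count_and_chrom(self):
        lib = generate_null_background(500, 100_000, seed=3)
        out = tags.extend_chip_tags(lib, 150)
        assert len(out) == len(lib) and out.total == lib.total
        assert (out.chrom == lib.chrom).all()


class TestCounting:
    def test_overlap_boundary(self):
        lib = make_library([("chr1", 100, 250, "+")], state="extended")
        assert tags.count_tags(lib, "chr1", (240, 300)) == 1
        assert tags.count_tags(lib, "chr1", (250, 300)) == 0  # half-open

    def test_antisense_convention(self):
        lib = make_library(
            [("chr1", 150, 151, "-"), ("chr1", 160, 161, "+")],
            assay="proseq", state="reduced",
        )
        assert tags.count_tags(lib, "chr1", (100, 200), "+", "sense_via_antisense") == 1
        assert tags.count_tags(lib, "chr1", (100, 200), "-", "sense_via_antisense") == 1

    def test_empty_library(self):
        lib = make_library([], state="extended")
        assert tags.count_tags(lib, "chr1", (0, 1000)) == 0

    def test_chip_antisense_mode_rejected(self):
        lib = make_library([("chr1", 0, 150, "+")], state="extended")
        with pytest.raises(ValueError):
            tags.count_tags(lib, "chr1", (0, 100), "+", "sense_via_antisense")

    def test_strand_mirror_symmetry(self):
        rng = np.random.default_rng(5)
        recs = [
            ("chr1", int(p), int(p) + 1, "+" if s else "-")
            for p, s in zip(rng.integers(0, 5000, 200), rng.integers(0, 2, 200))
        ]
        lib = make_library(recs, assay="proseq", state="reduced")
        flipped = make_library(
            [(c, s, e, "-" if st == "+" else "+") for c, s, e, st in recs],
            assay="proseq", state="reduced",
        )
        for gene_strand, flip_strand in (("+", "-"), ("-", "+")):
            assert tags.count_tags(
                lib, "chr1", (1000, 3000), gene_strand, "sense_via_antisense"
            ) == tags.count_tags(
                flipped, "chr1", (1000, 3000), flip_strand, "sense_via_antisense"
            )


class TestMatrix:
    def _region(self, strand="+", tss=50_000):
        if strand == "+":
            g = ann.GeneModel("G", "t", "chr1", "+", tss, tss + 20_000)
        else:
            g = ann.GeneModel("G", "t", "chr1", "-", tss - 20_000, tss)
        return ann.define_regions(g)

    def test_single_tag_bin_placement(self):
        r = self._region("+")
        lib = make_library([("chr1", 50_005, 50_006, "+")], state="extended")
        m = tags.tss_matrix(lib, [r])
        assert m.values.shape == (1, 300)
        assert m.values[0, 100] == 1 and m.values.sum() == 1

    def test_minus_strand_mirror_bin(self):
        r = self._region("-")
        # 5 bp upstream of the TSS in transcription direction = genomic TSS+5
        lib = make_library([("chr1", 50_004, 50_005, "+")], state="extended")
        m = tags.tss_matrix(lib, [r])
        assert m.values[0, 99] == 1 and m.values.sum() == 1

    def test_empty_library_zero_matrix(self):
        m = tags.tss_matrix(make_library([], state="extended"), [self._region()])
        assert not m.values.any()

    def test_window_must_divide_by_bin(self):
        with pytest.raises(ValueError):
            tags.tss_matrix(make_library([], state="extended"), [self._region()],
                            upstream=1003)

    def test_box_sum_equals_window_count_for_point_tags(self):
        rng = np.random.default_rng(0)
        pos = rng.integers(48_000, 53_000, 400)
        lib = make_library(
            [("chr1", int(p), int(p) + 1, "-") for p in pos],
            assay="proseq", state="reduced",
        )
        r = self._region("+")
        m = tags.tss_matrix(lib, [r], strand_mode="sense_via_antisense")
        b0, b1 = m.bin_of(-250), m.bin_of(250)
        assert m.values[0, b0:b1].sum() == tags.count_tags(
            lib, "chr1", r.tss_window, "+", "sense_via_antisense"
        )


class TestNormalization:
    def test_per10m_closed_form(self):
        assert tags.normalize_per10M(50, 5_000_000) == 100.0
        assert tags.normalize_per10M(7, 10_000_000) == 7.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            tags.normalize_per10M(1, 0)

    def test_commutes_with_row_sum(self):
        x = np.arange(12.0).reshape(3, 4)
        a = tags.normalize_per10M(x, 2_000_000).sum(axis=1)
        b = tags.normalize_per10M(x.sum(axis=1), 2_000_000)
        np.testing.assert_allclose(a, b)

    def test_average_profile(self):
        m = tags.SignalMatrix(["a", "b"], np.array([[0.0, 2.0], [4.0, 0.0]]),
                              10, 10, 10)
        np.testing.assert_array_equal(tags.average_profile(m), [2.0, 1.0])


class TestBedgraph:
    def test_single_tag_record(self, tmp_path):
        lib = make_library([("chr1", 0, 150, "+")], state="extended", total=10_000_000)
        p = tmp_path / "o.bedgraph"
        tags.export_bedgraph(lib, p)
        lines = p.read_text().strip().split("\n")
        assert lines[1] == "chr1\t0\t150\t1"

    def test_empty_library_header_only(self, tmp_path):
        p = tmp_path / "o.bedgraph"
        tags.export_bedgraph(make_library([], state="extended"), p)
        assert p.read_text().startswith("track type=bedGraph")
        assert len(p.read_text().strip().split("\n")) == 1

    def test_stacked_tags_pileup(self, tmp_path):
        lib = make_library(
            [("chr1", 0, 100, "+"), ("chr1", 50, 150, "+")],
            state="extended", total=10_000_000,
        )
        p = tmp_path / "o.bedgraph"
        tags.export_bedgraph(lib, p)
        body = [l.split("\t") for l in p.read_text().strip().split("\n")[1:]]
        assert [(b[1], b[2], b[3]) for b in body] == [
            ("0", "50", "1"), ("50", "100", "2"), ("100", "150", "1")
        ]

    def test_conservation_identity(self, tmp_path):
        lib = generate_null_background(300, 1_000_000, seed=9)
        lib = tags.extend_chip_tags(lib, 150)
        p = tmp_path / "o.bedgraph"
        tags.export_bedgraph(lib, p)
        total = 0.0
        for line in p.read_text().strip().split("\n")[1:]:
            _, s, e, v = line.split("\t")
            total += (int(e) - int(s)) * float(v)
        widths = (lib.end - lib.start).sum()
        np.testing.assert_allclose(total, widths * 1e7 / lib.total, rtol=1e-9)
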