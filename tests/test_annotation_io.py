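import pytest
from hypothesis import given
from hypothesis import strategies as st

from tiletar.annotation_io import (
    BedRecord,
    Gene,
    Interval,
    Probe,
    ProbeDesign,
    gene_span,
    interval_gap,
    merge_intervals,
    read_bed,
    read_gff,
    read_probe_design,
    union_length,
    write_bed,
    write_gff,
    write_probe_design,
)

GFF_TOY = """##gff-version 3
##sequence-region LG2 1 10000
LG2\ttest\tgene\t101\t900\t.\t+\t.\tID=gA
LG2\ttest\texon\t101\t200\t.\t+\t.\tID=gA.e1;Parent=gA
LG2\ttest\texon\t301\t400\t.\t+\t.\tID=gA.e2;Parent=gA
LG2\ttest\texon\t601\t900\t.\t+\t.\tID=gA.e3;Parent=gA
LG2\ttest\tgene\t2001\t3000\t.\t-\t.\tID=gB
LG2\ttest\tmRNA\t2001\t3000\t.\t-\t.\tID=gB.t1;Parent=gB
LG2\ttest\texon\t2001\t2200\t.\t-\t.\tID=gB.e1;Parent=gB.t1
LG2\ttest\texon\t2301\t2500\t.\t-\t.\tID=gB.e2;Parent=gB.t1
LG2\ttest\texon\t2801\t3000\t.\t-\t.\tID=gB.e3;Parent=gB.t1
"""


class TestReadGff:
    def test_coordinate_conversion(self, tmp_path):
        """A GFF exon 101..200 becomes the half-open interval [100, 200)."""
        p = tmp_path / "toy.gff3"
        p.write_text(GFF_TOY)
        ann = read_gff(p)
        ga = next(g for g in ann.genes if g.gene_id == "gA")
        assert ga.exons[0] == (100, 200)
        assert ga.exons[0][1] - ga.exons[0][0] == 100

    def test_two_genes_three_exons_each(self, tmp_path):
        p = tmp_path / "toy.gff3"
        p.write_text(GFF_TOY)
        ann = read_gff(p)
        assert len(ann.genes) == 2
        assert all(len(g.exons) == 3 for g in ann.genes)
        # exons reached through an mRNA parent are still grouped under the gene
        gb = next(g for g in ann.genes if g.gene_id == "gB")
        assert gb.exons == ((2000, 2200), (2300, 2500), (2800, 3000))

    def test_sequence_region_pragma_sets_length(self, tmp_path):
        p = tmp_path / "toy.gff3"
        p.write_text(GFF_TOY)
        ann = read_gff(p)
        assert ann.chromosome_lengths["LG2"] == 10000

    def test_overlapping_exon_records_unioned(self, tmp_path, caplog):
        gff = (
            "##gff-version 3\n"
            "LG2\tt\tgene\t101\t400\t.\t+\t.\tID=g\n"
            "LG2\tt\texon\t101\t250\t.\t+\t.\tID=e1;Parent=g\n"
            "LG2\tt\texon\t201\t400\t.\t+\t.\tID=e2;Parent=g\n"
        )
        p = tmp_path / "o.gff3"
        p.write_text(gff)
        import logging

        with caplog.at_level(logging.WARNING):
            ann = read_gff(p)
        # oracle: interval union of [100,250) and [200,400)
        assert ann.genes[0].exons == tuple(merge_intervals([(100, 250), (200, 400)]))
        assert ann.genes[0].exons == ((100, 400),)
        assert any("merged" in r.message for r in caplog.records)

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text("##gff-version 3\nLG2\tonly\tthree\n")
        with pytest.raises(ValueError, match="line 2"):
            read_gff(p)

    def test_orphan_exon_skipped_with_warning(self, tmp_path, caplog):
        gff = GFF_TOY + "LG2\tt\texon\t5001\t5100\t.\t+\t.\tID=orphan\n"
        p = tmp_path / "orph.gff3"
        p.write_text(gff)
        import logging

        with caplog.at_level(logging.WARNING):
            ann = read_gff(p)
        assert len(ann.genes) == 2
        assert any("without a parent gene" in r.message for r in caplog.records)

    def test_x_chromosome_labelling(self, tmp_path):
        gff = (
            "##gff-version 3\n"
            "##sequence-region LGX 1 5000\n"
            "LGX\tt\tgene\t1\t100\t.\t+\t.\tID=g\n"
            "LGX\tt\texon\t1\t100\t.\t+\t.\tID=e;Parent=g\n"
        )
        p = tmp_path / "x.gff3"
        p.write_text(gff)
        ann = read_gff(p)
        assert ann.chromosomes[0].chrom_class == "X"

    def test_round_trip(self, tmp_path, toy_annotation):
        p = tmp_path / "rt.gff3"
        write_gff(toy_annotation, p)
        back = read_gff(p)
        assert back.chromosome_lengths == toy_annotation.chromosome_lengths
        assert [(g.gene_id, g.chromosome, g.exons) for g in back.genes] == [
            (g.gene_id, g.chromosome, g.exons) for g in toy_annotation.genes
        ]


class TestProbeDesignIO:
    def _write(self, tmp_path, rows):
        p = tmp_path / "design.tsv"
        lines = ["probe_id\tclass\tchromosome\tstart\tend"]
        lines += ["\t".join(str(x) for x in r) for r in rows]
        p.write_text("\n".join(lines) + "\n")
        return p

    def test_counts_and_sorting(self, tmp_path):
        rows = [
            ("p3", "experimental", "LG2", 200, 260),
            ("p1", "experimental", "LG2", 0, 60),
            ("p2", "experimental", "LG2", 100, 160),
            ("p5", "experimental", "LGA", 50, 110),
            ("p4", "experimental", "LG2", 300, 360),
            ("r1", "random", "", "", ""),
            ("r2", "random", "", "", ""),
            ("r3", "random", "", "", ""),
        ]
        design = read_probe_design(self._write(tmp_path, rows), length_range=(40, 80))
        assert len(design.experimental) == 5
        assert len(design.random) == 3
        addresses = [(p.address.chromosome, p.address.start) for p in design.experimental]
        assert addresses == sorted(addresses)

    def test_duplicate_probe_id_rejected(self, tmp_path):
        rows = [
            ("p1", "experimental", "LG2", 0, 60),
            ("p1", "experimental", "LG2", 100, 160),
        ]
        with pytest.raises(ValueError, match="duplicate"):
            read_probe_design(self._write(tmp_path, rows), length_range=(40, 80))

    def test_random_probe_address_ignored(self, tmp_path, caplog):
        import logging

        rows = [("r1", "random", "LG2", 0, 60)]
        with caplog.at_level(logging.WARNING):
            design = read_probe_design(self._write(tmp_path, rows))
        assert design.random[0].address is None
        assert any("ignored" in r.message for r in caplog.records)

    def test_out_of_bounds_probe_rejected(self, tmp_path, toy_annotation):
        rows = [("p1", "experimental", "LG2", 9_990, 10_050)]
        with pytest.raises(ValueError, match="past the end"):
            read_probe_design(
                self._write(tmp_path, rows), toy_annotation, length_range=(40, 80)
            )

    def test_round_trip(self, tmp_path):
        design = ProbeDesign(
            [Probe("p1", "experimental", Interval("LG2", 0, 54))],
            [Probe("r1", "random", None)],
        )
        p = tmp_path / "d.tsv"
        write_probe_design(design, p)
        back = read_probe_design(p)
        assert back.experimental[0].address == Interval("LG2", 0, 54)
        assert back.random[0].probe_id == "r1"


class TestIntervalArithmetic:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (Interval("c", 0, 100), Interval("c", 100, 200), 0),  # abutting
            (Interval("c", 0, 100), Interval("c", 150, 200), 50),
            (Interval("c", 0, 100), Interval("c", 50, 200), 0),  # overlap
        ],
    )
    def test_interval_gap(self, a, b, expected):
        assert interval_gap(a, b) == expected

    def test_gap_requires_same_chromosome(self):
        with pytest.raises(ValueError):
            interval_gap(Interval("c1", 0, 10), Interval("c2", 0, 10))

    @given(
        st.tuples(st.integers(0, 10_000), st.integers(1, 500)),
        st.tuples(st.integers(0, 10_000), st.integers(1, 500)),
    )
    def test_gap_symmetric(self, a, b):
        ia = Interval("c", a[0], a[0] + a[1])
        ib = Interval("c", b[0], b[0] + b[1])
        assert interval_gap(ia, ib) == interval_gap(ib, ia)

    @pytest.mark.parametrize(
        "exons,expected",
        [
            (((100, 200), (400, 500)), (100, 500)),
            (((0, 310),), (0, 310)),
        ],
    )
    def test_gene_span(self, exons, expected):
        g = Gene("g", "c", "+", exons)
        assert (gene_span(g).start, gene_span(g).end) == expected

    def test_gene_span_order_invariant(self):
        sorted_exons = tuple(sorted([(400, 500), (100, 200)]))
        g = Gene("g", "c", "+", sorted_exons)
        assert gene_span(g) == Interval("c", 100, 500)

    def test_span_at_least_exon_union(self):
        g = Gene("g", "c", "+", ((100, 200), (400, 500)))
        assert gene_span(g).length >= union_length(g.exons)
        single = Gene("s", "c", "+", ((0, 310),))
        assert gene_span(single).length == union_length(single.exons)


class TestBed:
    def test_line_format(self, tmp_path):
        p = tmp_path / "a.bed"
        write_bed([BedRecord(Interval("LG3", 1000, 1250), "t1", 550)], p)
        lines = p.read_text().splitlines()
        assert lines[0].startswith("track")
        assert lines[1] == "LG3\t1000\t1250\tt1\t550\t."

    def test_empty_set_writes_header_only(self, tmp_path):
        p = tmp_path / "e.bed"
        write_bed([], p)
        lines = p.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("track")

    def test_sorted_by_chromosome_then_start(self, tmp_path):
        p = tmp_path / "s.bed"
        write_bed([Interval("LG9", 100, 200), Interval("LG2", 100, 200)], p)
        chroms = [l.split("\t")[0] for l in p.read_text().splitlines()[1:]]
        assert chroms == ["LG2", "LG9"]

    def test_round_trip(self, tmp_path):
        records = [
            BedRecord(Interval("LG2", 0, 100), "a", 10),
            BedRecord(Interval("LG2", 500, 700), "b", 990),
        ]
        p = tmp_path / "rt.bed"
        write_bed(records, p)
        assert [r.interval for r in read_bed(p)] == [r.interval for r in records]
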