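import numpy as np
import pytest

from seqexpr.intervals import GenomicInterval, total_length
from seqexpr.regions import (
    AnnotationError,
    GeneModel,
    REGION_KINDS,
    build_catalog,
    derive_dfr,
    derive_introns,
    merge_and_concatenate,
    reverse_complement,
    segment_promoter,
    select_tss,
)


def iv(start, end, chrom="chr1", strand="+"):
    return GenomicInterval(chrom, start, end, strand)


class TestSelectTss:
    @pytest.mark.parametrize(
        "tss_list, choice, expected",
        [
            ([100], "second", 100),  # fallback: no second TSS -> first
            ([100, 300], "third", 300),  # fallback: no third TSS -> second
            ([100, 300, 900], "last", 900),
            ([100, 300, 900], "first", 100),
            ([100, 300, 900], "second", 300),
            ([100, 300, 900], "third", 900),
        ],
    )
    def test_choice_with_fallback(self, tss_list, choice, expected):
        assert select_tss(tss_list, choice) == expected

    def test_empty_list_is_annotation_error(self):
        with pytest.raises(AnnotationError):
            select_tss([], "first")


class TestSegmentPromoter:
    def test_plus_strand_layout(self):
        segs = segment_promoter("chr1", 10000, "+")
        assert segs["DU"] == iv(8000, 9500)
        assert segs["CORE"] == iv(9500, 10500)
        assert segs["DD"] == iv(10500, 12000)

    def test_minus_strand_is_mirrored(self):
        segs = segment_promoter("chr1", 10000, "-", chrom_length=20000)
        assert segs["DU"] == iv(10500, 12000, strand="-")
        assert segs["CORE"] == iv(9500, 10500, strand="-")
        assert segs["DD"] == iv(8000, 9500, strand="-")

    def test_clipping_near_chromosome_start(self):
        segs = segment_promoter("chr1", 300, "+", chrom_length=50000)
        assert segs["DU"] is None  # [-1700, -200) entirely off-chromosome
        assert segs["CORE"] == iv(0, 800)
        assert segs["DD"] == iv(800, 2300)

    def test_segment_lengths_without_clipping(self):
        segs = segment_promoter("chr1", 50000, "+", chrom_length=100000)
        assert len(segs["CORE"]) == 1000
        assert len(segs["DU"]) == len(segs["DD"]) == 1500


class TestMergeAndConcatenate:
    genome = {"chr1": "ACGT" * 25}  # 100 bp

    def test_overlapping(self):
        merged, seq = merge_and_concatenate([iv(10, 20), iv(15, 30)], self.genome)
        assert merged == [iv(10, 30)]
        assert len(seq) == 20
        assert seq == self.genome["chr1"][10:30]

    def test_bookended(self):
        merged, _ = merge_and_concatenate([iv(10, 20), iv(20, 30)], self.genome)
        assert merged == [iv(10, 30)]

    def test_single_interval_identity(self):
        merged, seq = merge_and_concatenate([iv(4, 8)], self.genome)
        assert merged == [iv(4, 8)]
        assert seq == self.genome["chr1"][4:8]

    def test_minus_strand_reverse_complements_in_transcription_order(self):
        merged, seq = merge_and_concatenate(
            [iv(10, 14, strand="-"), iv(20, 24, strand="-")], self.genome
        )
        expected = reverse_complement(self.genome["chr1"][20:24]) + reverse_complement(
            self.genome["chr1"][10:14]
        )
        assert seq == expected

    def test_out_of_bounds_raises(self):
        with pytest.raises(ValueError, match="outside genome"):
            merge_and_concatenate([iv(90, 120)], self.genome)


class TestDeriveIntrons:
    def test_interior_intron(self):
        result = derive_introns(iv(0, 1000), [iv(0, 100), iv(100, 200), iv(900, 1000)])
        assert result == [iv(200, 900)]

    def test_fully_exonic_gene_has_no_introns(self):
        assert derive_introns(iv(0, 100), [iv(0, 100)]) == []

    def test_multiple_gaps(self):
        result = derive_introns(iv(0, 100), [iv(20, 40), iv(60, 80)])
        assert result == [iv(0, 20), iv(40, 60), iv(80, 100)]


class TestDeriveDfr:
    def _gene(self, start, end, strand):
        return GeneModel("g", "chr1", strand, start, end, tss_list=[start])

    def test_plus_strand(self):
        assert derive_dfr(self._gene(1000, 5000, "+"), 100000) == iv(5000, 6000)

    def test_minus_strand_mirrors(self):
        gene = self._gene(5000, 9000, "-")
        assert derive_dfr(gene, 100000) == iv(4000, 5000, strand="-")

    def test_clipped_at_chromosome_end(self):
        dfr = derive_dfr(self._gene(1000, 4800, "+"), 5000)
        assert dfr == iv(4800, 5000)
        assert len(dfr) == 200


class TestBuildCatalog:
    def test_all_eight_regions_populated(self, small_sim):
        catalog = small_sim["catalog"]
        assert len(catalog.entries) == 80
        for entry in catalog.entries.values():
            assert set(entry.regions) == set(REGION_KINDS)

    def test_intron_disjoint_from_exonic_regions(self, small_sim):
        for entry in small_sim["catalog"].entries.values():
            intr = set()
            for i in entry.regions["INTR"][0]:
                intr.update(range(i.start, i.end))
            exonic = set()
            for kind in ("UTR5", "CDS", "UTR3"):
                for i in entry.regions[kind][0]:
                    exonic.update(range(i.start, i.end))
            assert not intr & exonic

    def test_intron_plus_exonic_tile_gene_span(self, small_sim):
        gene_by_id = {g.gene_id: g for g in small_sim["annotation"].genes}
        for gid, entry in small_sim["catalog"].entries.items():
            gene = gene_by_id[gid]
            from seqexpr.intervals import merge

            exonic = merge(gene.utr5 + gene.cds + gene.utr3)
            covered = total_length(entry.regions["INTR"][0]) + total_length(exonic)
            assert covered == gene.end - gene.start

    def test_sequence_length_equals_interval_length(self, small_sim):
        for entry in small_sim["catalog"].entries.values():
            for kind in REGION_KINDS:
                intervals, seq = entry.regions[kind]
                assert len(seq) == total_length(intervals)

    def test_fully_exonic_gene_flagged(self):
        genome = {"chr1": "ACGT" * 3000}
        gene = GeneModel(
            "g1", "chr1", "+", 4000, 5000, tss_list=[4000],
            utr5=[iv(4000, 4200)], cds=[iv(4200, 4800)], utr3=[iv(4800, 5000)],
        )
        catalog = build_catalog([gene], genome)
        entry = catalog.entries["g1"]
        assert entry.regions["INTR"][1] == ""
        assert "INTR" in entry.missing

    def test_gene_without_tss_is_skipped(self):
        genome = {"chr1": "ACGT" * 3000}
        gene = GeneModel("g1", "chr1", "+", 4000, 5000, tss_list=[])
        catalog = build_catalog([gene], genome)
        assert catalog.skipped == ["g1"]
        assert not catalog.entries


class TestStrandCovariance:
    def test_mirrored_annotation_gives_identical_sequences(self, small_sim):
        """Reverse-complementing the genome and flipping annotations must
        reproduce the same extracted sequences."""
        ann = small_sim["annotation"]
        gene = next(g for g in ann.genes if g.strand == "+")
        genome = {gene.chrom: ann.genome[gene.chrom]}
        L = len(genome[gene.chrom])

        def flip_iv(i):
            return GenomicInterval(i.chrom, L - i.end, L - i.start, "-")

        flipped_genome = {gene.chrom: reverse_complement(genome[gene.chrom])}
        flipped = GeneModel(
            gene.gene_id,
            gene.chrom,
            "-",
            L - gene.end,
            L - gene.start,
            tss_list=[L - 1 - t for t in gene.tss_list],
            utr5=[flip_iv(i) for i in gene.utr5],
            cds=[flip_iv(i) for i in gene.cds],
            utr3=[flip_iv(i) for i in gene.utr3],
        )
        original = build_catalog([gene], genome).entries[gene.gene_id]
        mirrored = build_catalog([flipped], flipped_genome).entries[gene.gene_id]
        for kind in ("UTR5", "CDS", "UTR3", "INTR", "DFR"):
            assert original.regions[kind][1] == mirrored.regions[kind][1], kind
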