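"""Catalog extraction, categorization, gene models and overlap classes."""

import io

import pytest

from sporescreen import annotation as ann
from sporescreen.annotation import (
    GeneRecord,
    NcRNACatalog,
    classify_category,
    classify_overlap,
    load_gene_models,
    parse_genbank_ncrnas,
    transcript_coords,
)


def _genbank(features: str, seq: str) -> io.StringIO:
    n = len(seq)
    lines = [
        f"LOCUS       chrT                      {n} bp    DNA     linear   UNA 01-JAN-2020",
        "DEFINITION  test chromosome.",
        "ACCESSION   chrT",
        "VERSION     chrT",
        "FEATURES             Location/Qualifiers",
        features.rstrip("\n"),
        "ORIGIN",
    ]
    for i in range(0, n, 60):
        chunk = seq[i : i + 60]
        grouped = " ".join(chunk[j : j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {grouped}")
    lines.append("//")
    return io.StringIO("\n".join(lines) + "\n")


# 60-nt fixture chromosome
CHROM = "ATGGCCAAATTTGGGCCCAAATTTACGTACGTAAACCCGGGTTTAAACCCTTTGGGAAAC"

FEATURES = """\
     misc_RNA        5..16
                     /gene="RNA.plus"
     misc_RNA        complement(join(21..30,41..50))
                     /gene="RNA.minus"
     CDS             31..39
                     /gene="prot1"
"""


class TestParseGenbank:
    def test_two_records_extracted_cds_ignored(self):
        cat = parse_genbank_ncrnas(_genbank(FEATURES, CHROM))
        assert len(cat) == 2
        assert set(cat.records) == {"RNA.plus", "RNA.minus"}

    def test_plus_strand_sequence(self):
        cat = parse_genbank_ncrnas(_genbank(FEATURES, CHROM))
        expected = CHROM[4:16].replace("T", "U")
        assert cat["RNA.plus"].sequence == expected

    def test_minus_strand_join_hand_reverse_complement(self):
        cat = parse_genbank_ncrnas(_genbank(FEATURES, CHROM))
        rec = cat["RNA.minus"]
        assert rec.strand == "-"
        assert rec.exons == [(20, 30), (40, 50)]
        concat = CHROM[20:30] + CHROM[40:50]
        revcomp = concat[::-1].translate(str.maketrans("ACGT", "TGCA"))
        assert rec.sequence == revcomp.replace("T", "U")

    def test_no_misc_rna_gives_empty_catalog(self):
        only_cds = '     CDS             5..16\n                     /gene="p"\n'
        assert len(parse_genbank_ncrnas(_genbank(only_cds, CHROM))) == 0

    def test_malformed_genbank_raises(self):
        # declared length disagrees with the sequence body
        bad = _genbank(FEATURES, CHROM).getvalue().replace(" 60 bp", " 99 bp")
        with pytest.raises(ValueError, match="malformed GenBank"):
            parse_genbank_ncrnas(io.StringIO(bad))

    def test_unparseable_location_skipped_with_warning(self, caplog):
        broken = (
            '     misc_RNA        join(abc..def)\n'
            '                     /gene="broken"\n'
        )
        with caplog.at_level("WARNING", logger="sporescreen.annotation"):
            cat = parse_genbank_ncrnas(_genbank(broken + FEATURES, CHROM))
        assert "broken" not in cat
        assert len(cat) == 2
        assert any("skipping misc_RNA" in m for m in caplog.messages)


class TestClassifyCategory:
    def _rec(self, gid):
        return GeneRecord(gid, "chr1", "+", [(0, 10)])

    def test_qualifier_beats_nothing(self):
        assert classify_category(
            self._rec("SPBTRNAGLU.08"), {"SPBTRNAGLU.08": "tRNA Glutamic acid"}
        ) == "tRNA"

    def test_unqualified_unpatterned_is_unconventional(self):
        assert classify_category(self._rec("SPNCRNA.1669"), {}) == "unconventional"

    def test_pseudogene_qualifier_beats_name_pattern(self):
        assert classify_category(
            self._rec("SPBTRNAGLU.09"), {"SPBTRNAGLU.09": "pseudogene"}
        ) == "pseudogene"

    def test_name_pattern_fallback(self):
        assert classify_category(self._rec("SPBTRNALYS.01"), {}) == "tRNA"
        assert classify_category(self._rec("SPSNORNA.20"), {}) == "snoRNA"

    def test_conflicting_hints_raise(self):
        with pytest.raises(ValueError, match="conflicting"):
            classify_category(
                self._rec("X.1"), {"X.1": "snoRNA or maybe tRNA"}
            )


GFF3 = """##gff-version 3
chr1\tsrc\tgene\t101\t160\t.\t+\t.\tID=g1
chr1\tsrc\tmRNA\t101\t160\t.\t+\t.\tID=g1.1;Parent=g1
chr1\tsrc\tCDS\t101\t160\t.\t+\t0\tID=g1.1.cds;Parent=g1.1
"""


class TestGeneModels:
    def test_three_line_fixture_indexes_one_cds(self):
        idx = load_gene_models(io.StringIO(GFF3))
        hits = idx.query("chr1", 120, 130, "CDS")
        assert len(hits) == 1

    def test_one_based_inclusive_becomes_half_open(self):
        idx = load_gene_models(io.StringIO(GFF3))
        (hit,) = idx.query("chr1", 0, 10**6, "CDS")
        assert (hit.start, hit.end) == (100, 160)

    def test_empty_body_answers_no_hits(self):
        idx = load_gene_models(io.StringIO("##gff-version 3\n"))
        assert idx.query("chr1", 0, 10**9, "CDS") == []

    def test_half_open_query_excludes_touching(self):
        idx = load_gene_models(io.StringIO(GFF3))
        assert idx.query("chr1", 160, 200, "CDS") == []
        assert idx.query("chr1", 90, 100, "CDS") == []


class TestClassifyOverlap:
    def _models(self, lines):
        return load_gene_models(io.StringIO("##gff-version 3\n" + lines))

    def test_nested_in_antisense_cds(self):
        idx = self._models("chr1\ts\tCDS\t1\t500\t.\t-\t0\tID=c1\n")
        rec = GeneRecord("n1", "chr1", "+", [(100, 200)])
        assert classify_overlap(rec, idx).value == "antisense_to_cds"

    def test_no_overlap_is_cds_free(self):
        idx = self._models("chr1\ts\tCDS\t1\t50\t.\t+\t0\tID=c1\n")
        rec = GeneRecord("n1", "chr1", "+", [(100, 200)])
        assert classify_overlap(rec, idx).value == "cds_free"

    def test_utr_only_overlap(self):
        idx = self._models("chr1\ts\tfive_prime_UTR\t101\t150\t.\t+\t.\tID=u1\n")
        rec = GeneRecord("n1", "chr1", "+", [(100, 200)])
        assert classify_overlap(rec, idx).value == "cds_free_utr_overlap"

    def test_other_ncrna_sets_flag(self):
        idx = self._models("chr1\ts\tncRNA\t101\t150\t.\t+\t.\tID=other\n")
        rec = GeneRecord("n1", "chr1", "+", [(100, 200)])
        oc = classify_overlap(rec, idx)
        assert oc.value == "cds_free" and oc.overlaps_other_ncrna

    @pytest.mark.parametrize("strand", ["+", "-"])
    @pytest.mark.parametrize(
        "cds_interval, overlaps",
        [
            ((150, 160), True),    # nested
            ((50, 150), True),     # left overlap
            ((150, 250), True),    # right overlap
            ((50, 250), True),     # engulfing
            ((200, 300), False),   # touching end-to-start
            ((50, 100), False),    # touching start-to-end
            ((300, 400), False),   # disjoint
        ],
    )
    def test_cds_overlap_grid_never_cds_free(self, strand, cds_interval, overlaps):
        s, e = cds_interval
        idx = self._models(f"chr1\tsrc\tCDS\t{s + 1}\t{e}\t.\t{strand}\t0\tID=c\n")
        rec = GeneRecord("n1", "chr1", "+", [(100, 200)])
        oc = classify_overlap(rec, idx)
        assert (oc.value == "antisense_to_cds") == overlaps
        if overlaps:
            assert oc.value != "cds_free"


class TestCatalogContainer:
    def test_counts_sum_to_total(self, small_catalog):
        assert sum(small_catalog.counts_by_category.values()) == len(small_catalog)

    def test_tsv_round_trip_identical(self, small_catalog, tmp_path):
        path = tmp_path / "catalog.tsv"
        small_catalog.write_tsv(path)
        back = NcRNACatalog.read_tsv(path)
        assert set(back.records) == set(small_catalog.records)
        for gid, rec in small_catalog.records.items():
            other = back[gid]
            assert (rec.chrom, rec.strand, rec.exons, rec.category, rec.sequence) == (
                other.chrom, other.strand, other.exons, other.category, other.sequence
            )

    def test_duplicate_gene_ids_rejected(self):
        cat = NcRNACatalog()
        cat.add(GeneRecord("a", "chr1", "+", [(0, 10)]))
        with pytest.raises(ValueError, match="duplicate"):
            cat.add(GeneRecord("a", "chr1", "+", [(20, 30)]))

    def test_parse_recovers_generator_genes(self, small_screenset, small_catalog):
        expected = set(small_screenset.labels)
        assert set(small_catalog.records) == expected
        for gid, label in small_screenset.labels.items():
            assert small_catalog[gid].category == label.category

    def test_transcript_coords_minus_strand(self):
        rec = GeneRecord("m", "chr1", "-", [(10, 13), (20, 22)])
        assert list(transcript_coords(rec)) == [21, 20, 12, 11, 10]
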