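"""Domain types, translation, intron derivation, and file round-trips."""

import pytest

from genesift import io as gio
from genesift.models import (
    Contig,
    Genome,
    ModelValidationError,
    ScoringParams,
    StructuralError,
    derive_introns,
    translate_cds,
)
from genesift.synthetic import FixtureConfig, generate_fixture

from conftest import make_genome, make_model


class TestContig:
    def test_rejects_empty_and_bad_alphabet(self):
        with pytest.raises(ValueError):
            Contig("c", "")
        with pytest.raises(ValueError):
            Contig("c", "ACGU")

    def test_uppercases(self):
        assert Contig("c", "acgtn").sequence == "ACGTN"


class TestGeneModel:
    def test_exon_classes_two_exon_plus(self):
        m = make_model([(1, 10), (61, 90)])
        assert [e.exon_class for e in m.exons] == ["initial", "terminal"]

    def test_exon_classes_minus_strand_reversed(self):
        m = make_model([(1, 10), (61, 90)], strand="-")
        assert [e.exon_class for e in m.exons] == ["terminal", "initial"]
        assert m.exons_tx_order()[0].start == 61

    def test_single_exon_class(self):
        assert make_model([(5, 25)]).exons[0].exon_class == "single"

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ModelValidationError):
            make_model([(1, 50), (40, 90)])

    def test_cds_intervals_partition_transcript(self):
        m = make_model([(1, 9), (20, 28), (40, 45)], strand="-")
        spans = m.exon_cds_intervals()
        assert sorted(s for s, _ in spans)[0] == 1
        assert sum(e - s + 1 for s, e in spans) == m.cds_length


class TestTranslate:
    def test_minimal_orf(self):
        genome = make_genome("ATGGCATAA")
        res = translate_cds(make_model([(1, 9)]), genome)
        assert res.ok and res.protein == "MA"

    def test_internal_stop(self):
        genome = make_genome("ATGTAAGCATAA")
        assert translate_cds(make_model([(1, 12)]), genome).failure == "internal_stop"

    @pytest.mark.parametrize(
        "seq,failure",
        [
            ("GCAGCATAA", "no_start"),
            ("ATGGCAGCA", "no_stop"),
            ("ATGGCATA", "frame"),
            ("ATG" + "N" * 9 + "TAA", "too_many_N"),
        ],
    )
    def test_failure_reasons(self, seq, failure):
        genome = make_genome(seq)
        assert translate_cds(make_model([(1, len(seq))]), genome).failure == failure

    def test_n_count_boundary_eight_allowed(self):
        # 8 Ns pass the gate; translation proceeds with X residues
        seq = "ATG" + "AAN" * 8 + "GCA" + "TAA"
        genome = make_genome(seq)
        res = translate_cds(make_model([(1, len(seq))]), genome)
        assert res.ok

    def test_protein_length_identity(self, two_exon_gene):
        genome, model, _ = two_exon_gene
        res = translate_cds(model, genome)
        assert len(res.protein) == model.cds_length // 3 - 1

    def test_minus_strand_translation(self):
        # revcomp of ATGGCATAA placed on the minus strand
        from genesift.models import reverse_complement

        genome = make_genome("CC" + reverse_complement("ATGGCATAA") + "CC")
        res = translate_cds(make_model([(3, 11)], strand="-"), genome)
        assert res.ok and res.protein == "MA"


class TestDeriveIntrons:
    def test_plus_strand_donor_acceptor(self):
        seq = "A" * 10 + "GT" + "C" * 46 + "AG" + "G" * 30
        genome = make_genome(seq)
        introns = derive_introns(make_model([(1, 10), (61, 90)]), genome)
        assert len(introns) == 1
        i = introns[0]
        assert (i.start, i.end, i.donor, i.acceptor) == (11, 60, "GT", "AG")

    def test_single_exon_no_introns(self):
        genome = make_genome("A" * 50)
        assert derive_introns(make_model([(1, 30)]), genome) == []

    def test_minus_strand_reverse_complement(self):
        # genomic gap CT...AC reads GT...AG on the coding (minus) strand
        seq = "A" * 10 + "CT" + "G" * 46 + "AC" + "T" * 30
        genome = make_genome(seq)
        introns = derive_introns(make_model([(1, 10), (61, 90)], strand="-"), genome)
        assert introns[0].donor == "GT" and introns[0].acceptor == "AG"

    def test_abutting_exons_structural_error(self):
        genome = make_genome("A" * 100)
        with pytest.raises(StructuralError, match="Bad intron structure"):
            derive_introns(make_model([(1, 10), (11, 40)]), genome)

    def test_introns_complement_exons_within_span(self):
        genome = make_genome("A" * 10 + "GTAAAAAAAAAAAG" + "C" * 20 + "GTCCCCCCCCAG" + "G" * 40)
        model = make_model([(1, 10), (25, 44), (57, 80)])
        introns = derive_introns(model, genome)
        covered = set()
        for e in model.exons:
            covered.update(range(e.start, e.end + 1))
        for i in introns:
            covered.update(range(i.start, i.end + 1))
        assert covered == set(range(model.span_start, model.span_end + 1))


class TestGFF:
    def test_parent_grouping_and_classes(self, tmp_path):
        gff = tmp_path / "m.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tCDS\t1\t10\t.\t+\t0\tID=t1.c1;Parent=t1\n"
            "chr1\tsrc\tCDS\t61\t90\t.\t+\t0\tID=t1.c2;Parent=t1\n"
            "chr1\tsrc\tCDS\t200\t250\t.\t-\t0\tID=t2.c1;Parent=t2\n"
        )
        models = {m.id: m for m in gio.read_gff_models(gff)}
        assert set(models) == {"t1", "t2"}
        assert [e.exon_class for e in models["t1"].exons] == ["initial", "terminal"]
        assert models["t2"].exons[0].exon_class == "single"

    def test_mixed_strand_is_model_error(self, tmp_path):
        gff = tmp_path / "bad.gff3"
        gff.write_text(
            "chr1\tsrc\tCDS\t1\t10\t.\t+\t0\tParent=t1\n"
            "chr1\tsrc\tCDS\t61\t90\t.\t-\t0\tParent=t1\n"
        )
        with pytest.raises(ModelValidationError, match="strand"):
            gio.read_gff_models(gff)

    def test_malformed_line_names_line_number(self, tmp_path):
        gff = tmp_path / "trunc.gff3"
        gff.write_text("chr1\tsrc\tCDS\t1\t10\t.\t+\t0\n")
        with pytest.raises(gio.GFFParseError, match=":1:"):
            gio.read_gff_models(gff)

    def test_round_trip(self, tmp_path, small_bundle):
        path = tmp_path / "rt.gff3"
        gio.write_gff_models(small_bundle.candidates, path)
        back = gio.read_gff_models(path)
        orig = {m.id: m.cds_signature() for m in small_bundle.candidates}
        got = {m.id: m.cds_signature() for m in back}
        assert got == orig

    def test_unknown_contig_quarantined(self, small_bundle):
        stray = make_model([(1, 9)], contig_id="ghost", model_id="stray")
        valid, rejected = gio.partition_by_contig(
            list(small_bundle.truth) + [stray], small_bundle.genome
        )
        assert [m.id for m in rejected] == ["stray"]
        assert len(valid) == len(small_bundle.truth)


class TestTables:
    def test_bedgraph_round_trip(self, tmp_path, small_bundle):
        path = tmp_path / "cov.bedgraph"
        gio.write_bedgraph(small_bundle.coverage, path)
        back = gio.read_bedgraph(path, small_bundle.genome)
        for cid in small_bundle.coverage.contig_ids:
            assert (back.array(cid) == small_bundle.coverage.array(cid)).all()

    def test_junction_and_blast_round_trip(self, tmp_path, small_bundle):
        jpath = tmp_path / "j.tsv"
        gio.write_junctions(small_bundle.junctions, jpath)
        assert sorted(
            (j.contig_id, j.start, j.end, j.spliced_reads) for j in gio.read_junctions(jpath)
        ) == sorted(
            (j.contig_id, j.start, j.end, j.spliced_reads) for j in small_bundle.junctions
        )
        hpath = tmp_path / "h.tsv"
        gio.write_blast_tab(small_bundle.hits, hpath)
        back = [h for hs in gio.read_blast_tab(hpath).values() for h in hs]
        assert len(back) == len(small_bundle.hits)
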