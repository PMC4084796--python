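"""The scoring flow: gates, boundary factors, transcript score, statuses."""

import numpy as np
import pytest

from genesift.evidence import CoverageTrack, RnaSeqEvidence, SpliceJunction
from genesift.homology import HomologyHit
from genesift.models import Intron, ScoringParams
from genesift.scoring import (
    boundary_scores,
    classify_model,
    score_exon,
    score_intron,
    score_transcript,
)

from conftest import make_genome, make_model, uniform_coverage


def intron(donor, acceptor, length):
    return Intron("chr1", 101, 100 + length, donor, acceptor)


def evidence_for(genome, exon_intervals, junctions, depth=50.0):
    cov = uniform_coverage(genome, [("chr1", s, e) for s, e in exon_intervals], depth)
    return RnaSeqEvidence.build(cov, junctions)


def perfect_hit(model_id, aa):
    return HomologyHit(model_id, "sp|X", aa, aa, aa, 1, aa, evalue=1e-30, bitscore=200)


class TestIntronScore:
    @pytest.mark.parametrize(
        "donor,acceptor,length,expected",
        [
            ("GT", "AG", 60, 1),
            ("GC", "AG", 60, 1),
            ("AT", "AC", 60, 1),
            ("CT", "AC", 60, 0),  # unconventional pair
            ("GC", "AG", 9, 0),   # below minimum length
            ("GT", "AG", 10, 1),  # at minimum
            ("GT", "AG", 2000, 1),  # at maximum
            ("GT", "AG", 2001, 0),  # above maximum
        ],
    )
    def test_gate(self, donor, acceptor, length, expected, params):
        assert score_intron(intron(donor, acceptor, length), params) == expected


class TestBoundaryScores:
    def _model(self):
        return make_model([(1, 100), (201, 300), (401, 500)])

    def test_matched_boundaries_rewarded(self, params):
        m = self._model()
        js = [
            SpliceJunction("chr1", 101, 200, 10, rt=0.0),
            SpliceJunction("chr1", 301, 400, 10, rt=0.0),
        ]
        assert boundary_scores(m.exons[1], js, m, params) == (2.0, 1.0, 2.0)
        # outermost boundaries are exempt
        assert boundary_scores(m.exons[0], js, m, params)[0] == 1.0
        assert boundary_scores(m.exons[2], js, m, params)[2] == 1.0

    def test_no_junction_in_window_zeroes(self, params):
        m = self._model()
        r_left, _, _ = boundary_scores(m.exons[1], [], m, params)
        assert r_left == 0.0

    def test_missed_junction_penalised(self, params):
        m = self._model()
        js = [SpliceJunction("chr1", 101, 195, 10, rt=0.3)]  # ends 5 bp early
        r_left, _, _ = boundary_scores(m.exons[1], js, m, params)
        assert r_left == pytest.approx(0.3)

    def test_contained_junction_penalises_mid(self, params):
        m = self._model()
        js = [SpliceJunction("chr1", 220, 260, 10, rt=0.3)]
        _, r_mid, _ = boundary_scores(m.exons[1], js, m, params)
        assert r_mid == pytest.approx(0.3)

    def test_nearest_tie_prefers_more_spliced_reads(self, params):
        m = self._model()
        js = [
            SpliceJunction("chr1", 101, 195, 5, rt=0.2),   # 6 bp off
            SpliceJunction("chr1", 101, 205, 50, rt=0.4),  # 6 bp off, more reads
        ]
        r_left, _, _ = boundary_scores(m.exons[1], js, m, params)
        assert r_left == pytest.approx(0.4)


class TestScoreExon:
    def test_products(self):
        assert score_exon(1.0, (2.0, 1.0, 2.0)) == 4.0
        assert score_exon(4 / 3, (1.0, 1.0, 1.0)) == pytest.approx(4 / 3)
        assert score_exon(1.5, (2.0, 0.0, 2.0)) == 0.0


class TestScoreTranscript:
    def test_hand_traced_two_exon_score_is_four(self, two_exon_gene, params):
        genome, model, evidence = two_exon_gene
        b = score_transcript(model, genome, evidence, params=params)
        assert b.path == "detailed"
        assert b.intron_scores == (1,)
        assert b.boundary_scores == ((1.0, 1.0, 2.0), (2.0, 1.0, 1.0))
        assert b.score == pytest.approx(4.0)
        assert b.matches_rnaseq

    def _monoexonic(self, n_aa, tmp_depth=50.0):
        seq = "ATG" + "GCA" * (n_aa - 1) + "TAA"
        genome = make_genome(seq + "A" * 20)
        model = make_model([(1, len(seq))])
        evidence = evidence_for(genome, [(1, len(seq))], [], depth=tmp_depth)
        return genome, model, evidence

    def test_protein_length_ladder(self, params):
        # 149 aa, no intron, no hits: short_protein
        genome, model, evidence = self._monoexonic(149)
        b = score_transcript(model, genome, evidence, params=params)
        assert b.score == 0.0 and b.failure == "short_protein"
        # 149 aa with a BLASTp hit: rescued, proceeds to detailed path
        b = score_transcript(
            model, genome, evidence, hits=[perfect_hit(model.id, 149)], params=params
        )
        assert b.failure is None and b.path == "detailed"
        # single exon, all boundary factors 1: score = H_e; the hit spans
        # the protein (447 of 450 CDS bases; the stop codon is unaligned)
        assert b.score == pytest.approx(1 + (1 / 3) * (447 / 450))
        # 150 aa passes outright
        genome, model, evidence = self._monoexonic(150)
        b = score_transcript(model, genome, evidence, params=params)
        assert b.failure is None

    def test_rescued_model_still_needs_fifty_aa(self, params):
        # 49-aa protein with an intron: rescued by the intron but below
        # the hard floor, so still short_protein
        exon1 = "ATG" + "GCA" * 30
        intr = "GT" + "C" * 36 + "AG"
        exon2 = "GCA" * 18 + "TAA"
        genome = make_genome(exon1 + intr + exon2)
        e1 = (1, len(exon1))
        e2 = (len(exon1) + len(intr) + 1, len(exon1) + len(intr) + len(exon2))
        model = make_model([e1, e2])
        evidence = evidence_for(genome, [e1, e2], [])
        b = score_transcript(model, genome, evidence, params=params)
        assert b.failure == "short_protein"

    def test_internal_stop_scores_zero(self, params):
        seq = "ATG" + "TAA" + "GCA" * 160 + "TAA"
        genome = make_genome(seq)
        model = make_model([(1, len(seq))])
        evidence = evidence_for(genome, [(1, len(seq))], [])
        b = score_transcript(model, genome, evidence, params=params)
        assert b.score == 0.0 and b.failure == "internal_stop"
        assert classify_model(b, params) == "cannot_translate"

    def test_n_count_gate_boundary(self, params):
        for n_count, ok in [(8, True), (9, False)]:
            codons = ["ATG"] + ["GCA"] * 160
            seq = "".join(codons) + "AAN" * (n_count // 2) + ("NAA" if n_count % 2 else "") + "TAA"
            # build exactly n_count Ns in-frame
            seq = "ATG" + "GCA" * 160 + ("AAN" * n_count) + "TAA"
            genome = make_genome(seq)
            model = make_model([(1, len(seq))])
            evidence = evidence_for(genome, [(1, len(seq))], [])
            b = score_transcript(model, genome, evidence, params=params)
            if ok:
                assert b.failure != "too_many_N"
            else:
                assert b.failure == "too_many_N"
                assert classify_model(b, params) == "cannot_translate"

    def test_bad_intron_zeroes(self, two_exon_gene, params):
        genome, model, evidence = two_exon_gene
        short = ScoringParams(min_intron=100)  # the 60-bp intron now fails
        b = score_transcript(model, genome, evidence, params=short)
        assert b.score == 0.0 and b.failure == "bad_intron_structure"
        assert classify_model(b, short) == "bad_intron_structure"

    def test_low_coverage_bypass(self, two_exon_gene, params):
        genome, model, _ = two_exon_gene
        evidence = evidence_for(
            genome, [(e.start, e.end) for e in model.exons], [], depth=5.0
        )
        b = score_transcript(model, genome, evidence, params=params)
        assert b.path == "low_coverage" and b.low_coverage
        assert b.score == pytest.approx(0.6)  # penalty * 1 * (H_e = 1)^2
        assert classify_model(b, params) == "accepted"

    def test_bypass_includes_homology_baseline(self, two_exon_gene, params):
        genome, model, _ = two_exon_gene
        evidence = evidence_for(
            genome, [(e.start, e.end) for e in model.exons], [], depth=5.0
        )
        b = score_transcript(
            model, genome, evidence, hits=[perfect_hit(model.id, 181)], params=params
        )
        assert b.score > 0.6  # each H_e > 1 with a perfect hit

    def test_coverage_gap_rejected(self, two_exon_gene, params):
        genome, model, _ = two_exon_gene
        cov = uniform_coverage(
            genome, [(model.contig_id, e.start, e.end) for e in model.exons], 50.0
        )
        cov.array("chr1")[10:30] = 0.0  # 20-base exonic gap
        evidence = RnaSeqEvidence.build(cov, [SpliceJunction("chr1", 304, 363, 20)])
        b = score_transcript(model, genome, evidence, params=params)
        assert b.score == 0.0 and b.failure == "coverage_error"
        assert classify_model(b, params) == "coverage_error"

    def test_detailed_below_threshold_is_intron_error(self, two_exon_gene, params):
        genome, model, _ = two_exon_gene
        # junction shifted 6 bp: both flanks become penalty(rt=0.4)
        cov = uniform_coverage(
            genome, [(model.contig_id, e.start, e.end) for e in model.exons], 50.0
        )
        evidence = RnaSeqEvidence.build(
            cov, [SpliceJunction("chr1", 310, 369, 20, rt=0.4)]
        )
        b = score_transcript(model, genome, evidence, params=params)
        assert 0.0 < b.score < params.match_threshold
        assert not b.matches_rnaseq
        assert classify_model(b, params) == "intron_error"

    def test_threshold_inclusive(self, params):
        from genesift.scoring import ScoreBreakdown

        ok = ScoreBreakdown("m", 0.6, "detailed", matches_rnaseq=True)
        low = ScoreBreakdown("m", 0.4, "detailed", matches_rnaseq=False)
        assert classify_model(ok, params) == "accepted"
        assert classify_model(low, params) == "intron_error"


class TestMonotonicity:
    def test_matched_junction_rt_never_helps(self, two_exon_gene, params):
        genome, model, _ = two_exon_gene
        cov = uniform_coverage(
            genome, [(model.contig_id, e.start, e.end) for e in model.exons], 50.0
        )
        scores = []
        for rt in np.arange(0.0, 0.91, 0.1):
            ev = RnaSeqEvidence.build(
                cov, [SpliceJunction("chr1", 304, 363, 20, rt=float(rt))]
            )
            scores.append(score_transcript(model, genome, ev, params=params).score)
        assert all(a >= b - 1e-12 for a, b in zip(scores, scores[1:]))

    def test_missed_junction_rt_never_hurts(self, two_exon_gene, params):
        genome, model, _ = two_exon_gene
        cov = uniform_coverage(
            genome, [(model.contig_id, e.start, e.end) for e in model.exons], 50.0
        )
        scores = []
        for rt in np.arange(0.0, 0.91, 0.1):
            ev = RnaSeqEvidence.build(
                cov, [SpliceJunction("chr1", 310, 369, 20, rt=float(rt))]
            )
            scores.append(score_transcript(model, genome, ev, params=params).score)
        assert all(a <= b + 1e-12 for a, b in zip(scores, scores[1:]))
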