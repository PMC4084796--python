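"""Shared fixtures: hand-built micro-genes and a mid-sized synthetic bundle."""

from __future__ import annotations

import numpy as np
import pytest

from genesift.evidence import CoverageTrack, RnaSeqEvidence, SpliceJunction
from genesift.models import Contig, Exon, GeneModel, Genome, ScoringParams
from genesift.synthetic import FixtureConfig, generate_fixture


def make_genome(seq: str, contig_id: str = "chr1") -> Genome:
    return Genome([Contig(contig_id, seq)])


def make_model(
    exon_coords,
    strand: str = "+",
    contig_id: str = "chr1",
    model_id: str = "m1",
    source: str = "test",
    score: float | None = None,
) -> GeneModel:
    m = GeneModel(
        id=model_id,
        source=source,
        contig_id=contig_id,
        strand=strand,
        exons=tuple(Exon(contig_id, s, e) for s, e in exon_coords),
    )
    m.score = score
    return m


def uniform_coverage(genome: Genome, intervals, depth: float) -> CoverageTrack:
    """Coverage with ``depth`` over (contig, start, end) intervals, zero elsewhere."""
    cov = CoverageTrack.zeros(genome)
    for contig_id, start, end in intervals:
        cov.array(contig_id)[start - 1 : end] = depth
    return cov


@pytest.fixture
def params() -> ScoringParams:
    return ScoringParams()


@pytest.fixture
def two_exon_gene():
    """A clean two-exon gene: 181-aa protein, one GT-AG intron with a
    matching clean junction (rt = 0), uniform exonic depth 50.

    Exon1 = chr1:1-303 (ATG + 100 GCA codons), intron chr1:304-363
    (GT..AG, 60 bp), exon2 = chr1:364-606 (80 GCA codons + TAA).
    """
    exon1 = "ATG" + "GCA" * 100
    intron = "GT" + "C" * 56 + "AG"
    exon2 = "GCA" * 80 + "TAA"
    genome = make_genome(exon1 + intron + exon2 + "A" * 50)
    model = make_model([(1, 303), (364, 606)])
    coverage = uniform_coverage(genome, [("chr1", 1, 303), ("chr1", 364, 606)], 50.0)
    junction = SpliceJunction("chr1", 304, 363, spliced_reads=20)
    evidence = RnaSeqEvidence.build(coverage, [junction])
    return genome, model, evidence


@pytest.fixture(scope="session")
def small_bundle():
    """A 12-gene corrupted fixture used by several suites (read-only)."""
    return generate_fixture(FixtureConfig(seed=11, n_genes=12))


def bundle_evidence(bundle) -> RnaSeqEvidence:
    return RnaSeqEvidence.build(bundle.coverage, bundle.junctions)


def bundle_hits(bundle) -> dict:
    hits: dict[str, list] = {}
    for h in bundle.hits:
        hits.setdefault(h.model_id, []).append(h)
    return hits
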