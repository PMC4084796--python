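"""Protein-homology scores from BLASTp tabular hits.

Each significant hit contributes

    H_it = norm * (Matches + Similarities) / (2 * Len)

where Matches/Similarities/Len are the identical-residue count,
positive-scoring-residue count and alignment length reported by BLASTp,
and ``norm`` is 1/max_homologs under the default ``printed``
normalisation (so a perfect hit contributes 1/max_homologs and a model
backed by max_homologs perfect hits reaches the ceiling of 1).  The hit
score is divided among the exons of the model in proportion to their
overlap with the aligned query span:

    H_e = 1 + sum_i H_it * len(e  ^ B_i) / len(e)

so an exon with no homology support keeps the neutral score 1.
"""

from __future__ import annotations

from dataclasses import dataclass

from .models import GeneModel, ScoringParams, DEFAULT_PARAMS

__all__ = ["HomologyHit", "hit_score", "exon_homology_score", "select_hits",
           "model_homology_scores"]


@dataclass(frozen=True)
class HomologyHit:
    """One BLASTp alignment of a model's predicted protein.

    ``qstart_aa``/``qend_aa`` are 1-based query protein coordinates; the
    corresponding CDS-coordinate span is ``cds_span`` (1-based inclusive
    positions along the spliced transcript).
    """

    model_id: str
    subject_id: str
    matches: int
    similarities: int
    aln_len: int
    qstart_aa: int
    qend_aa: int
    evalue: float = 0.0
    bitscore: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.matches <= self.similarities <= self.aln_len):
            raise ValueError(
                f"hit {self.model_id}/{self.subject_id}: require "
                f"0 <= matches ({self.matches}) <= similarities "
                f"({self.similarities}) <= aln_len ({self.aln_len})"
            )
        if self.qstart_aa < 1 or self.qend_aa < self.qstart_aa:
            raise ValueError("bad query coordinates")

    @property
    def cds_span(self) -> tuple[int, int]:
        """Aligned query span in CDS coordinates (1-based inclusive)."""
        return (self.qstart_aa - 1) * 3 + 1, self.qend_aa * 3


def hit_score(hit: HomologyHit, params: ScoringParams = DEFAULT_PARAMS) -> float:
    """Per-hit homology score H_it; in [0, norm]."""
    if hit.aln_len == 0:
        raise ValueError("alignment length must be > 0")
    norm = 1.0 / params.max_homologs if params.homology_norm == "printed" else 1.0
    return norm * (hit.matches + hit.similarities) / (2.0 * hit.aln_len)


def select_hits(
    hits: list[HomologyHit], params: ScoringParams = DEFAULT_PARAMS
) -> list[HomologyHit]:
    """Significant hits, ranked by bit score (ties by subject id), capped at max_homologs."""
    kept = [h for h in hits if h.evalue <= params.evalue_cutoff]
    kept.sort(key=lambda h: (-h.bitscore, h.subject_id))
    return kept[: params.max_homologs]


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def exon_homology_score(
    exon_cds_span: tuple[int, int],
    hits: list[HomologyHit],
    params: ScoringParams = DEFAULT_PARAMS,
) -> float:
    """H_e for one exon, given its CDS-coordinate interval and the retained hits.

    ``hits`` must already be filtered/capped by :func:`select_hits`.
    H_e >= 1 always; with the printed normalisation H_e <= 2.
    """
    exon_len = exon_cds_span[1] - exon_cds_span[0] + 1
    total = 0.0
    for hit in hits:
        total += hit_score(hit, params) * _overlap(exon_cds_span, hit.cds_span) / exon_len
    return 1.0 + total


def model_homology_scores(
    model: GeneModel,
    hits: list[HomologyHit],
    params: ScoringParams = DEFAULT_PARAMS,
) -> list[float]:
    """H_e per exon (aligned with ``model.exons``, genomic order)."""
    retained = select_hits(hits, params)
    return [
        exon_homology_score(span, retained, params)
        for span in model.exon_cds_intervals()
    ]
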