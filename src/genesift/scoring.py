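"""Model scoring: structural gates, coverage gates, exon/boundary scores.

The flow for one candidate model is:

1. translate the spliced CDS; any invalid coding sequence (no ATG, no
   stop, internal stop, frame, too many Ns) scores 0;
2. protein-length gate: proteins shorter than ``min_protein_aa`` score 0
   unless the model contains an intron or has at least one significant
   BLASTp hit, and even rescued models score 0 below
   ``rescue_min_protein_aa``;
3. intron gate: any intron with an unconventional donor-acceptor pair or
   out-of-range length zeroes the model;
4. low-coverage bypass: models whose median exonic depth is below
   ``low_median_cutoff`` cannot be checked against coverage continuity
   or junction usage, so they receive
   ``low_coverage_penalty * prod(I_i) * prod(H_e)`` without detailed
   exon scoring;
5. continuity gate: a low-coverage run longer than ``max_low_run_len``
   or an exon whose mean depth leaves ``exon_depth_range`` x the
   transcript median zeroes the model;
6. detailed scoring:  V_t = prod_i I_i * prod_e V_x(e)  with
   V_x(e) = H_e * R_left(e) * R_mid(e) * R_right(e), where the boundary
   factors reward exon ends that coincide with observed splice
   junctions, penalise ends that miss the nearest junction, penalise
   exons that fully contain (i.e. read through) a junction, and zero an
   exon end whose search window contains no junction at all;
7. the model *matches the RNA-Seq data* iff V_t >= ``match_threshold``.

Boundary-factor orientation: junctions are strand-agnostic, so the
left/right factors are evaluated in genomic orientation and the
"initial/terminal exon" exemptions apply to the genomically outermost
boundaries of the transcript span (for a plus-strand model these are
exactly the initial and terminal exons).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .evidence import (
    RnaSeqEvidence,
    SpliceJunction,
    exon_depth_in_range,
    find_low_coverage_runs,
    penalty,
    reward,
    transcript_depth_stats,
)
from .homology import HomologyHit, model_homology_scores, select_hits
from .models import (
    DEFAULT_PARAMS,
    Exon,
    GeneModel,
    Genome,
    Intron,
    ScoringParams,
    StructuralError,
    derive_introns,
    translate_cds,
)

__all__ = [
    "ScoreBreakdown",
    "IMPERFECT_STATUSES",
    "score_intron",
    "boundary_scores",
    "score_exon",
    "score_transcript",
    "classify_model",
]

IMPERFECT_STATUSES = (
    "cannot_translate",
    "short_protein",
    "bad_intron_structure",
    "coverage_error",
    "intron_error",
)

_TRANSLATION_FAILURES = frozenset(
    {"no_start", "no_stop", "internal_stop", "frame", "too_many_N"}
)


@dataclass
class ScoreBreakdown:
    """Per-model audit of every score factor."""

    model_id: str
    score: float
    path: str  # gate | low_coverage | detailed
    matches_rnaseq: bool
    low_coverage: bool = False
    failure: str | None = None
    protein_len: int | None = None
    intron_scores: tuple[int, ...] = ()
    homology_scores: tuple[float, ...] = ()
    boundary_scores: tuple[tuple[float, float, float], ...] = ()
    exon_scores: tuple[float, ...] = ()


def score_intron(intron: Intron, params: ScoringParams = DEFAULT_PARAMS) -> int:
    """1 iff the donor-acceptor pair is acceptable and the length is in range."""
    if intron.donor_acceptor not in params.acceptable_donor_acceptor:
        return 0
    if not (params.min_intron <= len(intron) <= params.max_intron):
        return 0
    return 1


def _nearest(
    candidates: list[SpliceJunction], target: int, endpoint: str
) -> SpliceJunction:
    """Junction whose matched endpoint is closest to ``target``.

    Ties go to the junction with more spliced reads, then the leftmost.
    """
    def key(j: SpliceJunction):
        pos = j.end + 1 if endpoint == "end" else j.start - 1
        return (abs(pos - target), -j.spliced_reads, j.start)

    return min(candidates, key=key)


def boundary_scores(
    exon: Exon,
    junctions: list[SpliceJunction],
    model: GeneModel,
    params: ScoringParams = DEFAULT_PARAMS,
) -> tuple[float, float, float]:
    """(R_left, R_mid, R_right) for one exon against the observed junctions.

    ``junctions`` must belong to the model's contig and carry rt values.
    """
    form = params.boundary_score_form
    span_start, span_end = model.span_start, model.span_end

    # R_left: genomic-left boundary.  Exempt for the outermost exon.
    if exon.start == span_start:
        r_left = 1.0
    else:
        window = [j for j in junctions if span_start <= j.end <= exon.end]
        matched = [j for j in window if j.end + 1 == exon.start]
        if matched:
            r_left = reward(_nearest(matched, exon.start, "end").rt, form)
        elif window:
            r_left = penalty(_nearest(window, exon.start, "end").rt, form)
        else:
            r_left = 0.0

    # R_right: genomic-right boundary.
    if exon.end == span_end:
        r_right = 1.0
    else:
        window = [j for j in junctions if exon.start <= j.start <= span_end]
        matched = [j for j in window if j.start - 1 == exon.end]
        if matched:
            r_right = reward(_nearest(matched, exon.end, "start").rt, form)
        elif window:
            r_right = penalty(_nearest(window, exon.end, "start").rt, form)
        else:
            r_right = 0.0

    # R_mid: junctions completely contained in the exon (read-through).
    contained = [j for j in junctions if exon.start <= j.start and j.end <= exon.end]
    r_mid = 1.0
    for j in contained:
        r_mid *= penalty(j.rt, form)

    return r_left, r_mid, r_right


def score_exon(h_e: float, boundary: tuple[float, float, float]) -> float:
    """V_x(e) = H_e * R_left * R_mid * R_right."""
    r_left, r_mid, r_right = boundary
    return h_e * r_left * r_mid * r_right


def _gate(model_id: str, failure: str, protein_len: int | None = None,
          intron_scores: tuple[int, ...] = ()) -> ScoreBreakdown:
    return ScoreBreakdown(
        model_id=model_id, score=0.0, path="gate", matches_rnaseq=False,
        failure=failure, protein_len=protein_len, intron_scores=intron_scores,
    )


def score_transcript(
    model: GeneModel,
    genome: Genome,
    evidence: RnaSeqEvidence,
    hits: list[HomologyHit] | None = None,
    params: ScoringParams = DEFAULT_PARAMS,
) -> ScoreBreakdown:
    """Run the full scoring flow for one candidate model."""
    hits = hits or []
    if model.contig_id not in genome:
        raise StructuralError(f"model {model.id}: contig {model.contig_id!r} not in genome")
    if model.contig_id not in evidence.coverage:
        raise StructuralError(
            f"model {model.id}: no coverage for contig {model.contig_id!r}"
        )

    # (1) translation gate
    translation = translate_cds(model, genome, params)
    if not translation.ok:
        return _gate(model.id, translation.failure)
    protein_len = len(translation.protein)

    # intron derivation (abutting exons are a structural failure)
    try:
        introns = derive_introns(model, genome)
    except StructuralError:
        return _gate(model.id, "bad_intron_structure", protein_len)

    # (2) protein-length gate with intron/homology rescue
    if protein_len < params.min_protein_aa:
        rescued = bool(introns) or bool(select_hits(hits, params))
        if not rescued or protein_len < params.rescue_min_protein_aa:
            return _gate(model.id, "short_protein", protein_len)

    # (3) intron gate
    intron_scores = tuple(score_intron(i, params) for i in introns)
    if any(s == 0 for s in intron_scores):
        return _gate(model.id, "bad_intron_structure", protein_len, intron_scores)

    stats = transcript_depth_stats(model, evidence.coverage)
    homology = tuple(model_homology_scores(model, hits, params))

    # (4) low-coverage bypass: homology and intron scores only
    if stats.median < params.low_median_cutoff:
        score = (
            params.low_coverage_penalty * math.prod(intron_scores) * math.prod(homology)
        )
        return ScoreBreakdown(
            model_id=model.id,
            score=score,
            path="low_coverage",
            matches_rnaseq=score >= params.match_threshold,
            low_coverage=True,
            protein_len=protein_len,
            intron_scores=intron_scores,
            homology_scores=homology,
        )

    # (5) coverage continuity / depth-range gate
    runs = find_low_coverage_runs(model, evidence.coverage, stats, params)
    depth_ok = all(
        exon_depth_in_range(m, stats.median, params) for m in stats.per_exon_mean
    )
    if runs or not depth_ok:
        return _gate(model.id, "coverage_error", protein_len, intron_scores)

    # (6) detailed exon scoring
    junctions = evidence.junctions(model.contig_id)
    boundaries = tuple(
        boundary_scores(e, junctions, model, params) for e in model.exons
    )
    exon_scores = tuple(
        score_exon(h, b) for h, b in zip(homology, boundaries)
    )
    score = math.prod(intron_scores) * math.prod(exon_scores)
    return ScoreBreakdown(
        model_id=model.id,
        score=score,
        path="detailed",
        matches_rnaseq=score >= params.match_threshold,
        protein_len=protein_len,
        intron_scores=intron_scores,
        homology_scores=homology,
        boundary_scores=boundaries,
        exon_scores=exon_scores,
    )


def classify_model(
    breakdown: ScoreBreakdown, params: ScoringParams = DEFAULT_PARAMS
) -> str:
    """Accepted/imperfect status for a representative model.

    Returns ``"accepted"`` or exactly one diagnostic status, chosen by
    gate order: cannot_translate > short_protein > bad_intron_structure
    > coverage_error > intron_error.
    """
    if breakdown.failure in _TRANSLATION_FAILURES:
        return "cannot_translate"
    if breakdown.failure == "short_protein":
        return "short_protein"
    if breakdown.failure == "bad_intron_structure":
        return "bad_intron_structure"
    if breakdown.failure == "coverage_error":
        return "coverage_error"
    if breakdown.low_coverage:
        return "accepted" if breakdown.score > 0 else "intron_error"
    return "accepted" if breakdown.matches_rnaseq else "intron_error"
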