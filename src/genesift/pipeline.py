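"""End-to-end orchestration: score -> select -> classify.

The main entry point is :func:`run_pipeline`, which scores every
candidate, preselects the redundant pooled source down to ~1-2 models
per locus, runs chain selection over all sources together, resolves
remaining overlaps with a seeded final pass, and classifies each
representative as accepted or imperfect with a diagnostic status.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .evidence import RnaSeqEvidence
from .homology import HomologyHit
from .models import DEFAULT_PARAMS, GeneModel, Genome, ScoringParams
from .scoring import IMPERFECT_STATUSES, ScoreBreakdown, classify_model, score_transcript
from .selection import group_overlapping, resolve_representatives, select_chain
from . import io as gio

__all__ = ["PipelineResult", "score_all", "run_pipeline", "write_outputs"]

POOLED_SOURCE = "pooled"


@dataclass
class PipelineResult:
    breakdowns: dict[str, ScoreBreakdown]
    representatives: list[GeneModel]
    accepted: list[GeneModel]
    imperfect: list[GeneModel]
    rejects: list[GeneModel]
    log: dict


def score_all(
    models: Iterable[GeneModel],
    genome: Genome,
    evidence: RnaSeqEvidence,
    hits_by_model: dict[str, list[HomologyHit]] | None = None,
    params: ScoringParams = DEFAULT_PARAMS,
) -> dict[str, ScoreBreakdown]:
    """Score every model, attaching ``model.score`` and state ``scored``."""
    hits_by_model = hits_by_model or {}
    breakdowns: dict[str, ScoreBreakdown] = {}
    for m in models:
        b = score_transcript(m, genome, evidence, hits_by_model.get(m.id), params)
        m.score = b.score
        m.state = "scored"
        breakdowns[m.id] = b
    return breakdowns


def run_pipeline(
    genome: Genome,
    candidates: Iterable[GeneModel],
    evidence: RnaSeqEvidence,
    hits_by_model: dict[str, list[HomologyHit]] | None = None,
    params: ScoringParams = DEFAULT_PARAMS,
    seed: int = 0,
) -> PipelineResult:
    candidates = list(candidates)
    valid, rejects = gio.partition_by_contig(candidates, genome)
    breakdowns = score_all(valid, genome, evidence, hits_by_model, params)

    pooled = [m for m in valid if m.source == POOLED_SOURCE]
    others = [m for m in valid if m.source != POOLED_SOURCE]
    preselected = []
    for group in group_overlapping(pooled):
        preselected.extend(select_chain(group, params))

    survivors: list[GeneModel] = []
    for group in group_overlapping(others + preselected):
        survivors.extend(select_chain(group, params))
    representatives = resolve_representatives(survivors, params, rng_seed=seed)

    accepted, imperfect = [], []
    for m in representatives:
        status = classify_model(breakdowns[m.id], params)
        m.status = status
        if status == "accepted":
            m.state = "accepted"
            accepted.append(m)
        else:
            m.state = "imperfect"
            imperfect.append(m)

    status_counts = {s: 0 for s in IMPERFECT_STATUSES}
    for m in imperfect:
        status_counts[m.status] += 1
    log = {
        "seed": seed,
        "params": _params_dict(params),
        "counts": {
            "candidates": len(candidates),
            "rejected_unknown_contig": len(rejects),
            "scored": len(breakdowns),
            "pooled_preselected": len(preselected),
            "representative": len(representatives),
            "accepted": len(accepted),
            "imperfect": len(imperfect),
            "imperfect_by_status": status_counts,
        },
    }
    return PipelineResult(
        breakdowns=breakdowns,
        representatives=representatives,
        accepted=accepted,
        imperfect=imperfect,
        rejects=rejects,
        log=log,
    )


def _params_dict(params: ScoringParams) -> dict:
    from .config import params_to_dict

    d = params_to_dict(params)
    d["config_hash"] = hashlib.sha256(
        json.dumps(d, sort_keys=True).encode()
    ).hexdigest()[:16]
    return d


def write_outputs(result: PipelineResult, outdir, input_paths: dict | None = None) -> dict:
    """Write accepted/imperfect GFF3, the score report, and the run log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "accepted": outdir / "accepted.gff3",
        "imperfect": outdir / "imperfect.gff3",
        "scores": outdir / "scores.tsv",
        "log": outdir / "run_log.json",
    }
    gio.write_gff_models(result.accepted, paths["accepted"])
    gio.write_gff_models(result.imperfect, paths["imperfect"])
    gio.write_score_report(result.breakdowns.values(), paths["scores"])
    log = dict(result.log)
    if input_paths:
        log["input_checksums"] = {
            name: hashlib.sha256(Path(p).read_bytes()).hexdigest()[:16]
            for name, p in sorted(input_paths.items())
        }
    with open(paths["log"], "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {k: str(v) for k, v in paths.items()}
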