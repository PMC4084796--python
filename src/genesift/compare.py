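"""Evaluation machinery: CDS matching, sensitivity/specificity, overlap.

Gene-level matching compares the full ordered list of CDS coordinates
(*fixed* mode requires exact identity of every coordinate and the
strand; *flexible* mode additionally accepts models that are identical
except at the coding start, i.e. the 5' boundary of the first coding
exon differs by a multiple of 3).  Exon-level matching compares
(contig, strand, start, end, class) tuples, with flexible mode relaxing
the coding-start coordinate of initial and single exons.  Sensitivity
is measured against a reference set and specificity against the
prediction set; the two may use different reference sets (e.g. a
high-confidence subset for sensitivity, all annotations for
specificity).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .models import GeneModel

__all__ = [
    "EvalResult",
    "exact_cds_match",
    "match_except_start",
    "evaluate",
    "overlap_fraction",
    "similarity_categories",
    "consensus_set",
    "SIMILARITY_CATEGORIES",
]

SIMILARITY_CATEGORIES = (
    "identical",
    "identical_except_start",
    "different_gt5",
    "different_lt5",
)


@dataclass(frozen=True)
class EvalResult:
    level: str  # gene | exon
    mode: str  # fixed | flexible
    tp: int
    fn: int
    fp: int
    exon_class: str | None = None
    tp_spec: int | None = None  # confirmed predictions, when the
    # specificity reference differs from the sensitivity reference

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else math.nan

    @property
    def specificity(self) -> float:
        """Fraction of predictions that are correct."""
        tp = self.tp if self.tp_spec is None else self.tp_spec
        return tp / (tp + self.fp) if (tp + self.fp) else math.nan


# -- model-pair predicates --------------------------------------------


def exact_cds_match(a: GeneModel, b: GeneModel) -> bool:
    """Strand and every exon (start, end) pair identical."""
    return a.cds_signature() == b.cds_signature()


def _start_masked_signature(m: GeneModel) -> tuple:
    """CDS signature with the coding-start boundary masked out."""
    coords = [[e.start, e.end] for e in m.exons]
    if m.strand == "+":
        coords[0][0] = None
    else:
        coords[-1][1] = None
    return (m.contig_id, m.strand, tuple(tuple(c) for c in coords))


def _coding_start(m: GeneModel) -> int:
    return m.exons[0].start if m.strand == "+" else m.exons[-1].end


def match_except_start(a: GeneModel, b: GeneModel) -> bool:
    """Models identical except for an in-frame shift of the coding start.

    Exclusive of :func:`exact_cds_match`: an exact match returns False.
    """
    if exact_cds_match(a, b):
        return False
    if _start_masked_signature(a) != _start_masked_signature(b):
        return False
    return abs(_coding_start(a) - _coding_start(b)) % 3 == 0


# -- set-level evaluation ---------------------------------------------


def _gene_matched(
    targets: Sequence[GeneModel], predictions: Sequence[GeneModel], mode: str
) -> tuple[int, int]:
    """(# targets matched, # predictions matching), one prediction per target.

    Predictions are assigned greedily in coordinate order, so a
    reference model is credited at most once.
    """
    preds = sorted(
        predictions, key=lambda m: (m.contig_id, m.span_start, m.span_end, m.id)
    )
    used = [False] * len(preds)
    matched_targets = 0
    for t in sorted(targets, key=lambda m: (m.contig_id, m.span_start, m.span_end, m.id)):
        for i, p in enumerate(preds):
            if used[i]:
                continue
            if exact_cds_match(p, t) or (mode == "flexible" and match_except_start(p, t)):
                used[i] = True
                matched_targets += 1
                break
    return matched_targets, sum(used)


def _exon_keys(models: Iterable[GeneModel], mode: str, exon_class: str | None):
    """Set of exon identity keys; flexible mode masks the coding start
    of initial and single exons."""
    keys = set()
    for m in models:
        for e in m.exons:
            if exon_class is not None and e.exon_class != exon_class:
                continue
            start, end = e.start, e.end
            if mode == "flexible" and e.exon_class in ("initial", "single"):
                if m.strand == "+":
                    start = None
                else:
                    end = None
            keys.add((m.contig_id, m.strand, e.exon_class, start, end))
    return keys


def evaluate(
    predictions: Sequence[GeneModel],
    reference: Sequence[GeneModel],
    mode: str = "fixed",
    level: str = "gene",
    exon_class: str | None = None,
    spec_reference: Sequence[GeneModel] | None = None,
) -> EvalResult:
    """Sensitivity/specificity of ``predictions`` against ``reference``.

    Sensitivity counts reference models (or exons) recovered; specificity
    counts predictions confirmed — against ``spec_reference`` when given
    (supporting a high-confidence subset for sensitivity and the full
    annotation for specificity), else against ``reference``.
    """
    if mode not in ("fixed", "flexible"):
        raise ValueError(f"unknown mode {mode!r}")
    spec_ref = reference if spec_reference is None else spec_reference
    if level == "gene":
        tp_sens, _ = _gene_matched(reference, predictions, mode)
        _, tp_spec = _gene_matched(spec_ref, predictions, mode)
        fn = len(reference) - tp_sens
        fp = len(predictions) - tp_spec
        return EvalResult(
            level, mode, tp=tp_sens, fn=fn, fp=fp,
            tp_spec=None if spec_reference is None else tp_spec,
        )
    if level == "exon":
        ref_keys = _exon_keys(reference, mode, exon_class)
        spec_keys = _exon_keys(spec_ref, mode, exon_class)
        pred_keys = _exon_keys(predictions, mode, exon_class)
        tp_sens = len(ref_keys & pred_keys)
        tp_spec = len(spec_keys & pred_keys)
        return EvalResult(
            level, mode,
            tp=tp_sens,
            fn=len(ref_keys) - tp_sens,
            fp=len(pred_keys) - tp_spec,
            exon_class=exon_class,
            tp_spec=None if spec_reference is None else tp_spec,
        )
    raise ValueError(f"unknown level {level!r}")


# -- overlap and similarity categories --------------------------------


def overlap_fraction(model: GeneModel, other_set: Iterable[GeneModel]) -> float:
    """Fraction of the model's CDS bases shared with the union of the
    other set's CDS bases on the same contig; in [0, 1]."""
    others = [
        (e.start, e.end)
        for m in other_set
        if m.contig_id == model.contig_id
        for e in m.exons
    ]
    if not others:
        return 0.0
    # merge other-set exon intervals
    others.sort()
    merged: list[list[int]] = []
    for s, e in others:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    shared = 0
    for exon in model.exons:
        for s, e in merged:
            lo, hi = max(exon.start, s), min(exon.end, e)
            if lo <= hi:
                shared += hi - lo + 1
    return shared / model.cds_length


def similarity_categories(
    models: Sequence[GeneModel],
    other_set: Sequence[GeneModel],
    overlap_cutoff: float = 0.05,
) -> tuple[dict[str, str], Counter]:
    """Assign each model one of four exclusive similarity categories.

    identical > identical_except_start > different with more/less than
    ``overlap_cutoff`` CDS overlap in the other set.  The categories
    partition the input: counts sum to ``len(models)``.
    """
    per_model: dict[str, str] = {}
    for m in models:
        if any(exact_cds_match(m, o) for o in other_set):
            cat = "identical"
        elif any(match_except_start(m, o) for o in other_set):
            cat = "identical_except_start"
        elif overlap_fraction(m, other_set) > overlap_cutoff:
            cat = "different_gt5"
        else:
            cat = "different_lt5"
        per_model[m.id] = cat
    return per_model, Counter(per_model.values())


def consensus_set(
    set_a: Sequence[GeneModel], set_b: Sequence[GeneModel]
) -> list[GeneModel]:
    """Models of ``set_a`` with an exact CDS match in ``set_b``, duplicates collapsed."""
    b_signatures = {m.cds_signature() for m in set_b}
    out, seen = [], set()
    for m in set_a:
        sig = m.cds_signature()
        if sig in b_signatures and sig not in seen:
            seen.add(sig)
            out.append(m)
    return out
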