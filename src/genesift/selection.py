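"""Selection of representative models.

Scored candidates are partitioned into *overlap groups* — the
transitive closure of genomic-span overlap, strand-blind.  Within each
group the chain (mutually non-overlapping subset) with the highest
summed *effective score* is found by weighted-interval-scheduling
dynamic programming.  The effective score adds a small per-base
pseudoscore to every model so that zero-scoring models are still chosen
where nothing better overlaps them, with the longest zero-scoring model
preferred, and so that exact score ties between distinct spans are rare.

When several chains tie exactly, all of them are carried forward; a
final seeded pass over the genome resolves any remaining overlaps by
keeping the highest effective score, breaking exact ties randomly.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Iterable, Sequence

from .models import DEFAULT_PARAMS, GeneModel, ScoringParams

__all__ = [
    "OverlapGroup",
    "effective_score",
    "group_overlapping",
    "optimal_chains",
    "select_chain",
    "preselect_pooled",
    "resolve_representatives",
]


@dataclass
class OverlapGroup:
    contig_id: str
    models: list[GeneModel]  # sorted by (start, end)

    @property
    def span(self) -> tuple[int, int]:
        return self.models[0].span_start, max(m.span_end for m in self.models)

    def __len__(self) -> int:
        return len(self.models)


def effective_score(model: GeneModel, params: ScoringParams = DEFAULT_PARAMS) -> float:
    """V_t plus the per-base pseudoscore over the transcript span.

    With ``pseudoscore_basis="exonic"`` only exonic bases count.
    """
    if model.score is None:
        raise ValueError(f"model {model.id} has not been scored")
    length = (
        model.span_length if params.pseudoscore_basis == "span" else model.cds_length
    )
    return model.score + params.pseudoscore_per_base * length


def group_overlapping(models: Iterable[GeneModel]) -> list[OverlapGroup]:
    """Partition models by transitive genomic-span overlap (strand ignored)."""
    ordered = sorted(models, key=lambda m: (m.contig_id, m.span_start, m.span_end, m.id))
    groups: list[OverlapGroup] = []
    current: list[GeneModel] = []
    current_end = -1
    current_contig = None
    for m in ordered:
        if current and m.contig_id == current_contig and m.span_start <= current_end:
            current.append(m)
            current_end = max(current_end, m.span_end)
        else:
            if current:
                groups.append(OverlapGroup(current_contig, current))
            current = [m]
            current_contig = m.contig_id
            current_end = m.span_end
    if current:
        groups.append(OverlapGroup(current_contig, current))
    return groups


def optimal_chains(
    group: OverlapGroup | Sequence[GeneModel],
    params: ScoringParams = DEFAULT_PARAMS,
    max_chains: int = 10_000,
) -> tuple[float, list[list[GeneModel]]]:
    """Best total effective score and every exactly-tying optimal chain.

    Weighted interval scheduling over members sorted by span end; two
    members are compatible iff their spans share no genomic base.
    """
    members = group.models if isinstance(group, OverlapGroup) else list(group)
    if not members:
        return 0.0, [[]]
    ms = sorted(members, key=lambda m: (m.span_end, m.span_start, m.id))
    values = [effective_score(m, params) for m in ms]
    n = len(ms)
    # pred[i]: number of models (prefix length) wholly left of ms[i]
    ends = [m.span_end for m in ms]
    pred = []
    for i, m in enumerate(ms):
        lo, hi = 0, i
        while lo < hi:  # rightmost j with end < start
            mid = (lo + hi) // 2
            if ends[mid] < m.span_start:
                lo = mid + 1
            else:
                hi = mid
        pred.append(lo)
    dp = [0.0] * (n + 1)
    for i in range(1, n + 1):
        dp[i] = max(dp[i - 1], values[i - 1] + dp[pred[i - 1]])

    memo: dict[int, list[list[int]]] = {0: [[]]}

    def chains_at(i: int) -> list[list[int]]:
        if i in memo:
            return memo[i]
        result: list[list[int]] = []
        if dp[i] == dp[i - 1]:
            result.extend(chains_at(i - 1))
        if dp[i] == values[i - 1] + dp[pred[i - 1]]:
            for c in chains_at(pred[i - 1]):
                if len(result) >= max_chains:
                    break
                result.append(c + [i - 1])
        memo[i] = result[:max_chains]
        return memo[i]

    chains = [[ms[i] for i in idxs] for idxs in chains_at(n)]
    return dp[n], chains


def select_chain(
    group: OverlapGroup | Sequence[GeneModel],
    params: ScoringParams = DEFAULT_PARAMS,
) -> list[GeneModel]:
    """Union of all exactly-tying optimal chains for one overlap group.

    When a single chain is optimal this is that chain; when several tie,
    their members are all returned (possibly mutually overlapping) for
    the seeded final resolution pass.
    """
    _, chains = optimal_chains(group, params)
    seen: dict[int, GeneModel] = {}
    for chain in chains:
        for m in chain:
            seen.setdefault(id(m), m)
    return sorted(seen.values(), key=lambda m: (m.span_start, m.span_end, m.id))


def preselect_pooled(
    pooled_models: Iterable[GeneModel],
    params: ScoringParams = DEFAULT_PARAMS,
) -> list[GeneModel]:
    """Reduce a redundant pooled prediction set to ~1-2 models per locus."""
    selected: list[GeneModel] = []
    for group in group_overlapping(pooled_models):
        selected.extend(select_chain(group, params))
    return selected


def resolve_representatives(
    selected: Iterable[GeneModel],
    params: ScoringParams = DEFAULT_PARAMS,
    rng_seed: int = 0,
) -> list[GeneModel]:
    """Final pass: keep the highest effective score among overlapping survivors.

    Exact score ties are broken by a seeded random draw, so a fixed seed
    gives the same winner on every rerun.  Returned models are
    non-overlapping, sorted by position, and marked
    ``state="representative"``.
    """
    rng = random.Random(rng_seed)
    canonical = sorted(
        selected,
        key=lambda m: (m.contig_id, m.span_start, m.span_end, m.id, m.source),
    )
    decorated = [(-effective_score(m, params), rng.random(), i) for i, m in enumerate(canonical)]
    kept: list[GeneModel] = []
    kept_by_contig: dict[str, list[GeneModel]] = {}
    for _, _, i in sorted(decorated):
        m = canonical[i]
        if any(m.overlaps(k) for k in kept_by_contig.get(m.contig_id, [])):
            continue
        m.state = "representative"
        kept.append(m)
        kept_by_contig.setdefault(m.contig_id, []).append(m)
    kept.sort(key=lambda m: (m.contig_id, m.span_start, m.span_end, m.id))
    return kept
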