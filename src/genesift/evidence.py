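"""RNA-Seq evidence: splice junctions, coverage tracks, and derived statistics.

Splice junctions are strand-agnostic intron intervals supported by
spliced reads; each carries an empirical *read-through ratio*

    rt = mean depth inside the intron / (that mean + spliced read count)

which is ~0 for a cleanly spliced intron and approaches 1 when the
intron is largely retained in the transcript population.  Junction
bonuses and penalties used by exon-boundary scoring are functions of rt;
the default ``linear`` forms are reward = 2*(1-rt), penalty = rt, and an
``exponential`` alternative (2**(1-rt), 1-(1-rt)**2) is available via
:class:`~genesift.models.ScoringParams.boundary_score_form`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .models import CoordinateError, GeneModel, Genome, ScoringParams, DEFAULT_PARAMS

__all__ = [
    "SpliceJunction",
    "CoverageTrack",
    "TranscriptDepthStats",
    "RnaSeqEvidence",
    "compute_read_through",
    "reward",
    "penalty",
    "transcript_depth_stats",
    "find_low_coverage_runs",
    "exon_depth_in_range",
    "assemble_read_islands",
    "model_read_depth",
    "depth_bin",
    "DEPTH_BIN_EDGES",
]

DEPTH_BIN_EDGES = (0.05, 0.1, 0.5, 1.0, 2.0, 4.0)


@dataclass(frozen=True)
class SpliceJunction:
    """An observed intron interval (1-based inclusive) with spliced-read support."""

    contig_id: str
    start: int
    end: int
    spliced_reads: int
    rt: float | None = None

    def __post_init__(self) -> None:
        if self.spliced_reads < 1:
            raise ValueError(
                f"junction {self.contig_id}:{self.start}-{self.end}: "
                "spliced_reads must be >= 1 (junctions exist only where spliced reads were seen)"
            )
        if self.start > self.end:
            raise ValueError("junction start > end")
        if self.rt is not None and not (0 <= self.rt < 1):
            raise ValueError(f"read-through ratio {self.rt} outside [0, 1)")


class CoverageTrack:
    """Per-contig, per-base read depth (non-negative)."""

    def __init__(self, depths: dict[str, np.ndarray]):
        self._depths = {}
        for contig_id, arr in depths.items():
            a = np.asarray(arr, dtype=float)
            if a.ndim != 1:
                raise ValueError(f"coverage for {contig_id} is not 1-D")
            if (a < 0).any():
                raise ValueError(f"negative depths on {contig_id}")
            self._depths[contig_id] = a

    @classmethod
    def zeros(cls, genome: Genome) -> "CoverageTrack":
        return cls({c.id: np.zeros(len(c)) for c in genome})

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self._depths

    @property
    def contig_ids(self) -> list[str]:
        return list(self._depths)

    def array(self, contig_id: str) -> np.ndarray:
        return self._depths[contig_id]

    def depths(self, contig_id: str, start: int, end: int) -> np.ndarray:
        """Depth over ``[start, end]`` (1-based inclusive)."""
        if contig_id not in self._depths:
            raise CoordinateError(f"no coverage for contig {contig_id!r}")
        arr = self._depths[contig_id]
        if start < 1 or end > arr.size or start > end:
            raise CoordinateError(
                f"{contig_id}:{start}-{end} outside coverage bounds 1-{arr.size}"
            )
        return arr[start - 1 : end]


@dataclass(frozen=True)
class TranscriptDepthStats:
    """Depth summaries over the multiset of exonic per-base depths."""

    median: float
    mean: float
    per_exon_mean: tuple[float, ...]


@dataclass
class RnaSeqEvidence:
    """Coverage plus read-through-annotated junctions, indexed by contig."""

    coverage: CoverageTrack
    junctions_by_contig: dict[str, list[SpliceJunction]]

    @classmethod
    def build(
        cls, coverage: CoverageTrack, junctions: list[SpliceJunction]
    ) -> "RnaSeqEvidence":
        by_contig: dict[str, list[SpliceJunction]] = {}
        for j in junctions:
            rt = j.rt if j.rt is not None else compute_read_through(j, coverage)
            by_contig.setdefault(j.contig_id, []).append(replace(j, rt=rt))
        for js in by_contig.values():
            js.sort(key=lambda j: (j.start, j.end))
        return cls(coverage, by_contig)

    def junctions(self, contig_id: str) -> list[SpliceJunction]:
        return self.junctions_by_contig.get(contig_id, [])


def compute_read_through(junction: SpliceJunction, coverage: CoverageTrack) -> float:
    """rt = mean intronic depth / (mean intronic depth + spliced reads); in [0, 1)."""
    inside = float(
        np.mean(coverage.depths(junction.contig_id, junction.start, junction.end))
    )
    return inside / (inside + junction.spliced_reads)


def reward(rt: float, form: str = "linear") -> float:
    """Bonus for an exon boundary that matches a junction; decreasing in rt."""
    if not (0 <= rt < 1):
        raise ValueError(f"read-through ratio {rt} outside [0, 1)")
    if form == "linear":
        return 2.0 * (1.0 - rt)
    if form == "exponential":
        return 2.0 ** (1.0 - rt)
    raise ValueError(f"unknown boundary score form {form!r}")


def penalty(rt: float, form: str = "linear") -> float:
    """Penalty for a missed or covered junction; increasing in rt."""
    if not (0 <= rt < 1):
        raise ValueError(f"read-through ratio {rt} outside [0, 1)")
    if form == "linear":
        return rt
    if form == "exponential":
        return 1.0 - (1.0 - rt) ** 2
    raise ValueError(f"unknown boundary score form {form!r}")


def _exonic_depths(model: GeneModel, coverage: CoverageTrack) -> list[np.ndarray]:
    return [coverage.depths(model.contig_id, e.start, e.end) for e in model.exons]


def transcript_depth_stats(
    model: GeneModel, coverage: CoverageTrack
) -> TranscriptDepthStats:
    """Median/mean over all exonic bases, plus per-exon means in genomic order."""
    per_exon = _exonic_depths(model, coverage)
    allbases = np.concatenate(per_exon)
    return TranscriptDepthStats(
        median=float(np.median(allbases)),
        mean=float(np.mean(allbases)),
        per_exon_mean=tuple(float(np.mean(d)) for d in per_exon),
    )


def find_low_coverage_runs(
    model: GeneModel,
    coverage: CoverageTrack,
    stats: TranscriptDepthStats,
    params: ScoringParams = DEFAULT_PARAMS,
) -> list[tuple[int, int]]:
    """Maximal exonic runs below threshold that exceed the allowed length.

    A base is *low* when its depth is strictly below
    ``low_run_threshold_frac * transcript mean``; a maximal run of
    consecutive low exonic bases is a violation iff it is longer than
    ``max_low_run_len``.  Only violations are returned, as genomic
    (start, end) intervals.
    """
    threshold = params.low_run_threshold_frac * stats.mean
    violations: list[tuple[int, int]] = []
    for exon, depths in zip(model.exons, _exonic_depths(model, coverage)):
        low = depths < threshold
        i = 0
        n = low.size
        while i < n:
            if low[i]:
                j = i
                while j + 1 < n and low[j + 1]:
                    j += 1
                if (j - i + 1) > params.max_low_run_len:
                    violations.append((exon.start + i, exon.start + j))
                i = j + 1
            else:
                i += 1
    return violations


def exon_depth_in_range(
    exon_mean: float,
    transcript_median: float,
    params: ScoringParams = DEFAULT_PARAMS,
) -> bool:
    """True iff lo*median <= exon mean <= hi*median (inclusive bounds)."""
    if transcript_median <= 0:
        raise ValueError("transcript median must be > 0")
    lo, hi = params.exon_depth_range
    return lo * transcript_median <= exon_mean <= hi * transcript_median


def assemble_read_islands(
    coverage: CoverageTrack, params: ScoringParams = DEFAULT_PARAMS
) -> list[tuple[str, int, int]]:
    """Maximal intervals with depth >= island_min_depth and length >= island_min_len.

    Islands are evidence of transcription independent of any gene model;
    returned sorted as (contig, start, end), 1-based inclusive.
    """
    islands: list[tuple[str, int, int]] = []
    for contig_id in sorted(coverage.contig_ids):
        arr = coverage.array(contig_id)
        above = arr >= params.island_min_depth
        # boundaries of maximal True runs
        padded = np.concatenate(([False], above, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.nonzero(diff == 1)[0]
        ends = np.nonzero(diff == -1)[0]  # exclusive
        for s, e in zip(starts, ends):
            if e - s >= params.island_min_len:
                islands.append((contig_id, int(s) + 1, int(e)))
    return islands


def model_read_depth(model: GeneModel, read_count_in_exons: float) -> float:
    """Reads mapped within the model's exons divided by total exon length."""
    if read_count_in_exons < 0:
        raise ValueError("read count must be >= 0")
    return read_count_in_exons / model.cds_length


def depth_bin(depth: float) -> str:
    """Left-closed depth bin label for the standard cut points."""
    edges = DEPTH_BIN_EDGES
    if depth < edges[0]:
        return f"[0,{edges[0]})"
    for lo, hi in zip(edges, edges[1:]):
        if lo <= depth < hi:
            return f"[{lo},{hi})"
    return f">={edges[-1]}"
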