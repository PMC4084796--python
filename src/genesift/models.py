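"""Domain types for gene models and scoring parameters.

Coordinate convention
---------------------
All public interfaces use GFF3-style coordinates: 1-based, inclusive at
both ends, on the forward genomic strand.  A :class:`GeneModel` stores
its exons sorted by genomic position; transcription order for
minus-strand models is the reverse of genomic order.  Exon classes
(``initial`` / ``internal`` / ``terminal`` / ``single``) always follow
transcription order, so for a minus-strand model the initial exon is the
genomically rightmost one.

Models carry only coding sequence (CDS): no UTRs, one transcript per
model.  The stop codon is included in the terminal CDS interval; the
translated protein excludes it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

from Bio.Seq import Seq

__all__ = [
    "Contig",
    "Genome",
    "Exon",
    "Intron",
    "GeneModel",
    "ScoringParams",
    "TranslationResult",
    "ModelValidationError",
    "CoordinateError",
    "StructuralError",
    "translate_cds",
    "derive_introns",
    "spliced_cds",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_ALPHABET = frozenset("ACGTN")


class ModelValidationError(ValueError):
    """A gene model violates a structural invariant."""


class CoordinateError(ValueError):
    """A feature lies outside the bounds of its contig."""


class StructuralError(ValueError):
    """Bad intron structure (e.g. abutting CDS features)."""


@dataclass(frozen=True)
class Contig:
    """A single genome sequence, uppercase A/C/G/T/N."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"contig {self.id!r} has empty sequence")
        seq = self.sequence.upper()
        if set(seq) - _ALPHABET:
            bad = sorted(set(seq) - _ALPHABET)
            raise ValueError(f"contig {self.id!r} contains non-ACGTN symbols: {bad}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


class Genome:
    """A collection of contigs with 1-based inclusive sequence access."""

    def __init__(self, contigs: Iterable[Contig]):
        self._contigs: dict[str, Contig] = {}
        for c in contigs:
            if c.id in self._contigs:
                raise ValueError(f"duplicate contig id {c.id!r}")
            self._contigs[c.id] = c

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self._contigs

    def __getitem__(self, contig_id: str) -> Contig:
        return self._contigs[contig_id]

    def __iter__(self):
        return iter(self._contigs.values())

    def __len__(self) -> int:
        return len(self._contigs)

    @property
    def contig_ids(self) -> list[str]:
        return list(self._contigs)

    def length(self, contig_id: str) -> int:
        return len(self._contigs[contig_id])

    def fetch(self, contig_id: str, start: int, end: int) -> str:
        """Sequence of ``[start, end]`` (1-based inclusive, forward strand)."""
        if contig_id not in self._contigs:
            raise CoordinateError(f"unknown contig {contig_id!r}")
        contig = self._contigs[contig_id]
        if start < 1 or end > len(contig) or start > end:
            raise CoordinateError(
                f"{contig_id}:{start}-{end} outside contig bounds 1-{len(contig)}"
            )
        return contig.sequence[start - 1 : end]


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class Exon:
    contig_id: str
    start: int
    end: int
    exon_class: str = "internal"  # initial | internal | terminal | single

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ModelValidationError(
                f"exon start {self.start} > end {self.end} on {self.contig_id}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Intron:
    """An intron interval: first/last intronic base, donor/acceptor on the coding strand."""

    contig_id: str
    start: int
    end: int
    donor: str = ""
    acceptor: str = ""

    def __len__(self) -> int:
        return self.end - self.start + 1

    @property
    def donor_acceptor(self) -> str:
        return f"{self.donor}-{self.acceptor}"


def _assign_classes(exons: list[Exon], strand: str) -> tuple[Exon, ...]:
    n = len(exons)
    if n == 1:
        return (replace(exons[0], exon_class="single"),)
    classes = ["internal"] * n
    if strand == "+":
        classes[0], classes[-1] = "initial", "terminal"
    else:
        classes[0], classes[-1] = "terminal", "initial"
    return tuple(replace(e, exon_class=c) for e, c in zip(exons, classes))


@dataclass
class GeneModel:
    """One candidate transcript: ordered CDS exons on one contig and strand.

    ``exons`` are stored sorted by genomic start regardless of strand.
    ``score`` is filled by the scoring stage; ``state`` tracks the
    lifecycle candidate -> scored -> representative -> accepted/imperfect.
    """

    id: str
    source: str
    contig_id: str
    strand: str
    exons: tuple[Exon, ...]
    state: str = "candidate"
    score: float | None = None
    status: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ModelValidationError(f"model {self.id}: bad strand {self.strand!r}")
        if not self.exons:
            raise ModelValidationError(f"model {self.id}: no exons")
        exons = sorted(self.exons, key=lambda e: (e.start, e.end))
        for e in exons:
            if e.contig_id != self.contig_id:
                raise ModelValidationError(
                    f"model {self.id}: exon on {e.contig_id}, model on {self.contig_id}"
                )
        for a, b in zip(exons, exons[1:]):
            if b.start <= a.end:
                raise ModelValidationError(
                    f"model {self.id}: overlapping exons {a.start}-{a.end} / {b.start}-{b.end}"
                )
        self.exons = _assign_classes(exons, self.strand)

    # -- geometry -----------------------------------------------------

    @property
    def span_start(self) -> int:
        return self.exons[0].start

    @property
    def span_end(self) -> int:
        return self.exons[-1].end

    @property
    def span_length(self) -> int:
        """Genomic length of the transcript span, introns included."""
        return self.span_end - self.span_start + 1

    @property
    def cds_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def exons_tx_order(self) -> tuple[Exon, ...]:
        """Exons in transcription (5'->3') order."""
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))

    def exon_cds_intervals(self) -> list[tuple[int, int]]:
        """1-based inclusive CDS-coordinate interval of each exon.

        Returned in *genomic* order, aligned with ``self.exons``; the
        intervals themselves count along the spliced transcript.
        """
        spans_tx = []
        pos = 1
        for e in self.exons_tx_order():
            spans_tx.append((pos, pos + len(e) - 1))
            pos += len(e)
        return spans_tx if self.strand == "+" else list(reversed(spans_tx))

    def overlaps(self, other: "GeneModel") -> bool:
        """Shared genomic bases between transcript spans (strand-blind)."""
        return (
            self.contig_id == other.contig_id
            and self.span_start <= other.span_end
            and other.span_start <= self.span_end
        )

    def cds_signature(self) -> tuple:
        return (
            self.contig_id,
            self.strand,
            tuple((e.start, e.end) for e in self.exons),
        )


@dataclass(frozen=True)
class ScoringParams:
    """Tunable thresholds for model scoring, selection and island assembly.

    Defaults are the values used for fungal genomes; all are
    configurable.  ``homology_norm``, ``boundary_score_form``,
    ``evalue_cutoff`` and ``pseudoscore_basis`` select between documented
    alternative readings of the score definitions (see docs/methods.md).
    """

    max_homologs: int = 3
    acceptable_donor_acceptor: frozenset[str] = frozenset({"GT-AG", "GC-AG", "AT-AC"})
    min_intron: int = 10
    max_intron: int = 2000
    min_protein_aa: int = 150
    rescue_min_protein_aa: int = 50
    low_median_cutoff: float = 10.0
    low_coverage_penalty: float = 0.6
    exon_depth_range: tuple[float, float] = (0.15, 3.0)
    max_low_run_len: int = 10
    low_run_threshold_frac: float = 0.05
    max_n_per_transcript: int = 8
    match_threshold: float = 0.5
    pseudoscore_per_base: float = 0.0001
    island_min_depth: float = 3.0
    island_min_len: int = 100
    evalue_cutoff: float = 1e-5
    homology_norm: str = "printed"  # printed | unnormalized
    boundary_score_form: str = "linear"  # linear | exponential
    pseudoscore_basis: str = "span"  # span | exonic

    def __post_init__(self) -> None:
        numeric = (
            self.max_homologs,
            self.min_intron,
            self.max_intron,
            self.min_protein_aa,
            self.rescue_min_protein_aa,
            self.low_median_cutoff,
            self.low_coverage_penalty,
            self.max_low_run_len,
            self.low_run_threshold_frac,
            self.max_n_per_transcript,
            self.match_threshold,
            self.pseudoscore_per_base,
            self.island_min_depth,
            self.island_min_len,
        )
        if any(v <= 0 for v in numeric):
            raise ValueError("all numeric scoring parameters must be > 0")
        lo, hi = self.exon_depth_range
        if not (0 < lo < hi):
            raise ValueError(f"bad exon_depth_range {self.exon_depth_range}")
        if self.homology_norm not in ("printed", "unnormalized"):
            raise ValueError(f"bad homology_norm {self.homology_norm!r}")
        if self.boundary_score_form not in ("linear", "exponential"):
            raise ValueError(f"bad boundary_score_form {self.boundary_score_form!r}")
        if self.pseudoscore_basis not in ("span", "exonic"):
            raise ValueError(f"bad pseudoscore_basis {self.pseudoscore_basis!r}")


DEFAULT_PARAMS = ScoringParams()


# -- sequence operations ---------------------------------------------


def spliced_cds(model: GeneModel, genome: Genome) -> str:
    """Concatenated exon sequence in transcription order (coding strand)."""
    parts = [genome.fetch(model.contig_id, e.start, e.end) for e in model.exons]
    cds = "".join(parts)
    return reverse_complement(cds) if model.strand == "-" else cds


@dataclass(frozen=True)
class TranslationResult:
    protein: str | None
    failure: str | None  # no_start | no_stop | internal_stop | frame | too_many_N
    cds: str

    @property
    def ok(self) -> bool:
        return self.failure is None


def translate_cds(
    model: GeneModel, genome: Genome, params: ScoringParams = DEFAULT_PARAMS
) -> TranslationResult:
    """Translate the spliced CDS, validating ORF structure.

    Valid iff the CDS length is divisible by 3, begins with ATG, ends
    with a stop codon, contains no internal stop, and has at most
    ``params.max_n_per_transcript`` N bases.  The returned protein
    excludes the stop codon.
    """
    cds = spliced_cds(model, genome)
    if cds.count("N") > params.max_n_per_transcript:
        return TranslationResult(None, "too_many_N", cds)
    if len(cds) % 3 != 0 or len(cds) < 6:
        return TranslationResult(None, "frame", cds)
    if not cds.startswith("ATG"):
        return TranslationResult(None, "no_start", cds)
    if cds[-3:] not in STOP_CODONS:
        return TranslationResult(None, "no_stop", cds)
    protein = str(Seq(cds[:-3]).translate())
    if "*" in protein:
        return TranslationResult(None, "internal_stop", cds)
    return TranslationResult(protein, None, cds)


def derive_introns(model: GeneModel, genome: Genome) -> list[Intron]:
    """Introns between consecutive exons, donor/acceptor on the coding strand.

    Returned in genomic order.  Raises :class:`StructuralError` for a
    zero-length gap (abutting CDS features).
    """
    introns: list[Intron] = []
    for a, b in zip(model.exons, model.exons[1:]):
        gap_start, gap_end = a.end + 1, b.start - 1
        if gap_start > gap_end:
            raise StructuralError(
                f"Bad intron structure in model {model.id}: abutting exons at {a.end}"
            )
        seq = genome.fetch(model.contig_id, gap_start, gap_end)
        if model.strand == "-":
            seq = reverse_complement(seq)
        donor, acceptor = (seq[:2], seq[-2:]) if len(seq) >= 2 else (seq, seq)
        introns.append(Intron(model.contig_id, gap_start, gap_end, donor, acceptor))
    return introns
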