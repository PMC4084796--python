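"""Readers and writers for the standard file formats.

Formats handled:

* FASTA genome (via Biopython SeqIO)
* GFF3 gene models, CDS features only, 1-based inclusive; a ``mRNA``
  line per model carries optional ``score=`` / ``status=`` attributes
* bedGraph coverage (0-based half-open per that standard; converted to
  1-based arrays at this boundary)
* junction tables (TSV: contig, intron start, intron end, spliced read
  count; 1-based inclusive)
* BLASTp tabular hits (outfmt-6 style with identity/positive counts:
  qseqid sseqid nident positive length qstart qend evalue bitscore)
* BED read islands, TSV score reports
"""

from __future__ import annotations

import urllib.parse
from typing import Iterable, TextIO

import numpy as np
import pandas as pd
from Bio import SeqIO

from .evidence import CoverageTrack, SpliceJunction
from .homology import HomologyHit
from .models import Contig, Exon, GeneModel, Genome, ModelValidationError

__all__ = [
    "GFFParseError",
    "read_fasta",
    "write_fasta",
    "read_gff_models",
    "write_gff_models",
    "partition_by_contig",
    "read_bedgraph",
    "write_bedgraph",
    "read_junctions",
    "write_junctions",
    "read_blast_tab",
    "write_blast_tab",
    "write_islands_bed",
    "write_score_report",
]

BLAST_COLUMNS = [
    "qseqid", "sseqid", "nident", "positive", "length",
    "qstart", "qend", "evalue", "bitscore",
]


class GFFParseError(ValueError):
    """A malformed GFF3 line; the message names the offending line number."""


# -- FASTA ------------------------------------------------------------


def read_fasta(path) -> Genome:
    return Genome(Contig(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta"))


def write_fasta(genome: Genome, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for contig in genome:
            fh.write(f">{contig.id}\n")
            for i in range(0, len(contig), width):
                fh.write(contig.sequence[i : i + width] + "\n")


# -- GFF3 -------------------------------------------------------------


def _parse_attributes(raw: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for field in raw.strip().rstrip(";").split(";"):
        if not field:
            continue
        if "=" not in field:
            raise ValueError(f"attribute {field!r} missing '='")
        key, value = field.split("=", 1)
        attrs[key.strip()] = urllib.parse.unquote(value.strip())
    return attrs


def read_gff_models(path, genome: Genome | None = None) -> list[GeneModel]:
    """Read CDS features grouped by transcript into :class:`GeneModel`.

    One model per distinct ``Parent`` (or ``ID`` when no Parent) value.
    Exon classes are assigned from each model's own structure; the
    phase column is ignored (recomputed on write).  Raises
    :class:`GFFParseError` naming the line number for malformed lines
    and :class:`ModelValidationError` if one transcript mixes strands or
    contigs.  Models on contigs absent from ``genome`` (when given) are
    *not* dropped here; use :func:`partition_by_contig` to quarantine
    them.
    """
    per_model: dict[str, dict] = {}
    sources: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GFFParseError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            seqid, source, ftype, start, end, _score, strand, _phase, attr_raw = cols
            if ftype != "CDS":
                continue
            try:
                start_i, end_i = int(start), int(end)
                attrs = _parse_attributes(attr_raw)
            except ValueError as exc:
                raise GFFParseError(f"{path}:{lineno}: {exc}") from exc
            if strand not in ("+", "-"):
                raise GFFParseError(f"{path}:{lineno}: bad strand {strand!r}")
            model_id = attrs.get("Parent") or attrs.get("ID")
            if not model_id:
                raise GFFParseError(
                    f"{path}:{lineno}: CDS feature lacks Parent/ID attribute"
                )
            entry = per_model.setdefault(
                model_id, {"contig": seqid, "strand": strand, "exons": []}
            )
            if entry["strand"] != strand or entry["contig"] != seqid:
                raise ModelValidationError(
                    f"{path}:{lineno}: transcript {model_id!r} mixes "
                    f"strands/contigs ({entry['contig']}{entry['strand']} vs {seqid}{strand})"
                )
            entry["exons"].append(Exon(seqid, start_i, end_i))
            sources.setdefault(model_id, source)
    models = []
    for model_id, entry in per_model.items():
        models.append(
            GeneModel(
                id=model_id,
                source=sources[model_id],
                contig_id=entry["contig"],
                strand=entry["strand"],
                exons=tuple(entry["exons"]),
            )
        )
    return models


def partition_by_contig(
    models: Iterable[GeneModel], genome: Genome
) -> tuple[list[GeneModel], list[GeneModel]]:
    """Split models into (valid, quarantined-on-unknown-contig)."""
    valid, rejected = [], []
    for m in models:
        (valid if m.contig_id in genome else rejected).append(m)
    return valid, rejected


def _cds_phases(model: GeneModel) -> list[int]:
    """GFF3 phase per exon (genomic order), recomputed from exon structure."""
    phases_tx = []
    cum = 0
    for e in model.exons_tx_order():
        phases_tx.append((3 - cum % 3) % 3)
        cum += len(e)
    return phases_tx if model.strand == "+" else list(reversed(phases_tx))


def write_gff_models(models: Iterable[GeneModel], path) -> None:
    """Write models as mRNA + CDS lines, deterministically ordered.

    The mRNA line carries ``score=`` and ``status=`` attributes when the
    model has been scored/classified.
    """
    ordered = sorted(models, key=lambda m: (m.contig_id, m.span_start, m.span_end, m.id))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in ordered:
            attrs = [f"ID={m.id}"]
            if m.score is not None:
                attrs.append(f"score={m.score:.6g}")
            if m.status is not None:
                attrs.append(f"status={m.status}")
            fh.write(
                "\t".join(
                    [m.contig_id, m.source, "mRNA", str(m.span_start), str(m.span_end),
                     ".", m.strand, ".", ";".join(attrs)]
                )
                + "\n"
            )
            for exon, phase in zip(m.exons, _cds_phases(m)):
                fh.write(
                    "\t".join(
                        [m.contig_id, m.source, "CDS", str(exon.start), str(exon.end),
                         ".", m.strand, str(phase), f"ID={m.id}.cds;Parent={m.id}"]
                    )
                    + "\n"
                )


# -- bedGraph ---------------------------------------------------------


def read_bedgraph(path, genome: Genome) -> CoverageTrack:
    """Read 0-based half-open bedGraph intervals into per-base arrays."""
    depths = {c.id: np.zeros(len(c)) for c in genome}
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["contig", "start", "end", "depth"],
        dtype={"contig": str, "start": int, "end": int, "depth": float},
    )
    for row in df.itertuples(index=False):
        if row.contig not in depths:
            raise ValueError(f"bedGraph references unknown contig {row.contig!r}")
        depths[row.contig][row.start : row.end] = row.depth
    return CoverageTrack(depths)


def write_bedgraph(coverage: CoverageTrack, path) -> None:
    """Write runs of equal depth as 0-based half-open intervals (zeros omitted)."""
    with open(path, "w") as fh:
        for contig_id in sorted(coverage.contig_ids):
            arr = coverage.array(contig_id)
            if arr.size == 0:
                continue
            boundaries = np.nonzero(np.diff(arr))[0] + 1
            starts = np.concatenate(([0], boundaries))
            ends = np.concatenate((boundaries, [arr.size]))
            for s, e in zip(starts, ends):
                d = arr[s]
                if d != 0:
                    fh.write(f"{contig_id}\t{s}\t{e}\t{d:g}\n")


# -- junction tables --------------------------------------------------


def read_junctions(path) -> list[SpliceJunction]:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["contig", "start", "end", "spliced_reads"],
        dtype={"contig": str, "start": int, "end": int, "spliced_reads": int},
    )
    return [
        SpliceJunction(row.contig, row.start, row.end, row.spliced_reads)
        for row in df.itertuples(index=False)
    ]


def write_junctions(junctions: Iterable[SpliceJunction], path) -> None:
    ordered = sorted(junctions, key=lambda j: (j.contig_id, j.start, j.end))
    with open(path, "w") as fh:
        fh.write("#contig\tstart\tend\tspliced_reads\n")
        for j in ordered:
            fh.write(f"{j.contig_id}\t{j.start}\t{j.end}\t{j.spliced_reads}\n")


# -- BLAST tabular ----------------------------------------------------


def read_blast_tab(path) -> dict[str, list[HomologyHit]]:
    """Read custom outfmt-6 hits, grouped by query (model) id."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=BLAST_COLUMNS)
    hits: dict[str, list[HomologyHit]] = {}
    for row in df.itertuples(index=False):
        hit = HomologyHit(
            model_id=str(row.qseqid),
            subject_id=str(row.sseqid),
            matches=int(row.nident),
            similarities=int(row.positive),
            aln_len=int(row.length),
            qstart_aa=int(row.qstart),
            qend_aa=int(row.qend),
            evalue=float(row.evalue),
            bitscore=float(row.bitscore),
        )
        hits.setdefault(hit.model_id, []).append(hit)
    return hits


def write_blast_tab(hits: Iterable[HomologyHit], path) -> None:
    ordered = sorted(hits, key=lambda h: (h.model_id, -h.bitscore, h.subject_id))
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(BLAST_COLUMNS) + "\n")
        for h in ordered:
            fh.write(
                f"{h.model_id}\t{h.subject_id}\t{h.matches}\t{h.similarities}\t"
                f"{h.aln_len}\t{h.qstart_aa}\t{h.qend_aa}\t{h.evalue:g}\t{h.bitscore:g}\n"
            )


# -- reports ----------------------------------------------------------


def write_islands_bed(islands: Iterable[tuple[str, int, int]], path) -> None:
    """Write read islands as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for contig_id, start, end in islands:
            fh.write(f"{contig_id}\t{start - 1}\t{end}\tisland\n")


def write_score_report(breakdowns, path) -> None:
    """TSV of per-model score factors (one row per model)."""
    with open(path, "w") as fh:
        fh.write(
            "model_id\tpath\tscore\tmatches_rnaseq\tfailure\tprotein_len\t"
            "intron_scores\thomology_scores\tboundary_scores\texon_scores\n"
        )
        for b in sorted(breakdowns, key=lambda b: b.model_id):
            fh.write(
                "\t".join(
                    [
                        b.model_id,
                        b.path,
                        f"{b.score:.6g}",
                        str(b.matches_rnaseq).lower(),
                        b.failure or ".",
                        str(b.protein_len) if b.protein_len is not None else ".",
                        ",".join(str(i) for i in b.intron_scores) or ".",
                        ",".join(f"{h:.6g}" for h in b.homology_scores) or ".",
                        ",".join(
                            f"{l:.6g}|{m:.6g}|{r:.6g}" for l, m, r in b.boundary_scores
                        )
                        or ".",
                        ",".join(f"{v:.6g}" for v in b.exon_scores) or ".",
                    ]
                )
                + "\n"
            )
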