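"""Seeded generator of complete toy datasets for the scoring pipeline.

A fixture bundles a genome with planted multi-exon genes, the truth
models, a candidate pool (truth plus deliberately corrupted variants),
a junction table, a coverage track and a homology table — all mutually
consistent, so that the scorer's behaviour on each construct is known
analytically:

* planted genes translate cleanly (ATG..stop, no internal stop), use
  GT-AG introns of in-range length, and get uniform exonic coverage with
  one clean junction per intron, so they take the detailed scoring path
  and match the RNA-Seq data;
* *corrupted variants* overlap their parent gene and are each built to
  lose at least one multiplicative score factor (shifted start, shifted
  or dropped or fabricated intron, fused genes, truncation), so chain
  selection always prefers the truth model;
* *lone constructs* occupy loci with no truth model and become
  representative yet imperfect, each with a predictable diagnostic
  status (internal coverage gap, short intronless ORF, intron that
  contradicts the observed junction).

Sequence planting details: exon boundaries are codon-aligned; every
first exon reserves codon 10 as an in-frame ATG (start-shift target) and
codons 12-21 as a GT..AG segment (fabricated-intron target); the first
intron begins ``GTCGT`` and the second exon begins ``AAG`` so that
shifting the intron 3 bases downstream still yields a GT-AG intron of
unchanged length.  Intronic read depth is ``read_through x exonic
depth`` and spliced counts are ``(1 - read_through) x depth``, making
junction read-through ratios exact by construction.
"""

from __future__ import annotations

import hashlib
import json
import random
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .evidence import CoverageTrack, SpliceJunction
from .homology import HomologyHit
from .models import Contig, Exon, GeneModel, Genome, reverse_complement, translate_cds
from . import io as gio

__all__ = ["FixtureConfig", "FixtureBundle", "generate_fixture"]

_STOPS = {"TAA", "TAG", "TGA"}
_SAFE_CODONS = sorted(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS and a + b + c != "ATG"
)

CORRUPTION_TYPES = (
    "start_shift",
    "intron_shift",
    "intron_drop",
    "fusion",
    "truncation",
    "unsupported_intron",
)
LONE_TYPES = ("coverage_gap", "short_orf", "intron_mismatch")


@dataclass
class FixtureConfig:
    """Study conditions for one synthetic dataset."""

    seed: int = 0
    n_genes: int = 50
    exons_per_gene: tuple[int, int] = (2, 5)
    intron_len: tuple[int, int] = (40, 100)
    intergenic: tuple[int, int] = (300, 800)
    protein_aa: tuple[int, int] = (170, 400)
    coverage_depth: float = 50.0
    read_through: float = 0.0
    corruptions: dict[str, int] | None = None  # per-type gene counts; None = every gene
    lone_constructs: dict[str, int] = field(
        default_factory=lambda: {"coverage_gap": 2, "short_orf": 2, "intron_mismatch": 2}
    )
    decoy_homology: float = 0.3
    genes_per_contig: int = 25

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not (10 <= self.intron_len[0] <= self.intron_len[1] <= 2000):
            raise ValueError("intron_len range must lie within [10, 2000]")
        for lo, hi in (self.exons_per_gene, self.intergenic, self.protein_aa):
            if not (0 < lo <= hi):
                raise ValueError("ranges must be positive and ordered")
        if self.exons_per_gene[0] < 2:
            raise ValueError("planted genes are multi-exon; exons_per_gene min >= 2")
        if self.protein_aa[0] < 165:
            raise ValueError("protein_aa min must be >= 165 (start-shift headroom)")
        if not (0 <= self.read_through < 1):
            raise ValueError("read_through must be in [0, 1)")
        if self.corruptions is None:
            self.corruptions = {t: self.n_genes for t in CORRUPTION_TYPES}
        unknown = set(self.corruptions) - set(CORRUPTION_TYPES)
        if unknown:
            raise ValueError(f"unknown corruption types: {sorted(unknown)}")
        unknown = set(self.lone_constructs) - set(LONE_TYPES)
        if unknown:
            raise ValueError(f"unknown lone construct types: {sorted(unknown)}")


@dataclass
class _Locus:
    """One planted region, in transcript-oriented 0-based region coords."""

    kind: str  # gene | coverage_gap | short_orf | intron_mismatch
    index: int
    strand: str
    region: str  # transcript-oriented sequence
    exons: list[tuple[int, int]]
    introns: list[tuple[int, int]]
    aa: int
    # filled during assembly:
    contig_id: str = ""
    offset: int = 0  # genomic 1-based start of the region

    @property
    def region_len(self) -> int:
        return len(self.region)

    def map_interval(self, a: int, b: int) -> tuple[int, int]:
        """Region interval (0-based incl.) -> genomic (1-based incl.)."""
        if self.strand == "+":
            return self.offset + a, self.offset + b
        last = self.region_len - 1
        return self.offset + last - b, self.offset + last - a

    def genomic_sequence(self) -> str:
        return self.region if self.strand == "+" else reverse_complement(self.region)

    def make_model(
        self, model_id: str, source: str, region_exons: list[tuple[int, int]]
    ) -> GeneModel:
        exons = tuple(
            Exon(self.contig_id, *self.map_interval(a, b)) for a, b in region_exons
        )
        return GeneModel(
            id=model_id, source=source, contig_id=self.contig_id,
            strand=self.strand, exons=exons,
        )


@dataclass
class FixtureBundle:
    config: FixtureConfig
    genome: Genome
    truth: list[GeneModel]
    candidates: list[GeneModel]
    junctions: list[SpliceJunction]
    coverage: CoverageTrack
    hits: list[HomologyHit]
    manifest: dict

    def write(self, outdir) -> dict[str, str]:
        """Write the bundle to ``outdir``; returns the file map."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "truth": outdir / "truth.gff3",
            "candidates": outdir / "candidates.gff3",
            "junctions": outdir / "junctions.tsv",
            "coverage": outdir / "coverage.bedgraph",
            "hits": outdir / "hits.tsv",
            "manifest": outdir / "manifest.json",
        }
        gio.write_fasta(self.genome, paths["genome"])
        gio.write_gff_models(self.truth, paths["truth"])
        gio.write_gff_models(self.candidates, paths["candidates"])
        gio.write_junctions(self.junctions, paths["junctions"])
        gio.write_bedgraph(self.coverage, paths["coverage"])
        gio.write_blast_tab(self.hits, paths["hits"])
        with open(paths["manifest"], "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return {k: str(v) for k, v in paths.items()}


# -- sequence builders ------------------------------------------------


def _coding_sequence(rng: random.Random, aa: int) -> str:
    """ATG + (aa-1) non-stop codons + TAA, with planted start-shift ATG at
    codon 10 and a GT..AG 10-codon segment at codons 12-21."""
    codons = ["ATG"] + [rng.choice(_SAFE_CODONS) for _ in range(aa - 1)] + ["TAA"]
    codons[10] = "ATG"  # in-frame alternative start, 30 bases downstream
    codons[12] = "GTT"  # fabricated-intron segment: GT...
    for k in range(13, 21):
        codons[k] = rng.choice(_SAFE_CODONS)
    codons[21] = "AAG"  # ...AG
    return "".join(codons)


def _intron_sequence(rng: random.Random, length: int, shiftable: bool) -> str:
    body = "".join(rng.choice("ACGT") for _ in range(length - 7))
    if shiftable:
        # GTC GT ... AG: still a GT-AG intron after a +3 shift
        return "GTC" + "GT" + body + "AG"
    return "GT" + "C" + "".join(rng.choice("ACGT") for _ in range(2)) + body + "AG"


def _split_codon_aligned(
    rng: random.Random, total: int, n_chunks: int
) -> list[int]:
    """Split ``total`` (multiple of 3) into chunks of multiples of 3;
    first chunk >= 78 (room for planted features), others >= 30."""
    mins = [78] + [30] * (n_chunks - 1)
    extra_units = (total - sum(mins)) // 3
    if extra_units < 0:
        raise ValueError("coding sequence too short for requested exon count")
    shares = [0] * n_chunks
    left = extra_units
    for i in range(n_chunks - 1):
        shares[i] = rng.randint(0, left)
        left -= shares[i]
    shares[-1] = left
    return [m + 3 * s for m, s in zip(mins, shares)]


def _build_gene_locus(rng: random.Random, cfg: FixtureConfig, index: int,
                      kind: str = "gene") -> _Locus:
    aa = rng.randint(*cfg.protein_aa)
    n_exons = 2 if kind == "intron_mismatch" else rng.randint(*cfg.exons_per_gene)
    coding = _coding_sequence(rng, aa)
    chunks = _split_codon_aligned(rng, len(coding), n_exons)
    intron_lens = [rng.randint(*cfg.intron_len) for _ in range(n_exons - 1)]
    strand = rng.choice("+-")

    region_parts: list[str] = []
    exons: list[tuple[int, int]] = []
    introns: list[tuple[int, int]] = []
    pos = 0
    cpos = 0
    # second exon must begin AAG so the first intron can shift in frame
    coding = coding[: chunks[0]] + "AAG" + coding[chunks[0] + 3 :]
    for i, chunk in enumerate(chunks):
        region_parts.append(coding[cpos : cpos + chunk])
        exons.append((pos, pos + chunk - 1))
        pos += chunk
        cpos += chunk
        if i < n_exons - 1:
            iseq = _intron_sequence(rng, intron_lens[i], shiftable=(i == 0))
            region_parts.append(iseq)
            introns.append((pos, pos + len(iseq) - 1))
            pos += len(iseq)
    return _Locus(kind=kind, index=index, strand=strand,
                  region="".join(region_parts), exons=exons, introns=introns, aa=aa)


def _build_orf_locus(rng: random.Random, index: int, kind: str, aa: int) -> _Locus:
    codons = ["ATG"] + [rng.choice(_SAFE_CODONS) for _ in range(aa - 1)] + ["TAA"]
    region = "".join(codons)
    return _Locus(kind=kind, index=index, strand=rng.choice("+-"),
                  region=region, exons=[(0, len(region) - 1)], introns=[], aa=aa)


# -- fixture assembly -------------------------------------------------


def generate_fixture(config: FixtureConfig) -> FixtureBundle:
    """Build a complete deterministic dataset from ``config``."""
    cfg = config
    rng = random.Random(cfg.seed)

    loci: list[_Locus] = [
        _build_gene_locus(rng, cfg, i) for i in range(cfg.n_genes)
    ]
    lone_index = 0
    for kind in LONE_TYPES:
        for _ in range(cfg.lone_constructs.get(kind, 0)):
            if kind == "short_orf":
                loci.append(_build_orf_locus(rng, lone_index, kind, aa=100))
            elif kind == "coverage_gap":
                loci.append(_build_orf_locus(rng, lone_index, kind, aa=180))
            else:  # intron_mismatch: a normal-looking two-exon gene
                loci.append(_build_gene_locus(rng, cfg, lone_index, kind="intron_mismatch"))
            lone_index += 1

    # lay loci onto contigs
    contig_seqs: dict[str, list[str]] = {}
    contig_cursor: dict[str, int] = {}
    for i, locus in enumerate(loci):
        contig_id = f"ctg{i // cfg.genes_per_contig + 1:02d}"
        parts = contig_seqs.setdefault(contig_id, [])
        cursor = contig_cursor.get(contig_id, 0)
        gap = rng.randint(*cfg.intergenic)
        parts.append("".join(rng.choice("ACGT") for _ in range(gap)))
        locus.contig_id = contig_id
        locus.offset = cursor + gap + 1
        parts.append(locus.genomic_sequence())
        contig_cursor[contig_id] = cursor + gap + locus.region_len
    for contig_id in list(contig_seqs):
        tail = rng.randint(*cfg.intergenic)
        contig_seqs[contig_id].append("".join(rng.choice("ACGT") for _ in range(tail)))
        contig_cursor[contig_id] += tail
    genome = Genome(
        Contig(cid, "".join(parts)) for cid, parts in sorted(contig_seqs.items())
    )

    coverage = CoverageTrack.zeros(genome)
    depth = cfg.coverage_depth
    intron_depth = round(cfg.read_through * depth)
    spliced = max(1, round((1.0 - cfg.read_through) * depth))

    truth: list[GeneModel] = []
    candidates: list[GeneModel] = []
    junctions: list[SpliceJunction] = []
    genes = [l for l in loci if l.kind == "gene"]

    def _paint(locus: _Locus, region_iv: tuple[int, int], value: float) -> None:
        s, e = locus.map_interval(*region_iv)
        coverage.array(locus.contig_id)[s - 1 : e] = value

    for g in genes:
        gene_id = f"g{g.index + 1:03d}"
        source = "genemark" if g.index % 2 == 0 else "splice_hinted"
        model = g.make_model(gene_id, source, g.exons)
        truth.append(model)
        candidates.append(g.make_model(gene_id, source, g.exons))
        for iv in g.exons:
            _paint(g, iv, depth)
        for iv in g.introns:
            if intron_depth:
                _paint(g, iv, intron_depth)
            s, e = g.map_interval(*iv)
            junctions.append(SpliceJunction(g.contig_id, s, e, spliced))

    # corrupted variants (overlap their parent gene; always lose selection)
    for kind, count in sorted(cfg.corruptions.items()):
        for g in genes[: min(count, len(genes))]:
            gene_id = f"g{g.index + 1:03d}"
            vid = f"{gene_id}_{kind}"
            c1 = g.exons[0][1] - g.exons[0][0] + 1
            if kind == "start_shift":
                exons = [(g.exons[0][0] + 30, g.exons[0][1])] + g.exons[1:]
            elif kind == "truncation":
                exons = g.exons[:-1]
            elif kind == "intron_drop":
                exons = [(g.exons[0][0], g.exons[1][1])] + g.exons[2:]
            elif kind == "unsupported_intron":
                a, b = g.exons[0]
                exons = [(a, a + 35), (a + 66, b)] + g.exons[1:]
            elif kind == "intron_shift":
                exons = [
                    (g.exons[0][0], g.exons[0][1] + 3),
                    (g.exons[1][0] + 3, g.exons[1][1]),
                ] + g.exons[2:]
            elif kind == "fusion":
                nxt = next(
                    (h for h in genes
                     if h.index == g.index + 1 and h.contig_id == g.contig_id),
                    None,
                )
                if nxt is None:
                    continue
                a_exons = [
                    Exon(g.contig_id, *g.map_interval(*iv)) for iv in g.exons
                ]
                b_exons = [
                    Exon(nxt.contig_id, *nxt.map_interval(*iv)) for iv in nxt.exons
                ]
                candidates.append(
                    GeneModel(id=vid, source="pooled", contig_id=g.contig_id,
                              strand=g.strand, exons=tuple(a_exons + b_exons))
                )
                continue
            candidates.append(g.make_model(vid, "pooled", exons))

    # lone constructs: representative but imperfect by construction
    for locus in loci:
        if locus.kind == "gene":
            continue
        lid = f"lone_{locus.kind}_{locus.index}"
        if locus.kind == "short_orf":
            candidates.append(locus.make_model(lid, "pooled", locus.exons))
            _paint(locus, locus.exons[0], depth)
        elif locus.kind == "coverage_gap":
            candidates.append(locus.make_model(lid, "pooled", locus.exons))
            _paint(locus, locus.exons[0], depth)
            mid = (locus.exons[0][0] + locus.exons[0][1]) // 2
            _paint(locus, (mid, mid + 19), 0.0)  # 20-base gap > max run of 10
        else:  # intron_mismatch: junction sits 3 bases downstream of the intron
            candidates.append(locus.make_model(lid, "pooled", locus.exons))
            for iv in locus.exons:
                _paint(locus, iv, depth)
            ia, ib = locus.introns[0]
            s, e = locus.map_interval(ia + 3, ib + 3)
            junctions.append(SpliceJunction(locus.contig_id, s, e, spliced))

    # homology: perfect full-length hits for a fraction of genes, shared
    # with their translatable variants.  Each hit spans the *model's own*
    # protein, so homology support is proportionate and cannot flip the
    # selection away from the truth model.
    hits: list[HomologyHit] = []
    with_hits = [g for g in genes if rng.random() < cfg.decoy_homology]
    by_gene: dict[str, list[GeneModel]] = {}
    for m in candidates:
        by_gene.setdefault(m.id.split("_")[0], []).append(m)
    for g in with_hits:
        gene_id = f"g{g.index + 1:03d}"
        n_hits = rng.randint(1, 3)
        for k in range(n_hits):
            for m in by_gene.get(gene_id, []):
                translation = translate_cds(m, genome)
                if not translation.ok:
                    continue
                aa = len(translation.protein)
                hits.append(
                    HomologyHit(
                        model_id=m.id, subject_id=f"sp|H{g.index:04d}_{k}",
                        matches=aa, similarities=aa, aln_len=aa,
                        qstart_aa=1, qend_aa=aa,
                        evalue=1e-50, bitscore=500.0 - k,
                    )
                )

    junctions.sort(key=lambda j: (j.contig_id, j.start, j.end))
    cfg_dict = asdict(cfg)
    manifest = {
        "seed": cfg.seed,
        "config": json.loads(json.dumps(cfg_dict, default=list)),
        "n_truth": len(truth),
        "n_candidates": len(candidates),
        "n_junctions": len(junctions),
        "n_hits": len(hits),
        "contigs": {c.id: len(c) for c in genome},
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=list).encode()
        ).hexdigest()[:16],
    }
    return FixtureBundle(
        config=cfg, genome=genome, truth=truth, candidates=candidates,
        junctions=junctions, coverage=coverage, hits=hits, manifest=manifest,
    )
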