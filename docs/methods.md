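# Methods

## Scope and model of the data

`genesift` operates on CDS-only gene models: one transcript per model,
no UTRs, no alternative isoforms. Coordinates are GFF3-style (1-based,
inclusive) at every public interface; bedGraph input is converted from
its native 0-based half-open convention at the I/O boundary. RNA-Seq
evidence is assumed non-strand-specific: splice junctions are intron
intervals matched to models by coordinates alone, and coverage is a
single per-base depth track per contig.

## The scoring flow

A candidate model passes through ordered gates; the first failure
determines both its score (0) and its diagnostic status.

1. **Translation.** The spliced CDS must be divisible by 3, start with
   ATG, end with a stop codon (the stop is included in the terminal CDS
   interval, matching the GFF conventions of the usual fungal
   predictors; the protein excludes it), contain no internal stop, and
   carry at most 8 N bases. Failures: `cannot_translate`.
2. **Protein length.** Proteins under 150 aa score 0
   (`short_protein`) unless the model has an intron or at least one
   significant BLASTp hit (default E ≤ 1e-5); rescued models still fail
   below 50 aa. The rescue heuristics reflect that short spurious ORFs
   are the dominant false-positive class in compact genomes.
3. **Intron structure.** Each intron must use GT-AG, GC-AG or AT-AC
   (read on the coding strand) and be 10–2000 bp long; any violation
   zeroes the model (`bad_intron_structure`). Abutting CDS intervals
   are treated as the same structural failure.
4. **Low-coverage bypass.** A transcript whose median exonic depth is
   below 10 cannot be tested against coverage continuity or junction
   usage. It receives `0.6 · Π I_i · Π H_e` — homology and intron
   evidence only, down-weighted by the low-coverage penalty factor so
   that it competes honestly with detailed scores during selection.
   Such models are accepted-eligible whenever their score is non-zero,
   and are flagged `low_coverage` in the score report. The per-exon
   homology baseline (H_e ≥ 1) is kept in the bypass product, so an
   intronless model with no hits still scores 0.6 rather than 0.
5. **Coverage continuity.** With adequate median depth, a maximal run
   of consecutive exonic bases below `0.05 × transcript mean depth`
   longer than 10 bases, or any exon whose mean depth leaves
   `[0.15, 3] × transcript median` (inclusive bounds), rejects the
   model (`coverage_error`). Depth summaries use the multiset of
   exonic per-base depths, not per-exon averages of averages.
6. **Detailed scoring.** `V_t = Π I_i · Π V_x(e)` with
   `V_x(e) = H_e · R_left · R_mid · R_right`. A model matches the
   RNA-Seq data iff `V_t ≥ 0.5`; a representative below the threshold
   (through boundary penalties or zeros) is `intron_error`.

### Boundary factors

Junction bonuses and penalties are functions of the junction's
read-through ratio `rt = mean intronic depth / (mean + spliced reads)`.
The default forms are linear — `reward(rt) = 2(1−rt)`,
`penalty(rt) = rt` — chosen as the plainest reading consistent with the
required endpoints (reward 2 and penalty 0 at rt = 0, reward → 0 and
penalty → 1 as rt → 1). An `exponential` alternative
(`2^(1−rt)`, `1−(1−rt)²`) is available behind
`boundary_score_form`; both forms agree at rt = 0 and share the same
monotonicity, so every test that depends on the shape declares the form.

Since junctions are strand-agnostic, the factors are evaluated in
genomic orientation, and the "initial/terminal exon" exemptions apply
to the genomically outermost boundaries of the transcript span. For a
plus-strand model these are exactly the initial and terminal exons; for
a minus-strand model the mapping is reversed, which is the only reading
under which the 5′-most exon of either strand is exempt at its
transcript-outer edge.

For a non-exempt left boundary the search window is junctions ending
within `[transcript start, exon end]`: a junction ending exactly one
base before the exon start is *matched* (reward); otherwise the
*nearest* junction in the window is penalised — nearest by distance of
its matched endpoint, ties broken by higher spliced-read count, then
leftmost, so the choice is deterministic. An empty window scores 0:
the model predicts splicing where none was observed upstream at all.
Right boundaries mirror this. `R_mid` multiplies the penalties of
every junction completely contained in the exon (a retained-intron
signal); the product is the conservative extension of the
single-junction definition to multiple contained junctions.

### Homology

Each hit contributes
`H_it = norm · (Matches + Similarities) / (2 · Len)`, with `norm =
1/max_homologs` by default, capped at the top `max_homologs = 3` hits
by bit score (ties by subject id). `Len` is the reported alignment
length — the only per-hit length in BLAST tabular output consistent
with "fraction of matching and similar residues". The aligned query
protein span is mapped ×3 into CDS coordinates and intersected with
each exon's CDS interval, so `Σ_e (H_e − 1)·|e|` conserves
`H_it · |B_i ∩ CDS|` exactly. With the default normalisation
`1 ≤ H_e ≤ 2`. An `unnormalized` switch drops the `1/max_homologs`
factor; it exists because the two readings cannot be distinguished from
the score definition alone, and keeping both testable was judged safer
than hard-wiring one.

## Selection

Overlap groups are the transitive closure of genomic-span overlap,
strand-blind (cross-strand overlaps must also be resolved, since
non-strand-specific coverage cannot separate them). Within a group,
weighted-interval-scheduling DP maximises the summed *effective score*
`V_t + 0.0001 × span length`. The pseudoscore basis is the full
genomic span (exons + introns) — the reading that makes "prefer the
longest zero-scoring model" literal; an `exonic` basis is available
behind `pseudoscore_basis`. Zero-scoring models are thus selected
wherever nothing better overlaps them, which is deliberate: they become
imperfect representatives that flag evidence of a gene even when no
candidate passes.

The DP keeps *all* exactly-tying optimal chains (exact float equality;
a cap of 10⁴ chains guards pathological inputs) and defers their
resolution to a final seeded pass over the genome: survivors are taken
in order of decreasing effective score, greedily keeping each model
that overlaps no already-kept model, with exact ties ordered by a
seeded random draw. The output is non-overlapping and byte-reproducible
for a fixed seed. Redundant pooled prediction sets are preselected by
the same group-and-chain machinery before entering the main selection,
which keeps the main DP's groups small.

## Evaluation machinery

Gene-level matching compares strand plus the full ordered CDS
coordinate list (*fixed* mode). *Flexible* mode additionally accepts a
pair that becomes identical when the coding-start boundary of the first
coding exon is ignored, provided the shift is a multiple of 3; for
minus-strand models the biological coding start is the genomic right
boundary, and that is what is relaxed. A reference model is credited
at most once (greedy one-to-one assignment in coordinate order).
Exon-level matching compares (contig, strand, class, start, end)
tuples — class-aware, so a single-exon prediction cannot claim an
initial exon — with flexible mode masking the coding-start coordinate
of initial and single exons. Sensitivity and specificity may use
different reference sets (e.g. a high-confidence subset for
sensitivity, the full annotation for specificity). Model-to-set
similarity is reported in four exclusive categories (identical /
identical-except-start / >5% / <5% CDS-base overlap) that partition
any input set. Read-depth binning uses left-closed bins at
0.05, 0.1, 0.5, 1, 2, 4 reads per exonic base.

## Parameters

| parameter | default | units / note |
|---|---|---|
| max_homologs | 3 | hits kept per protein |
| acceptable_donor_acceptor | GT-AG, GC-AG, AT-AC | coding strand |
| min/max_intron | 10 / 2000 | bp |
| min_protein_aa | 150 | aa; rescue floor 50 aa |
| low_median_cutoff | 10 | reads/base; bypass below |
| low_coverage_penalty | 0.6 | multiplies bypass score |
| exon_depth_range | 0.15–3.0 | × transcript median, inclusive |
| max_low_run_len | 10 | bases |
| low_run_threshold_frac | 0.05 | × transcript mean |
| max_n_per_transcript | 8 | N bases |
| match_threshold | 0.5 | on V_t |
| pseudoscore_per_base | 0.0001 | per span base |
| island_min_depth / island_min_len | 3 / 100 | reads/base, bp |
| evalue_cutoff | 1e-5 | hit significance |

These defaults target ascomycete/basidiomycete genomes; other organisms
will need retuning, particularly the intron length caps and the
protein-length floor.

## Synthetic data: what it emulates, what it does not

The generator plants non-overlapping multi-exon genes (default 50;
2–5 codon-aligned exons; proteins 170–400 aa, leaving headroom over the
150-aa gate after a 10-codon start shift; GT-AG introns of 40–100 bp;
intergenic gaps 300–800 bp) on one contig per 25 loci, with uniform
exonic depth 50, intronic depth `read_through × 50`, and spliced counts
`(1 − read_through) × 50`, so junction read-through ratios are exact by
construction (default 0: clean splicing). Sequence planting (an
in-frame ATG at codon 10, a GT..AG segment at codons 12–21, a
`GTCGT...AG` first intron followed by an AAG codon) guarantees that
every corruption type yields a structurally parseable variant that
provably loses at least one score factor: start shifts lose only span
length (pseudoscore breaks the tie toward the truth model), shifted and
fabricated introns lose a boundary factor (penalty(0) = 0 under clean
junctions), dropped introns lose coverage continuity or R_mid, fusions
acquire an internal stop or an unsupported junction gap, truncations
lose the stop codon. Truth models are always retained in the candidate
pool; corruptions are applied to copies, mirroring the redundancy of a
pooled prediction stage. A configurable fraction of genes receives 1–3
perfect full-length BLASTp hits, shared with each translatable variant
against its own protein so homology support is proportionate and cannot
flip a selection.

Truth-free "lone" constructs exercise the imperfect statuses that
overlap-corruptions can never reach (a variant overlapping its truth
gene always loses selection): an ORF with an internal 20-base coverage
gap (`coverage_error`), a 100-aa intronless hit-less ORF
(`short_protein`), and a two-exon gene whose junction is observed 3 bp
away from its predicted intron (`intron_error`).

What the fixtures do **not** emulate: sequencing noise and non-uniform
library coverage, strand-specific signal, overlapping or nested real
genes, alternative isoforms, soft intron-length distributions, and
homology hits with realistic partial identity. Passing the
planted-truth tests therefore demonstrates that the score factors,
gates and selection interact as specified — not that the default
thresholds are optimal for any particular real genome.

## Numerical and procedural choices

* All products use exact float multiplication; chain-tie detection uses
  exact equality, which is intentional — ties arise from byte-identical
  duplicated models, not numerical coincidence.
* The DP-vs-enumeration oracle compares totals at 1e-9 absolute
  tolerance, covering summation-order effects only.
* Intron donor/acceptor of a 1-base intron degenerates to the single
  base; such introns fail the length gate regardless.
* `transcript_depth_stats` on a zero-coverage model yields mean =
  median = 0: the model takes the bypass path, never a division by
  zero; `exon_depth_in_range` requires a positive median and is only
  called on the detailed path.
* Scoring is order-invariant (each model is scored independently) and
  the pipeline is deterministic end-to-end for a fixed seed; the run
  log carries the config hash, seed and input checksums, and no output
  file contains timestamps.
* Problem sizes in tests and the acceptance script (50-gene fixtures,
  500 DP oracle trials with ≤ 12 members) were chosen so the whole
  verification suite completes in seconds while still covering every
  corruption type, both strands, multiple contigs and all five
  diagnostic statuses.

## Known limitations

* Start-codon choice among in-frame ATGs is not modelled; the flexible
  evaluation mode exists precisely because this is the dominant
  near-miss class.
* Low-coverage loci are scored on homology and intron structure alone;
  with no hits and valid introns the bypass score is a flat 0.6, so
  selection among such models degenerates to the pseudoscore.
* Junction evidence is strand-blind; antisense transcription can
  inflate apparent read-through and coverage.
* `R_left`/`R_right` windows extend to the transcript span ends, so a
  junction belonging to a neighbouring gene inside a fused model's span
  influences its penalty — intended for fusion detection, but it means
  boundary scores are not purely local to the exon.
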