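#!/bin/sh
# End-to-end shell workflow: simulate a dataset, classify its candidate
# models, and evaluate the accepted set against the planted truth.
set -e

WORK=$(mktemp -d)

genesift simulate --seed 5 --n-genes 10 --out-dir "$WORK/fixture"

genesift classify \
    --genome    "$WORK/fixture/genome.fa" \
    --models    "$WORK/fixture/candidates.gff3" \
    --junctions "$WORK/fixture/junctions.tsv" \
    --coverage  "$WORK/fixture/coverage.bedgraph" \
    --hits      "$WORK/fixture/hits.tsv" \
    --seed 5 \
    --out-dir   "$WORK/run"

genesift compare \
    --predictions "$WORK/run/accepted.gff3" \
    --reference   "$WORK/fixture/truth.gff3" \
    --mode fixed --out -

rm -rf "$WORK"
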