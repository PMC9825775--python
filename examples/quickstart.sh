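#!/bin/sh
# Quickstart: build a small synthetic pooled BAM, then run a command per cell.
#
# Prints one flagstat summary per cell to per-cell files, demonstrating the
# batch structure (4 cells, batch size 2 -> 2 passes) and the {} / {BARCODE}
# template tokens. Everything is generated; no external data needed.
set -eu
workdir=$(mktemp -d)
trap 'rm -rf "$workdir"' EXIT
cd "$workdir"

percell fixtures -o pooled.bam --barcodes 4 --reads 25 --seed 11 --unbarcoded 0.1

mkdir flagstats
percell -i pooled.bam -b starsolo -B 2 -j 2 \
    -O 'flagstats/{BARCODE}.txt' \
    -C 'samtools flagstat {}'

echo "--- per-cell primary-read counts ---"
# each cell contributes exactly 25 reads; unbarcoded reads belong to no cell
for f in flagstats/*.txt; do
    printf '%s: %s\n' "$(basename "$f" .txt)" "$(head -1 "$f")"
done
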