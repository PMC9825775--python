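#!/bin/sh
# Per-cell expressed-SNV calling: the analysis this engine was built to drive.
#
# DOCUMENTED EXAMPLE ONLY — requires a real pooled scRNA-seq BAM (STARsolo/
# CellRanger output), a reference FASTA, and GATK; none are bundled here.
#
# The engine extracts one indexed scBAM per accepted cell and runs this
# whole pipeline-in-a-shell on it: HaplotypeCaller on the cell's reads,
# then bcftools quality filtering, yielding one VCF per cell barcode.
# Variants with low allele frequency in the pooled data — post-zygotic
# mutations, RNA editing — that pooled-data callers discard become callable
# at the single-cell level. Cells of interest can be re-run with a file
# template (-F) and a region restriction (-r) to keep their scBAMs for
# inspection, e.g. in a genome browser.
#
# Usage:
#   ./sce_snv_calling.sh pooled.bam barcodes.tsv reference.fa outdir
set -eu
POOLED=$1; ACCEPT=$2; REF=$3; OUT=$4
mkdir -p "$OUT"

percell -i "$POOLED" -b starsolo -L "$ACCEPT" \
    --index -B 150 -j 8 \
    -E "$OUT/{BARCODE}.log" \
    -C "gatk HaplotypeCaller -R $REF -I {} -O $OUT/{BARCODE}.raw.vcf.gz \
        && bcftools view -i 'QUAL>=30 && FORMAT/DP>=5' \
             -O z -o $OUT/{BAMBASE}.{BARCODE}.vcf.gz $OUT/{BARCODE}.raw.vcf.gz \
        && rm $OUT/{BARCODE}.raw.vcf.gz"
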