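# percell

Run a shell command on every cell of a pooled single-cell RNA-seq BAM.

Droplet scRNA-seq pipelines (CellRanger, STARsolo, UMI-tools) emit one
aggregated, coordinate-sorted BAM in which reads from thousands of cells are
distinguishable only by their cell barcode — a tag (`CB` corrected, `CR`
raw) or a token embedded in the read name. Most of the sequencing toolbox
(variant callers, coverage tools, splice analyses) was built for bulk data
and expects one BAM per sample. `percell` bridges the two: it streams the
pooled BAM, extracts single-cell BAMs ("scBAMs") in batches, and executes a
user-supplied shell command on each one, in the style of `find`/`xargs` —
enabling per-cell variant calling, allele-specific expression, or any other
cell-level analysis with unmodified bulk tools. The motivating use case is
calling single-cell-specific expressed SNVs, which pooled-data variant
callers discard as low-frequency noise.

## How it works

For n accepted barcodes and batch size B, the engine makes exactly
⌈n/B⌉ sequential scans of the pooled file. Each scan writes the scBAMs of
one batch of barcodes (header preserved verbatim, records in input order, so
sorted input yields sorted scBAMs); with no acceptance list, barcode
discovery is folded into the first scan. As soon as a batch's scBAMs are
written, its jobs are handed to a pool of at most P concurrent shell
commands while the next scan proceeds — so for commands slower than a scan,
total runtime approaches first-scan time plus serialized job time divided
by P, and memory and open file handles stay bounded by the batch, not by
the number of cells. Each scBAM's lifecycle is managed end to end:
creation, optional `samtools`-style indexing, command execution, deletion
(unless a filename template asks to keep them).

Command templates use `find`/`xargs` substitution: `{}` is the scBAM path,
`{BARCODE}` the cell barcode, `{BAMBASE}` the input BAM name without path or
`.bam`. A template with no token gets the scBAM path appended. Commands run
in a shell, so pipes, multi-command scripts and redirection work as usual.
Runs can be restricted to an acceptance list (e.g. STARsolo `barcodes.tsv`),
to genomic regions (samtools strings or BED), or to the first k barcodes.

## Worked example

Generate a small synthetic pooled BAM (4 cells × 25 reads plus 10%
unbarcoded reads) and count each cell's reads:

```sh
$ percell fixtures -o pooled.bam --barcodes 4 --reads 25 --seed 11 --unbarcoded 0.1
percell fixtures: wrote pooled.bam: 4 barcode(s), 100 assigned, 11 unbarcoded, 0 sentinel record(s)

$ mkdir counts
$ percell -i pooled.bam -b starsolo -B 2 -j 2 \
    -O 'counts/{BARCODE}.txt' -C 'samtools view -c {}'
percell: 2 pass(es), 4 barcode(s), 4 job(s) launched, 4 succeeded, 0 failed, 0 empty barcode(s) skipped

$ for f in counts/*; do echo "$f: $(cat $f)"; done
counts/AATCGGGACACT.txt: 25
counts/CGTCTACTAGCG.txt: 25
counts/GAGATTTGTCAG.txt: 25
counts/TTTGTTAACGTC.txt: 25
```

Two passes because 4 barcodes at batch size 2 need ⌈4/2⌉ scans; each cell's
scBAM contains exactly its 25 reads (the 11 unbarcoded reads are counted but
never assigned), the per-job `-O` stdout template wrote one count file per
cell, and every scBAM was deleted after its job finished.

The same engine is available as a library:

```python
from percell import RunConfig, run_pipeline

summary = run_pipeline(RunConfig(
    input_bam="pooled.bam",
    barcode_source="starsolo",          # CB tag; also tag:XX, qname:_:-2, regex:...
    command_template="samtools view -c {}",
    batch_size=100,
))
print(summary.jobs_succeeded, summary.stats.assigned)
```

`examples/` contains short narrative scripts, including the per-cell
GATK/Strelka2 variant-calling command script this engine was designed to
drive.

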