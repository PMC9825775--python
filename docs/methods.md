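# Methods

## The problem and the procedure

A pooled droplet scRNA-seq BAM interleaves the reads of thousands of cells,
distinguishable only by cell barcode. `percell` partitions that stream into
per-cell BAMs (scBAMs) and runs one shell command per scBAM, so tools built
for one-sample BAMs can be applied per cell.

The engine is a producer/consumer scheduler:

1. **Planning.** The accepted barcodes are fixed either by an acceptance
   list (file order, duplicates dropped keeping the first, optionally
   truncated to a limit) or by discovery — the distinct extractable
   barcodes in order of first appearance in the (region-restricted) stream.
   The ordered list is partitioned into consecutive batches of at most B
   barcodes, giving ⌈n/B⌉ batches.
2. **Extraction (producer, main thread).** One sequential scan of the
   pooled BAM per batch. Each in-scope record is classified once —
   assigned / unbarcoded / rejected by the acceptance policy / outside the
   regions — and assigned records of batch barcodes are appended to lazily
   opened per-barcode writers that share the input header object. Discovery
   is folded into scan 1: first-seen indices are assigned online, records
   of indices < B are written immediately, the rest of the order is
   memorized, so discovery costs no extra pass and the run performs exactly
   ⌈n/B⌉ scans. At most one scan is active at any time.
3. **Execution (consumers).** After a batch's writers close, one job per
   emitted scBAM is submitted to a thread pool of size P; each worker
   optionally indexes the scBAM, launches the rendered command via the
   shell, waits, and deletes the scBAM (and index) after the process has
   exited unless a filename template keeps it. The main thread immediately
   starts the next scan, so extraction of batch i+1 overlaps execution of
   batch i; all jobs are joined before the run summary is returned.

Per-batch state is bounded by the current batch: records stream directly to
at most B open scBAM writers, never into RAM, so memory and file-handle use
grow with B, not with the number of cells.

## Barcode extraction rules

Three rule kinds cover the common pipelines: a 2-character BAM tag
(`CB` corrected / `CR` raw for CellRanger and STARsolo), a delimited QNAME
token (0-based index, negatives from the right; the UMI-tools
`NAME_CELLBARCODE_UMI` convention is delimiter `_`, index −2), and a regular
expression with exactly one capturing group. An absent tag, out-of-range
index, non-match, empty value, or the `-` sentinel STARsolo writes for
unassigned reads all mean *unbarcoded* — counted, never fatal, and never
turned into a garbage pseudo-cell. Barcodes are matched as exact strings;
the CellRanger `-1` GEM-well suffix is deliberately not stripped, keeping
behavior lossless and acceptance lists from the same pipeline directly
usable. No whitelist correction or UMI handling is attempted.

## Accounting and its invariants

`DemuxStats` proves the partition lossless:
`total = assigned + unbarcoded + rejected + outside_regions` and
`assigned = Σ per-barcode counts = Σ scBAM record counts` over the run.
Classification precedence is regions → barcode → acceptance policy; the
order matters because in index-fetch region mode out-of-region records are
never visited (their count comes from the index statistics), and it makes
the four-way split well defined. Run-level stats are collected on scan 1,
which always visits the full in-scope stream and classifies against the
full accepted set (not just batch 1); later scans re-read but do not
re-count. Records cut off by `--limit` fall in the rejected bucket — the
limit acts as an implicit acceptance policy.

## Regions

Inputs are samtools strings (1-based inclusive) or BED (0-based half-open),
normalized to 1-based inclusive, validated against the BAM header, sorted
in header contig order and merged when overlapping or adjacent. Overlap is
samtools fetch semantics: any overlap of the reference-aligned span;
unmapped records are excluded in region mode and included (if barcoded)
otherwise. With an index the scan fetches each merged region, skipping
records already yielded by an earlier region on the same contig (a long
record can span two disjoint merged regions); without one it falls back to
a linear scan filter. The two paths are tested to yield identical record
sequences. The standalone barcode-enumeration operation refuses
region-restricted discovery on an unindexed BAM and tells the user to index.

## Output contract

scBAM headers are the input header verbatim — no @PG provenance line is
appended — so header equality is exact and downstream provenance parsing is
unaffected. Record order within each scBAM is a subsequence of the input
stream, hence coordinate-sorted input gives coordinate-sorted, indexable
scBAMs. Secondary/supplementary/duplicate flags pass through untouched;
filtering policy belongs to the user's command. Default scBAM names are
`{BAMBASE}.{BARCODE}.bam` in a run-scoped scratch directory, with barcode
text sanitized to `[A-Za-z0-9._-]` (collisions after sanitization are an
error, not silent merging). Acceptance-listed barcodes absent from the BAM
produce no scBAM and no job by default; `--emit-empty` writes header-only
scBAMs and schedules their jobs for consumers that need one output per
listed cell.

## Execution policies

Commands run via the shell in an optional per-job working directory, with
optional per-job stdout/stderr files (templates rendered per barcode;
relative paths resolve against the launch directory). A nonzero exit is
recorded and the run continues — per-cell analyses routinely fail on sparse
cells and one bad cell must not kill thousands of jobs; `--fail-fast` opts
into launching nothing new after the first failure. The tool's own exit
status is 0 unless a fatal error occurred (or `--fail-fast` tripped);
2 marks usage/configuration errors. An extraction error aborts scheduling
of later batches, waits for in-flight jobs, and surfaces in the summary's
fatal status. A structured JSON-lines event log (scan start/end, job
start/end/skip with timestamps) makes the scheduling contracts — pass
count, single active scan, overlap, concurrency cap — directly observable.

## Synthetic data generator

The fixture generator emulates exactly the features of pooled scRNA-seq
BAMs that extraction can observe: a coordinate-sorted stream in which reads
of different cells interleave along the genome (round-robin with per-round
shuffling, so batch extraction genuinely must skip other cells' records),
barcodes encoded as CB/CR/custom tags, UMI-tools-style read names, or both
at once, plus configurable fractions of unbarcoded and `-`-sentinel reads.
Positions increase monotonically along concatenated contigs with jittered
spacing; every record is a fixed-length single-M match with constant
qualities and deterministic pseudo-random sequence — alignment content is
irrelevant to barcode stratification, and determinism (same spec + seed ⇒
byte-identical BAM) enables byte-level tests. It does not model sequencing
error, UMIs, spliced or multi-mapped alignments, or expression structure,
so passing tests demonstrate correct stream partitioning and scheduling on
real-shaped inputs, not robustness to aligner quirks beyond the barcode
conventions modeled.

Default study conditions for end-to-end checks are 50 cells × 200 reads
with 10% unbarcoded and 5% sentinel reads on two 100 kb contigs — large
enough that batching (batch size 20, ⌈50/20⌉ = 3 passes) and interleaving
are exercised, small enough to verify every scBAM against two independent
oracles (a naive one-barcode linear filter, and `samtools view -d` in tag
mode) in seconds. Scheduling tests use 1–100 cells with batch sizes 1–1000
and deliberately slow (`sleep`) commands to expose overlap and the
concurrency cap via job-recorded timestamps.

## Numerical and degenerate-input choices

- Batch size defaults to 100: around 100–200 scBAMs per pass is typically
  enough to keep the job-execution processors busy; job count defaults to
  the processor count.
- Template substitution is plain text replacement with no escape syntax, so
  a literal `{}` cannot appear in a command; the rule that *any* token
  (`{}`, `{BARCODE}`, `{BAMBASE}`) suppresses appending the scBAM path
  reads the no-token convention literally.
- `bambase` strips only the final, case-sensitive `.bam` extension.
- Zero accepted barcodes: an empty acceptance list is a configuration
  error; discovery finding nothing still costs the one scan needed to learn
  that, then launches no jobs.
- Indexing (`--index`) is refused up front unless the input header says
  `SO:coordinate`, since scBAMs inherit the input's ordering.
- Restart determinism: identical input and configuration give identical
  scBAM contents and file sets regardless of P and B; only event timing
  varies.

## Known limitations

No CRAM support, re-sorting or re-heading; no barcode error correction; no
cluster/scheduler submission or retries — the tool is deliberately a thin
alternative to a workflow manager and can be called from one. Paths
containing shell metacharacters inside user templates are the user's
responsibility (commands run in a shell by design); the default scBAM names
are shell-safe.
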