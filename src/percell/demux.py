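"""Streaming batch extraction of single-cell BAMs from a pooled barcoded BAM.

The pooled file is scanned once per batch of barcodes; each scan writes one
scBAM per batch barcode.  scBAMs keep the input header verbatim (no @PG line
is appended) and their records in input-stream order, so a coordinate-sorted
input yields coordinate-sorted scBAMs.  The engine filters records only by
barcode and genomic region — secondary, supplementary and duplicate-flagged
records pass through untouched; filtering policy belongs to the user's
command.

:class:`DemuxStats` gives read accounting that proves the partition is
lossless: every scanned record is classified exactly once as assigned,
unbarcoded, rejected by the acceptance policy, or outside the regions.
"""

from __future__ import annotations

import gzip
import math
import os
import re
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import pysam

from .barcodes import BarcodeSpec, extract_barcode
from .errors import ConfigurationError, ExtractionError
from .regions import (
    Region,
    iter_region_records,
    record_overlaps,
    total_record_count,
)
from .templating import TemplateContext, bambase_of, render

#: Default scBAM filename template inside the run-scoped scratch directory.
DEFAULT_SCBAM_TEMPLATE = "{BAMBASE}.{BARCODE}.bam"

_UNSAFE_CHARS = re.compile(r"[^A-Za-z0-9._-]")

PathLike = Union[str, os.PathLike]


@dataclass
class DemuxStats:
    """Read-accounting counters for one classification pass.

    Invariants: ``total_records = assigned + unbarcoded +
    rejected_by_acceptlist + outside_regions`` and ``assigned`` equals the
    sum of the per-barcode counts.
    """

    total_records: int = 0
    assigned: int = 0
    unbarcoded: int = 0
    rejected_by_acceptlist: int = 0
    outside_regions: int = 0
    per_barcode: Dict[str, int] = field(default_factory=dict)

    @property
    def consistent(self) -> bool:
        return (
            self.total_records
            == self.assigned
            + self.unbarcoded
            + self.rejected_by_acceptlist
            + self.outside_regions
        ) and self.assigned == sum(self.per_barcode.values())


@dataclass(frozen=True)
class BatchPlan:
    """Order-preserving partition of barcodes into consecutive batches."""

    barcodes: Tuple[str, ...]
    batch_size: int
    batches: Tuple[Tuple[str, ...], ...]


def plan_batches(barcodes: Sequence[str], batch_size: int) -> BatchPlan:
    """Partition barcodes into consecutive groups of at most ``batch_size``.

    The number of batches is ``ceil(n / batch_size)``; all but possibly the
    last have exactly ``batch_size`` members.
    """
    if batch_size < 1:
        raise ConfigurationError(f"batch size must be >= 1, got {batch_size}")
    barcodes = tuple(barcodes)
    batches = tuple(
        barcodes[i : i + batch_size] for i in range(0, len(barcodes), batch_size)
    )
    assert len(batches) == math.ceil(len(barcodes) / batch_size)
    return BatchPlan(barcodes=barcodes, batch_size=batch_size, batches=batches)


def read_barcode_list(path: PathLike) -> List[str]:
    """Read a barcodes.tsv-style acceptance list (plain or gzip).

    One barcode per line, file order kept, duplicates dropped keeping the
    first occurrence, blank lines skipped.
    """
    with open(path, "rb") as raw:
        magic = raw.read(2)
    opener = gzip.open if magic == b"\x1f\x8b" else open
    seen: Dict[str, None] = {}
    with opener(path, "rt") as fh:
        for line in fh:
            barcode = line.strip()
            if barcode:
                seen.setdefault(barcode, None)
    if not seen:
        raise ConfigurationError(f"acceptance list {path} contains no barcodes")
    return list(seen)


def sanitize_barcode(barcode: str) -> str:
    """Make a barcode safe for use inside a filename."""
    return _UNSAFE_CHARS.sub("_", barcode)


def plan_scbam_paths(
    barcodes: Sequence[str],
    bambase: str,
    name_template: str = DEFAULT_SCBAM_TEMPLATE,
    base_dir: Optional[PathLike] = None,
) -> Dict[str, str]:
    """Render the scBAM filename template for each barcode.

    The barcode is sanitized (characters outside ``[A-Za-z0-9._-]`` become
    ``_``) before substitution; a collision between sanitized names is an
    error rather than silent data loss.
    """
    paths: Dict[str, str] = {}
    reverse: Dict[str, str] = {}
    for barcode in barcodes:
        ctx = TemplateContext(
            scbam_path="", barcode=sanitize_barcode(barcode), bambase=bambase
        )
        path = render(name_template, ctx)
        if base_dir is not None and not os.path.isabs(path):
            path = os.path.join(os.fspath(base_dir), path)
        if path in reverse:
            raise ConfigurationError(
                f"scBAM filename collision after sanitization: barcodes "
                f"{reverse[path]!r} and {barcode!r} both map to {path}"
            )
        reverse[path] = barcode
        paths[barcode] = path
    return paths


class ScbamWriterSet:
    """Lazily opened per-barcode scBAM writers sharing the input's header.

    ``paths`` is either a mapping barcode -> file path or a callable doing
    the same (so paths can be planned lazily during barcode discovery).
    """

    def __init__(
        self,
        template_af: pysam.AlignmentFile,
        paths: Union[Dict[str, str], Callable[[str], str]],
    ):
        self._template = template_af
        self._path_for = paths if callable(paths) else paths.__getitem__
        self._opened: Dict[str, str] = {}
        self._writers: Dict[str, pysam.AlignmentFile] = {}
        self.counts: Dict[str, int] = {}

    def write(self, barcode: str, rec: pysam.AlignedSegment) -> None:
        writer = self._writers.get(barcode)
        if writer is None:
            writer = self._open(barcode)
        writer.write(rec)
        self.counts[barcode] = self.counts.get(barcode, 0) + 1

    def ensure_open(self, barcode: str) -> None:
        """Force a (possibly header-only) scBAM for this barcode."""
        if barcode not in self._writers:
            self._open(barcode)
            self.counts.setdefault(barcode, 0)

    def _open(self, barcode: str) -> pysam.AlignmentFile:
        path = self._path_for(barcode)
        parent = os.path.dirname(path)
        if parent:
            os.makedirs(parent, exist_ok=True)
        writer = pysam.AlignmentFile(path, "wb", template=self._template)
        self._writers[barcode] = writer
        self._opened[barcode] = path
        return writer

    def close(self) -> Dict[str, str]:
        """Close all writers; return barcode -> path for files actually written."""
        for writer in self._writers.values():
            writer.close()
        return dict(self._opened)


def scan_records(
    af: pysam.AlignmentFile,
    regions: Optional[Sequence[Region]],
    on_record: Callable[[pysam.AlignedSegment], None],
    use_index: Optional[bool] = None,
) -> Tuple[int, int]:
    """One pass over ``af`` restricted to merged ``regions``.

    Calls ``on_record`` for every in-region record, in stream order, and
    returns ``(visited, outside)`` where ``outside`` counts records whose
    aligned span overlaps no region (unmapped records count as outside in
    region mode).  With an index the out-of-region records are never read;
    their count comes from the index statistics.
    """
    try:
        if not regions:
            visited = 0
            for rec in af.fetch(until_eof=True):
                visited += 1
                on_record(rec)
            return visited, 0
        if use_index is None:
            use_index = af.has_index()
        if use_index:
            inside = 0
            for rec in iter_region_records(af, regions, use_index=True):
                inside += 1
                on_record(rec)
            return inside, total_record_count(af) - inside
        inside = outside = 0
        for rec in af.fetch(until_eof=True):
            if record_overlaps(rec, regions):
                inside += 1
                on_record(rec)
            else:
                outside += 1
        return inside, outside
    except OSError as exc:
        raise ExtractionError(
            f"I/O error while streaming {af.filename!r}: {exc}"
        ) from exc


def demux_batch(
    bam: PathLike,
    batch: Sequence[str],
    spec: BarcodeSpec,
    out_dir: PathLike,
    regions: Optional[Sequence[Region]] = None,
    name_template: Optional[str] = None,
    emit_empty: bool = False,
    use_index: Optional[bool] = None,
) -> Tuple[Dict[str, str], DemuxStats]:
    """Extract one batch of barcodes from the pooled BAM in a single scan.

    Returns ``(paths, stats)`` where ``paths`` maps each batch barcode that
    produced an scBAM to its file.  By default a batch barcode with zero
    assigned records yields no file; ``emit_empty`` writes a header-only
    scBAM instead.  Records carrying a barcode outside the batch count as
    ``rejected_by_acceptlist``.
    """
    batch = list(batch)
    if not batch:
        raise ConfigurationError("demux_batch requires a non-empty batch")
    out_dir = os.fspath(out_dir)
    if not os.path.isdir(out_dir) or not os.access(out_dir, os.W_OK):
        raise ExtractionError(f"output directory {out_dir!r} is not writable")
    planned = plan_scbam_paths(
        batch,
        bambase_of(os.fspath(bam)),
        name_template or DEFAULT_SCBAM_TEMPLATE,
        base_dir=out_dir,
    )
    accept = set(batch)
    stats = DemuxStats()
    with pysam.AlignmentFile(os.fspath(bam), "rb") as af:
        writers = ScbamWriterSet(af, planned)

        def on_record(rec: pysam.AlignedSegment) -> None:
            barcode = extract_barcode(rec, spec)
            if barcode is None:
                stats.unbarcoded += 1
            elif barcode in accept:
                stats.assigned += 1
                stats.per_barcode[barcode] = stats.per_barcode.get(barcode, 0) + 1
                writers.write(barcode, rec)
            else:
                stats.rejected_by_acceptlist += 1

        visited, outside = scan_records(af, regions, on_record, use_index=use_index)
        stats.outside_regions = outside
        stats.total_records = visited + outside
        if emit_empty:
            for barcode in batch:
                writers.ensure_open(barcode)
        paths = writers.close()
    return paths, stats


def enumerate_barcodes(
    bam: PathLike,
    spec: BarcodeSpec,
    acceptlist: Optional[Sequence[str]] = None,
    regions: Optional[Sequence[Region]] = None,
    limit: Optional[int] = None,
) -> List[str]:
    """Determine the ordered barcodes a run will process.

    With an acceptance list, returns it in file order (presence in the BAM is
    not checked at this stage), truncated to ``limit``.  Otherwise returns
    the distinct extractable barcodes in order of first appearance in the
    (region-restricted) stream, truncated to ``limit``.
    """
    if acceptlist is not None:
        ordered = list(dict.fromkeys(acceptlist))
        return ordered[:limit] if limit is not None else ordered
    seen: Dict[str, None] = {}
    with pysam.AlignmentFile(os.fspath(bam), "rb") as af:
        if regions and not af.has_index():
            raise ConfigurationError(
                "region-restricted barcode discovery needs a BAM index; "
                "run `samtools index` on the input first"
            )
        for rec in iter_region_records(af, regions):
            barcode = extract_barcode(rec, spec)
            if barcode is not None and barcode not in seen:
                seen[barcode] = None
                if limit is not None and len(seen) >= limit:
                    break
    return list(seen)


def index_scbam(path: PathLike) -> str:
    """Index a coordinate-sorted scBAM; return the BAI path."""
    path = os.fspath(path)
    with pysam.AlignmentFile(path, "rb") as af:
        so = (af.header.to_dict().get("HD") or {}).get("SO")
    if so != "coordinate":
        raise ConfigurationError(
            f"cannot index {path}: indexing requires a coordinate-sorted BAM "
            f"(header SO={so!r})"
        )
    pysam.index(path)
    return path + ".bai"
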