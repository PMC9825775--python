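"""Genomic region restriction.

Regions arrive either as samtools-style strings (``contig:start-end``,
1-based inclusive, or a bare ``contig`` for the whole sequence) or as a BED
file (3+ columns, 0-based half-open).  Internally everything is 1-based
inclusive.  Before use, regions are validated against the BAM header,
sorted in header contig order, and overlapping or adjacent intervals are
merged, so a record can never be emitted twice because the user's regions
overlapped.

Overlap follows samtools fetch semantics: any overlap of the record's
reference-aligned span counts; unmapped records are excluded in region mode.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Union

import pysam

from .errors import ConfigurationError

_REGION_RE = re.compile(r"^(?P<contig>[^:]+)(?::(?P<start>\d+)-(?P<end>\d+))?$")


@dataclass(frozen=True)
class Region:
    """A closed genomic interval, 1-based inclusive on both ends."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ConfigurationError(
                f"invalid region {self.contig}:{self.start}-{self.end}: "
                "need 1 <= start <= end"
            )

    def __str__(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}"


def _check_contig(contig: str, header: pysam.AlignmentHeader) -> int:
    tid = header.get_tid(contig)
    if tid < 0:
        raise ConfigurationError(
            f"contig {contig!r} is not present in the BAM header"
        )
    return tid


def parse_region_string(text: str, header: pysam.AlignmentHeader) -> Region:
    """Parse one samtools-dialect region string against a BAM header."""
    m = _REGION_RE.match(text.strip())
    if m is None:
        raise ConfigurationError(f"malformed region string: {text!r}")
    contig = m.group("contig")
    tid = _check_contig(contig, header)
    if m.group("start") is None:
        return Region(contig, 1, header.get_reference_length(contig))
    region = Region(contig, int(m.group("start")), int(m.group("end")))
    del tid
    return region


def read_bed(path: Union[str, os.PathLike], header: pysam.AlignmentHeader) -> List[Region]:
    """Read a BED file (0-based half-open) into 1-based inclusive regions."""
    regions: List[Region] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ConfigurationError(
                    f"{path}:{lineno}: BED line needs >= 3 columns: {line!r}"
                )
            contig, start0, end0 = fields[0], int(fields[1]), int(fields[2])
            _check_contig(contig, header)
            regions.append(Region(contig, start0 + 1, end0))
    return regions


def merge_regions(
    regions: Iterable[Region], header: pysam.AlignmentHeader
) -> List[Region]:
    """Sort regions in header contig order and merge overlapping/adjacent ones."""
    ordered = sorted(
        regions, key=lambda r: (_check_contig(r.contig, header), r.start, r.end)
    )
    merged: List[Region] = []
    for region in ordered:
        if (
            merged
            and merged[-1].contig == region.contig
            and region.start <= merged[-1].end + 1
        ):
            last = merged[-1]
            merged[-1] = Region(last.contig, last.start, max(last.end, region.end))
        else:
            merged.append(region)
    return merged


def parse_regions(
    spec: Union[str, os.PathLike], header: pysam.AlignmentHeader
) -> List[Region]:
    """Parse a region specification into merged, validated regions.

    ``spec`` is either a path to a BED file or a comma-separated list of
    samtools-style region strings.
    """
    if isinstance(spec, os.PathLike) or os.path.exists(spec):
        regions = read_bed(spec, header)
    else:
        regions = [parse_region_string(part, header) for part in str(spec).split(",")]
    if not regions:
        raise ConfigurationError(f"region specification {spec!r} yields no regions")
    return merge_regions(regions, header)


def record_overlaps(rec: pysam.AlignedSegment, regions: Sequence[Region]) -> bool:
    """True iff the record's reference-aligned span overlaps any region."""
    if rec.is_unmapped:
        return False
    start0, end0 = rec.reference_start, rec.reference_end
    if end0 is None:  # no CIGAR: treat as zero-length at start
        end0 = start0 + 1
    for region in regions:
        if (
            rec.reference_name == region.contig
            and start0 < region.end
            and end0 > region.start - 1
        ):
            return True
    return False


def iter_region_records(
    af: pysam.AlignmentFile,
    regions: Optional[Sequence[Region]],
    use_index: Optional[bool] = None,
):
    """Yield records of ``af`` restricted to merged ``regions``, in stream order.

    With no regions, yields every record (including unmapped) sequentially.
    With regions and an index (or ``use_index=True``), random-access fetch is
    used; a record spanning two disjoint merged regions is yielded only once.
    Without an index the whole file is scanned and filtered.  Both paths
    yield identical record sequences.
    """
    if not regions:
        yield from af.fetch(until_eof=True)
        return
    if use_index is None:
        use_index = af.has_index()
    if use_index:
        prev_end = {}  # contig -> 1-based inclusive end of previous merged region
        for region in regions:
            skip_before = prev_end.get(region.contig)
            for rec in af.fetch(region.contig, region.start - 1, region.end):
                # A long record overlapping the preceding disjoint region on
                # this contig was already yielded there.
                if skip_before is not None and rec.reference_start < skip_before:
                    continue
                yield rec
            prev_end[region.contig] = region.end
    else:
        for rec in af.fetch(until_eof=True):
            if record_overlaps(rec, regions):
                yield rec


def total_record_count(af: pysam.AlignmentFile) -> int:
    """Total records in an indexed BAM (mapped + unmapped + no-coordinate)."""
    stats = af.get_index_statistics()
    return sum(s.total for s in stats) + af.nocoordinate
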