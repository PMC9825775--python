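"""Synthetic barcoded BAM generation with a machine-readable truth table.

Emulates the pooled, coordinate-sorted output of droplet scRNA-seq
processing pipelines (CellRanger/STARsolo-style CB/CR tags, or the
UMI-tools ``NAME_CELLBARCODE_UMI`` read-name convention) well enough to
exercise every demultiplexing code path: reads from different cells are
interleaved along the genome (round-robin with shuffled order per round)
rather than blocked, so batch extraction genuinely has to skip other cells'
records; a configurable fraction of reads is unbarcoded or carries the
``-`` sentinel.  It deliberately does not model sequencing errors, UMIs,
spliced alignments or expression structure — record content is irrelevant
to barcode-stratified extraction.

Everything is deterministic given the seed: the same spec and seed produce
byte-identical BAMs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Tuple, Union

import numpy as np
import pysam

from .errors import ConfigurationError

_BASES = np.array(list("ACGT"))
_UNBARCODED = "__unbarcoded__"
_SENTINEL = "__sentinel__"

PathLike = Union[str, os.PathLike]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic pooled BAM.

    ``encoding`` is one of ``tag_CB``, ``tag_CR``, ``tag:<XX>`` (custom
    2-character tag), ``qname_token:<delim>`` (UMI-tools-style read names),
    or ``mixed`` (CB tag *and* ``_``-delimited QNAME token on every read).
    Fractions are of the total record count; they must sum below 1.
    """

    n_barcodes: int = 3
    reads_per_barcode: Union[int, Mapping[str, int], Tuple[int, ...]] = 10
    barcode_length: int = 12
    suffix: str = ""  # e.g. "-1" for CellRanger GEM-well style barcodes
    encoding: str = "tag_CB"
    n_contigs: int = 2
    contig_length: int = 100_000
    read_length: int = 60
    unbarcoded_fraction: float = 0.0
    sentinel_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_contigs < 1:
            raise ConfigurationError("fixture needs at least one contig")
        if self.n_barcodes < 1:
            raise ConfigurationError("fixture needs at least one barcode")
        if not 0 <= self.unbarcoded_fraction + self.sentinel_fraction < 1:
            raise ConfigurationError("unbarcoded + sentinel fractions must be in [0, 1)")


@dataclass
class TruthTable:
    """Ground truth for one generated BAM.

    ``reads`` maps each barcode to its records as ``(qname, contig, pos)``
    tuples (1-based positions) in file order; ``order`` is the barcode
    first-appearance order in the BAM.
    """

    reads: Dict[str, List[Tuple[str, str, int]]] = field(default_factory=dict)
    order: List[str] = field(default_factory=list)
    unbarcoded: int = 0
    sentinel: int = 0

    @property
    def barcodes(self) -> List[str]:
        return list(self.reads)

    @property
    def total_assigned(self) -> int:
        return sum(len(v) for v in self.reads.values())

    @property
    def total_records(self) -> int:
        return self.total_assigned + self.unbarcoded + self.sentinel

    def to_tsv(self, path: PathLike) -> None:
        with open(path, "w") as fh:
            fh.write(f"#unbarcoded\t{self.unbarcoded}\n")
            fh.write(f"#sentinel\t{self.sentinel}\n")
            fh.write("#order\t" + ",".join(self.order) + "\n")
            for barcode, rows in self.reads.items():
                for qname, contig, pos in rows:
                    fh.write(f"{barcode}\t{qname}\t{contig}\t{pos}\n")

    @classmethod
    def from_tsv(cls, path: PathLike) -> "TruthTable":
        truth = cls()
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#unbarcoded\t"):
                    truth.unbarcoded = int(line.split("\t")[1])
                elif line.startswith("#sentinel\t"):
                    truth.sentinel = int(line.split("\t")[1])
                elif line.startswith("#order\t"):
                    value = line.split("\t", 1)[1]
                    truth.order = value.split(",") if value else []
                elif line:
                    barcode, qname, contig, pos = line.split("\t")
                    truth.reads.setdefault(barcode, []).append(
                        (qname, contig, int(pos))
                    )
        return truth


def _random_barcodes(rng: np.random.Generator, spec: FixtureSpec) -> List[str]:
    barcodes: Dict[str, None] = {}
    while len(barcodes) < spec.n_barcodes:
        bc = "".join(rng.choice(_BASES, size=spec.barcode_length)) + spec.suffix
        barcodes.setdefault(bc, None)
    return list(barcodes)


def _per_barcode_counts(spec: FixtureSpec, barcodes: List[str]) -> Dict[str, int]:
    rpb = spec.reads_per_barcode
    if isinstance(rpb, int):
        counts = {bc: rpb for bc in barcodes}
    elif isinstance(rpb, Mapping):
        counts = {bc: int(rpb.get(bc, 0)) for bc in barcodes}
    else:
        if len(rpb) != len(barcodes):
            raise ConfigurationError(
                "per-barcode read counts must match the number of barcodes"
            )
        counts = dict(zip(barcodes, (int(c) for c in rpb)))
    if sum(counts.values()) == 0:
        raise ConfigurationError("fixture needs at least one read")
    return counts


def _interleave_labels(
    rng: np.random.Generator, pools: Dict[str, int]
) -> List[str]:
    """Round-robin over labels with per-round shuffling (jittered interleave)."""
    remaining = dict(pools)
    sequence: List[str] = []
    while True:
        active = [label for label, count in remaining.items() if count > 0]
        if not active:
            return sequence
        rng.shuffle(active)
        for label in active:
            sequence.append(label)
            remaining[label] -= 1


def generate_fixture(spec: FixtureSpec, out_bam: PathLike) -> TruthTable:
    """Write a valid, indexed, coordinate-sorted barcoded BAM; return truth.

    Record positions increase monotonically along concatenated contigs with
    per-record jitter; every record is a simple full-length match (fixed
    length, single-M CIGAR), which is all barcode-stratified extraction can
    observe.
    """
    rng = np.random.default_rng(spec.seed)
    barcodes = _random_barcodes(rng, spec)
    counts = _per_barcode_counts(spec, barcodes)
    n_assigned = sum(counts.values())

    frac = spec.unbarcoded_fraction + spec.sentinel_fraction
    total = int(round(n_assigned / (1 - frac))) if frac > 0 else n_assigned
    n_unbarcoded = int(round(total * spec.unbarcoded_fraction))
    n_sentinel = int(round(total * spec.sentinel_fraction))

    pools: Dict[str, int] = {bc: c for bc, c in counts.items() if c > 0}
    if n_unbarcoded:
        pools[_UNBARCODED] = n_unbarcoded
    if n_sentinel:
        pools[_SENTINEL] = n_sentinel
    labels = _interleave_labels(rng, pools)
    n_total = len(labels)

    genome = spec.n_contigs * spec.contig_length
    if genome < 4 * n_total + spec.read_length * spec.n_contigs:
        raise ConfigurationError(
            "contigs too short for the requested read count; increase "
            "contig_length or n_contigs"
        )
    step = genome // n_total
    jitter = rng.integers(0, max(1, step // 2), size=n_total)

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": str(i + 1), "LN": spec.contig_length}
            for i in range(spec.n_contigs)
        ],
    }

    encoding = spec.encoding
    if encoding == "tag_CB":
        tag, delim = "CB", None
    elif encoding == "tag_CR":
        tag, delim = "CR", None
    elif encoding.startswith("tag:"):
        tag, delim = encoding[len("tag:") :], None
        if len(tag) != 2:
            raise ConfigurationError(f"custom tag must have 2 characters: {tag!r}")
    elif encoding.startswith("qname_token:"):
        tag, delim = None, encoding[len("qname_token:") :]
        if len(delim) != 1:
            raise ConfigurationError(f"qname delimiter must be 1 character: {delim!r}")
    elif encoding == "mixed":
        tag, delim = "CB", "_"
    else:
        raise ConfigurationError(f"unknown fixture encoding {spec.encoding!r}")

    truth = TruthTable(reads={bc: [] for bc in barcodes if counts[bc] > 0})
    seen_order: Dict[str, None] = {}
    qualities = pysam.qualitystring_to_array("I" * spec.read_length)

    out_bam = os.fspath(out_bam)
    header_obj = pysam.AlignmentHeader.from_dict(header)
    with pysam.AlignmentFile(out_bam, "wb", header=header) as bam:
        for i, label in enumerate(labels):
            g = i * step + int(jitter[i])
            tid = min(g // spec.contig_length, spec.n_contigs - 1)
            pos0 = min(
                g - tid * spec.contig_length,
                spec.contig_length - spec.read_length - 1,
            )
            qname = f"R{i:07d}"
            umi = "".join(rng.choice(_BASES, size=8))
            if label == _UNBARCODED:
                barcode_field = None
            elif label == _SENTINEL:
                barcode_field = "-"
            else:
                barcode_field = label

            rec = pysam.AlignedSegment(header=header_obj)
            if delim is not None and barcode_field is not None:
                rec.query_name = f"{qname}{delim}{barcode_field}{delim}{umi}"
            else:
                rec.query_name = qname
            rec.query_sequence = "".join(rng.choice(_BASES, size=spec.read_length))
            rec.flag = 0
            rec.reference_id = tid
            rec.reference_start = pos0
            rec.mapping_quality = 60
            rec.cigartuples = [(0, spec.read_length)]
            rec.query_qualities = qualities
            if tag is not None and barcode_field is not None:
                rec.set_tag(tag, barcode_field, value_type="Z")
            bam.write(rec)

            if label == _UNBARCODED:
                truth.unbarcoded += 1
            elif label == _SENTINEL:
                truth.sentinel += 1
            else:
                seen_order.setdefault(label, None)
                truth.reads[label].append((rec.query_name, str(tid + 1), pos0 + 1))
    truth.order = list(seen_order)
    pysam.index(out_bam)
    return truth
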