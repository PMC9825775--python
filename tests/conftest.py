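"""Shared fixtures: synthetic BAM factory and independent extraction oracles."""

from __future__ import annotations

import hashlib
import subprocess
from typing import List, Optional, Sequence

import pysam
import pytest

from percell import FixtureSpec, generate_fixture
from percell.barcodes import BarcodeSpec, extract_barcode
from percell.regions import Region, record_overlaps


@pytest.fixture
def make_fixture(tmp_path):
    """Factory: generate a synthetic pooled BAM; returns (bam_path, truth)."""

    counter = {"n": 0}

    def _make(**kwargs):
        counter["n"] += 1
        bam = tmp_path / f"pooled{counter['n']}.bam"
        spec = FixtureSpec(**{"seed": 7, **kwargs})
        truth = generate_fixture(spec, bam)
        return str(bam), truth

    return _make


def naive_single_barcode_extract(
    bam: str,
    barcode: str,
    spec: BarcodeSpec,
    regions: Optional[Sequence[Region]] = None,
) -> List[str]:
    """Oracle: one-barcode-at-a-time linear filter, as SAM record strings.

    Deliberately independent of the batch engine: a plain sequential scan
    applying the extraction rule (and region overlap test) per record.
    """
    out: List[str] = []
    with pysam.AlignmentFile(bam, "rb") as af:
        for rec in af.fetch(until_eof=True):
            if regions is not None and not record_overlaps(rec, regions):
                continue
            if extract_barcode(rec, spec) == barcode:
                out.append(rec.to_string())
    return out


def samtools_tag_extract(bam: str, tag: str, barcode: str) -> List[str]:
    """Oracle: `samtools view -d TAG:barcode` body lines."""
    result = subprocess.run(
        ["samtools", "view", "-d", f"{tag}:{barcode}", bam],
        check=True,
        capture_output=True,
        text=True,
    )
    return [line for line in result.stdout.splitlines() if line]


def scbam_records(path: str) -> List[str]:
    with pysam.AlignmentFile(path, "rb") as af:
        return [rec.to_string() for rec in af.fetch(until_eof=True)]


def scbam_header_text(path: str) -> str:
    with pysam.AlignmentFile(path, "rb") as af:
        return str(af.header)


def scbam_digest(path: str) -> str:
    """Digest of the decompressed content (header text + record lines)."""
    h = hashlib.sha256()
    h.update(scbam_header_text(path).encode())
    for line in scbam_records(path):
        h.update(line.encode())
        h.update(b"\n")
    return h.hexdigest()
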