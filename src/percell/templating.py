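"""find/xargs-style template substitution.

Three tokens, bit-exact and case-sensitive:

``{}``
    the generated single-cell BAM path (as in ``find -exec`` / ``xargs -I``),
``{BARCODE}``
    the cell barcode,
``{BAMBASE}``
    the input BAM filename without its directory or trailing ``.bam``.

Substitution is plain text replacement with no escaping mechanism, so a
literal ``{}`` cannot appear in a command — a documented limitation mirroring
the find/xargs behavior this engine emulates.  Following the xargs
convention, a command template containing *no* token gets the scBAM path
appended at the end; any token suppresses appending.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

TOKENS = ("{}", "{BARCODE}", "{BAMBASE}")


@dataclass(frozen=True)
class TemplateContext:
    """Per-job substitution values: scBAM path, barcode, input BAM basename."""

    scbam_path: str
    barcode: str
    bambase: str

    def __post_init__(self) -> None:
        assert os.sep not in self.bambase and not self.bambase.endswith(".bam")


def bambase_of(input_bam_path: str) -> str:
    """Final path component with one trailing ``.bam`` (case-sensitive) removed.

    >>> bambase_of("/data/run7/sample1.bam")
    'sample1'
    >>> bambase_of("pooled.sorted.bam")
    'pooled.sorted'
    """
    base = os.path.basename(input_bam_path)
    if base.endswith(".bam"):
        base = base[: -len(".bam")]
    return base


def has_token(template: str) -> bool:
    return any(token in template for token in TOKENS)


def render(template: str, ctx: TemplateContext) -> str:
    """Replace every occurrence of the three tokens; other braces untouched."""
    return (
        template.replace("{}", ctx.scbam_path)
        .replace("{BARCODE}", ctx.barcode)
        .replace("{BAMBASE}", ctx.bambase)
    )


def render_command(template: str, ctx: TemplateContext) -> str:
    """Render a command template; append the scBAM path iff no token occurs.

    >>> ctx = TemplateContext("t/ACGT.bam", "ACGT", "sample1")
    >>> render_command("samtools flagstat", ctx)
    'samtools flagstat t/ACGT.bam'
    >>> render_command("wc -l {}", ctx)
    'wc -l t/ACGT.bam'
    """
    if not has_token(template):
        return template + " " + ctx.scbam_path
    return render(template, ctx)
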