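"""Cell-barcode extraction rules.

Pooled scRNA-seq BAMs carry the cell of origin of each read either in an
auxiliary tag (CellRanger/STARsolo: ``CB`` corrected, ``CR`` raw) or embedded
in the read name (UMI-tools appends ``_CELLBARCODE_UMI`` to the QNAME).  A
:class:`BarcodeSpec` captures one such rule; :func:`extract_barcode` applies
it to a single alignment record.

A record from which the rule yields nothing — tag absent, token index out of
range, regex non-match, empty value, or the ``-`` sentinel STARsolo writes
for unassigned barcodes — is *unbarcoded*, never an error.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

import pysam

from .errors import ConfigurationError

#: Value STARsolo writes in the CB tag when no barcode could be assigned.
NO_BARCODE_SENTINEL = "-"

_MODES = ("tag", "qname_token", "qname_regex")


@dataclass(frozen=True)
class BarcodeSpec:
    """One rule for pulling a cell barcode out of an alignment record.

    Exactly the fields of the active mode are set:

    ``tag``
        ``tag_name``: a two-character BAM auxiliary tag of type Z.
    ``qname_token``
        ``delimiter``: single character; ``token_index``: 0-based from the
        left, negative counts from the right (Python slicing convention, so
        the UMI-tools ``NAME_CELLBARCODE_UMI`` layout is index ``-2``).
    ``qname_regex``
        ``pattern``: a regular expression with exactly one capturing group;
        the group is the barcode.
    """

    mode: str
    tag_name: Optional[str] = None
    delimiter: Optional[str] = None
    token_index: Optional[int] = None
    pattern: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ConfigurationError(
                f"unknown barcode mode {self.mode!r}; expected one of {_MODES}"
            )
        if self.mode == "tag":
            if not self.tag_name or len(self.tag_name) != 2:
                raise ConfigurationError(
                    f"tag mode needs a 2-character tag name, got {self.tag_name!r}"
                )
            self._require_unset(delimiter=None, token_index=None, pattern=None)
        elif self.mode == "qname_token":
            if not self.delimiter or len(self.delimiter) != 1:
                raise ConfigurationError(
                    f"qname_token mode needs a single-character delimiter, got {self.delimiter!r}"
                )
            if self.token_index is None:
                raise ConfigurationError("qname_token mode needs a token_index")
            self._require_unset(tag_name=None, pattern=None)
        else:  # qname_regex
            if not self.pattern:
                raise ConfigurationError("qname_regex mode needs a pattern")
            try:
                compiled = re.compile(self.pattern)
            except re.error as exc:
                raise ConfigurationError(f"invalid barcode pattern: {exc}") from exc
            if compiled.groups != 1:
                raise ConfigurationError(
                    "barcode pattern must contain exactly one capturing group, "
                    f"got {compiled.groups} in {self.pattern!r}"
                )
            self._require_unset(tag_name=None, delimiter=None, token_index=None)

    def _require_unset(self, **fields) -> None:
        for name in fields:
            if getattr(self, name) is not None:
                raise ConfigurationError(
                    f"field {name!r} is not valid in mode {self.mode!r}"
                )

    # -- constructors -----------------------------------------------------
    @classmethod
    def tag(cls, tag_name: str) -> "BarcodeSpec":
        return cls(mode="tag", tag_name=tag_name)

    @classmethod
    def qname_token(cls, delimiter: str, token_index: int) -> "BarcodeSpec":
        return cls(mode="qname_token", delimiter=delimiter, token_index=token_index)

    @classmethod
    def qname_regex(cls, pattern: str) -> "BarcodeSpec":
        return cls(mode="qname_regex", pattern=pattern)


#: Presets for the barcode encodings of common scRNA-seq pipelines.
PRESETS = {
    "cellranger": BarcodeSpec.tag("CB"),
    "starsolo": BarcodeSpec.tag("CB"),
    "starsolo_raw": BarcodeSpec.tag("CR"),
    "umitools": BarcodeSpec.qname_token("_", -2),
}


def preset_spec(name: str) -> BarcodeSpec:
    """Return the extraction rule for a named pipeline preset.

    ``cellranger`` and ``starsolo`` use the corrected-barcode CB tag,
    ``starsolo_raw`` the raw CR tag, and ``umitools`` the second-to-last
    ``_``-delimited token of the read name.
    """
    try:
        return PRESETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown barcode preset {name!r}; valid presets: "
            + ", ".join(sorted(PRESETS))
        ) from None


def extract_barcode(record: pysam.AlignedSegment, spec: BarcodeSpec) -> Optional[str]:
    """Apply ``spec`` to one alignment record; return the barcode or ``None``.

    ``None`` means *unbarcoded*: the tag is absent, the token index is out of
    range for the QNAME's token count, the regex does not match, or the value
    is empty or the ``-`` sentinel.  Pure: same record and spec always yield
    the same result.
    """
    value: Optional[str]
    if spec.mode == "tag":
        try:
            raw = record.get_tag(spec.tag_name)
        except KeyError:
            return None
        value = raw if isinstance(raw, str) else str(raw)
    elif spec.mode == "qname_token":
        tokens = (record.query_name or "").split(spec.delimiter)
        i = spec.token_index
        if i >= len(tokens) or i < -len(tokens):
            return None
        value = tokens[i]
    else:  # qname_regex
        match = re.search(spec.pattern, record.query_name or "")
        if match is None:
            return None
        value = match.group(1)
    if not value or value == NO_BARCODE_SENTINEL:
        return None
    return value
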