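"""Run configuration: the validated bundle of options a pipeline run needs.

A :class:`RunConfig` can be built from CLI flags, from a YAML key/value
config file mirroring the long flag names, or directly in Python.  CLI
values override file values.  Serializing and re-parsing a config yields an
equivalent configuration, so runs are reproducible from the file alone.
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass, field, fields
from typing import Any, Dict, Optional

import yaml

from .barcodes import PRESETS, BarcodeSpec, preset_spec
from .errors import ConfigurationError


def parse_barcode_source(text: str) -> BarcodeSpec:
    """Parse a barcode-source descriptor into an extraction rule.

    Accepted forms: a preset name (``cellranger``, ``starsolo``,
    ``starsolo_raw``, ``umitools``), ``tag:XX`` for an arbitrary 2-character
    tag, ``qname:<delim>:<index>`` for a delimited QNAME token (index 0-based
    from the left, negatives from the right), or ``regex:<pattern>`` with
    exactly one capturing group.
    """
    if text in PRESETS:
        return preset_spec(text)
    if text.startswith("tag:"):
        return BarcodeSpec.tag(text[len("tag:") :])
    if text.startswith("qname:"):
        rest = text[len("qname:") :]
        delim, sep, idx = rest.partition(":")
        if not sep:
            raise ConfigurationError(
                f"qname barcode source needs 'qname:<delim>:<index>', got {text!r}"
            )
        try:
            index = int(idx)
        except ValueError:
            raise ConfigurationError(
                f"qname token index must be an integer, got {idx!r}"
            ) from None
        return BarcodeSpec.qname_token(delim, index)
    if text.startswith("regex:"):
        return BarcodeSpec.qname_regex(text[len("regex:") :])
    raise ConfigurationError(
        f"unknown barcode source {text!r}; use a preset "
        f"({', '.join(sorted(PRESETS))}), tag:XX, qname:<delim>:<index> "
        "or regex:<pattern>"
    )


def _default_jobs() -> int:
    return os.cpu_count() or 1


@dataclass
class RunConfig:
    """Everything one pipeline run needs, validated."""

    input_bam: str
    command_template: str
    barcode_source: str = "starsolo"
    acceptlist_path: Optional[str] = None
    regions: Optional[str] = None  # comma-separated region strings or a BED path
    batch_size: int = 100
    jobs: int = field(default_factory=_default_jobs)
    limit: Optional[int] = None
    file_template: Optional[str] = None
    workdir_template: Optional[str] = None
    stdout_template: Optional[str] = None
    stderr_template: Optional[str] = None
    index: bool = False
    emit_empty: bool = False
    fail_fast: bool = False
    verbose: int = 0
    scratch_dir: Optional[str] = None  # scBAM directory when no file template
    event_log_path: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.command_template:
            raise ConfigurationError("a command template is required")
        if not self.input_bam:
            raise ConfigurationError("an input BAM is required")
        if self.batch_size < 1:
            raise ConfigurationError(f"batch size must be >= 1, got {self.batch_size}")
        if self.jobs < 1:
            raise ConfigurationError(f"job count must be >= 1, got {self.jobs}")
        if self.limit is not None and self.limit < 1:
            raise ConfigurationError(f"limit must be >= 1, got {self.limit}")
        parse_barcode_source(self.barcode_source)  # fail early on bad syntax

    @property
    def barcode_spec(self) -> BarcodeSpec:
        return parse_barcode_source(self.barcode_source)

    @property
    def keep_scbams(self) -> bool:
        """scBAMs are kept iff the user asked for a filename template."""
        return self.file_template is not None

    # -- config-file round trip -------------------------------------------
    def to_dict(self) -> Dict[str, Any]:
        return {k: v for k, v in asdict(self).items() if v is not None}

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, data: Dict[str, Any]) -> "RunConfig":
        valid = {f.name for f in fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise ConfigurationError(
                f"unknown configuration keys: {', '.join(sorted(unknown))}"
            )
        return cls(**data)

    @classmethod
    def load(cls, path: str, **overrides: Any) -> "RunConfig":
        """Load a YAML config file; keyword overrides win over file values."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} must be a key/value mapping")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_dict(data)
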