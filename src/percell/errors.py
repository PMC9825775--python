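"""Exception hierarchy for percell."""


class PercellError(Exception):
    """Base class for all percell errors."""


class ConfigurationError(PercellError):
    """Invalid user configuration: bad preset, malformed region, batch size < 1, ..."""


class ExtractionError(PercellError):
    """Failure while streaming or writing alignment records."""
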