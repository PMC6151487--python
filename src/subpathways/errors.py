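"""Exception hierarchy shared across the pipeline."""


class SubpathwaysError(Exception):
    """Base class for all package errors."""


class ValidationError(SubpathwaysError, ValueError):
    """An input object violates a structural invariant."""


class KGMLParseError(SubpathwaysError, ValueError):
    """Malformed pathway XML; the message names the offending element."""


class FormatError(SubpathwaysError, ValueError):
    """A serialized artifact has an unsupported or inconsistent format."""


class ConfigurationError(SubpathwaysError, ValueError):
    """Parameters are inconsistent with each other or with the data."""


class DegenerateGeneError(SubpathwaysError, ValueError):
    """A gene's expression values admit no high/low split (all identical)."""
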