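"""Exception taxonomy.

Parsers distinguish files that cannot be opened at all, files with an
unexpected internal layout, and per-read defects that are recoverable
(counted as "skipped") from genuinely fatal conditions.
"""


class NanorunError(Exception):
    """Base class for all package errors."""


class UnreadableFileError(NanorunError):
    """File is not a readable container of the expected kind."""


class UnknownLayoutError(NanorunError):
    """Valid HDF5 but neither single-read nor multi-read fast5 layout."""


class NotBasecalledError(NanorunError):
    """fast5 read lacks a basecall group; caller counts it as skipped."""


class MalformedFileError(NanorunError):
    """fast5 read is missing required channel/tracking attributes."""


class SchemaError(NanorunError):
    """Sequencing summary lacks a required column (named in the message)."""


class RowParseError(NanorunError):
    """A summary row holds an unparseable cell; message carries line number."""


class FastqParseError(NanorunError):
    """Truncated or malformed FASTQ record; message carries record index."""


class DegenerateFitError(NanorunError):
    """Regression requested on data with fewer than 2 distinct lengths."""


class DomainError(NanorunError, ValueError):
    """Argument outside its documented domain (channel, mux, threshold...)."""
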