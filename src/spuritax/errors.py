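"""Exception hierarchy.

``FormatError`` signals malformed external files (ragged TSV, duplicate
FASTA headers, unbalanced Newick); ``ValidationError`` signals structurally
well-formed data that violates a domain invariant (negative counts,
all-zero samples, unknown sample ids). The CLI maps them to exit codes
2 (config) and 3 (data validation).
"""


class SpuritaxError(ValueError):
    """Base class for all package errors."""


class FormatError(SpuritaxError):
    """A file could not be parsed as the expected format."""


class ValidationError(SpuritaxError):
    """Parsed data violates a domain invariant or precondition."""


class ConfigError(SpuritaxError):
    """An experiment configuration is inconsistent or incomplete."""
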