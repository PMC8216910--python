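"""Exception hierarchy.

``PolyGwasError`` marks user-facing errors (bad inputs, bad configuration);
anything else escaping the library is an internal error.
"""


class PolyGwasError(Exception):
    """Base class for user-facing errors."""


class ConfigError(PolyGwasError):
    """Malformed or inconsistent configuration file."""


class FormatError(PolyGwasError):
    """Malformed genotype/phenotype/map input."""


class DataError(PolyGwasError):
    """Inputs are well-formed but scientifically unusable (e.g. every marker filtered out)."""
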