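"""Exception types shared across the package."""


class EssError(Exception):
    """Base class for all package errors."""


class AlphabetError(EssError, ValueError):
    """A sequence contains characters outside {A,C,G,T} where they are required."""


class FormatError(EssError, ValueError):
    """A file or enriched string is malformed."""


class SpssViolationError(EssError, ValueError):
    """A string set violates the spectrum-preserving conditions (duplicate k-mer)."""


class GraphError(EssError, ValueError):
    """Invalid graph, path, or cover operation."""
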