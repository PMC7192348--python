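"""Exception types shared across the package."""


class ComgrowError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(ComgrowError, ValueError):
    """A model or evaluation parameter violates its constraints."""


class ParseError(ComgrowError, ValueError):
    """A network file could not be parsed; the message carries the line number."""


class UndefinedMeasureError(ComgrowError, ValueError):
    """A statistic is undefined for the given input (e.g. modularity of an
    edgeless graph, AUC when no non-edge exists)."""


class NotATreeError(ComgrowError, ValueError):
    """A community's induced subgraph is not a tree (cycle or disconnected)."""
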