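"""Exception types raised across the package."""


class MetabreduceError(Exception):
    """Base class for all package-specific errors."""


class DataFormatError(MetabreduceError, ValueError):
    """A file or header does not follow the expected layout."""


class DomainError(MetabreduceError, ValueError):
    """A value violates a domain constraint (e.g. negative concentration)."""


class MetadataError(MetabreduceError, ValueError):
    """Sample metadata is inconsistent (e.g. one region under two origins)."""


class CoincidenceError(MetabreduceError, ValueError):
    """The plain Weiszfeld operator was evaluated at a data point.

    The update divides by ``||y - x_i||`` and is undefined there; callers
    should switch to the modified (Vardi-Zhang) step, which is total.
    """


class DegenerateClusterError(MetabreduceError, RuntimeError):
    """A fuzzy cluster lost all of its membership mass during fitting."""


class DisconnectedGraphError(MetabreduceError, ValueError):
    """The k-nearest-neighbour graph is disconnected; increase n_neighbors."""
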