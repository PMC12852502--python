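"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`StreamSyncError`, so callers can catch one type at the pipeline
boundary while still distinguishing the failure modes below.
"""


class StreamSyncError(Exception):
    """Base class for all errors raised by streamsync."""


class FormatError(StreamSyncError, ValueError):
    """A file could not be parsed into the expected tabular layout."""


class ValidationError(StreamSyncError, ValueError):
    """Parsed data violate a domain invariant (negative density, bad label...)."""


class InsufficientDataError(StreamSyncError, ValueError):
    """Too few observations for the requested statistic (e.g. a single year)."""


class UnknownKeyError(StreamSyncError, KeyError):
    """A requested site, taxon or column does not exist."""


class DegenerateCommunityError(StreamSyncError, ArithmeticError):
    """The synchrony ratio is 0/0: every taxon is constant through time."""


class ConfigError(StreamSyncError, ValueError):
    """A configuration object violates its own invariants."""


class ConsistencyError(StreamSyncError, ValueError):
    """Two inputs that must describe the same entity disagree (site ids...)."""
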