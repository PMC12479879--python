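"""Exception hierarchy shared across the toolkit."""


class EODSortError(Exception):
    """Base class for all eodsort errors."""


class ConfigError(EODSortError, ValueError):
    """A configuration value violates its contract."""


class FormatError(EODSortError, ValueError):
    """A file could not be parsed as the declared container."""


class ShapeError(EODSortError, ValueError):
    """An array or table has the wrong dimensions."""


class OrderingError(EODSortError, ValueError):
    """An input sequence violates a required sort order."""


class DomainError(EODSortError, ValueError):
    """A value lies outside its mathematical domain."""
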