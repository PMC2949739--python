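"""Exception hierarchy shared across the package."""


class HapLDError(Exception):
    """Base class for all package-specific errors."""


class AlignmentError(HapLDError):
    """The input does not form a valid aligned set of haplotypes."""


class InvalidSymbolError(AlignmentError):
    """A sequence contains a character outside {A, C, G, T, -, N}."""


class InsufficientDataError(HapLDError):
    """Too few sequences / sites / observations for the requested statistic."""


class ConfigurationError(HapLDError):
    """Inconsistent or incomplete run configuration."""


class FilterError(HapLDError):
    """An operation was requested on a site excluded by the usable-site filter."""


class UndefinedStatisticError(HapLDError):
    """The statistic is undefined for the given table (e.g. monomorphic margin)."""
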