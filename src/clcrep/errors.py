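"""Exception types shared across the package."""


class ClcrepError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ClcrepError):
    """A simulation or pipeline configuration is invalid."""


class FormatError(ClcrepError):
    """An input table does not conform to the expected dialect."""


class ParameterError(ClcrepError):
    """An analysis parameter is outside its valid range."""


class UndefinedStatisticError(ClcrepError):
    """A statistic is undefined for the given input (e.g. all-zero counts)."""


class AlignmentRejected(ClcrepError):
    """A sequence aligned too poorly to its germline to be profiled."""
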