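"""Exception hierarchy.

Three broad families map onto distinct CLI exit codes: configuration
problems (bad parameters, malformed montage), data problems (shape or
label inconsistencies, degenerate datasets) and runtime faults.
"""


class NRDNNError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(NRDNNError):
    """Invalid configuration value (band edges, grids, montage file...)."""

    exit_code = 2


class InvalidMapError(ConfigError):
    """Region map violates its invariants (duplicate channel assignment)."""


class MontageMismatchError(NRDNNError):
    """A montage references channels the trial does not carry."""

    exit_code = 3


class DataError(NRDNNError):
    """Input data violates a precondition (non-finite values, bad labels)."""

    exit_code = 3


class DegenerateDataError(DataError):
    """A training set with a single class, a subject with no trials..."""


class ShapeError(DataError):
    """Array dimensions inconsistent with the model configuration."""


class DegenerateTestError(DataError):
    """A statistical test whose inputs make it undefined (all-zero diffs)."""
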