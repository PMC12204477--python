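"""Exception hierarchy shared across the package.

The CLI maps these onto distinct exit codes (see :mod:`demopair.cli`):
input-not-found -> 2, validation -> 3, computation -> 4.
"""


class DemographyError(Exception):
    """Base class for all errors raised by demopair."""


class InputNotFoundError(DemographyError):
    """A file, year, or location requested from an input source is absent."""


class ValidationError(DemographyError):
    """An input object violates a structural constraint (range, monotonicity, shape)."""


class ComputationError(DemographyError):
    """A quantity is undefined on the given input (zero totals, degenerate tables)."""
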