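"""Exception hierarchy for trajscreen.

All exceptions derive from :class:`TrajscreenError` so callers can catch
package failures with a single handler while still distinguishing schema
problems (malformed input files) from statistical ones (unidentifiable
model structures, degenerate data).
"""


class TrajscreenError(Exception):
    """Base class for all trajscreen errors."""


class SchemaError(TrajscreenError, ValueError):
    """An input table is missing a required column or has a bad dtype."""


class IntegrityError(TrajscreenError, ValueError):
    """Cross-table consistency violated (duplicates, missing covariates)."""


class DomainError(TrajscreenError, ValueError):
    """A value is outside the domain an operation requires."""


class StateError(TrajscreenError, RuntimeError):
    """An operation was applied in an invalid dataset state."""


class IdentifiabilityError(TrajscreenError, ValueError):
    """The requested model structure is not identifiable from the data."""


class VariableLookupError(TrajscreenError, KeyError):
    """A requested variable id is not present in the dataset."""


class DataError(TrajscreenError, ValueError):
    """Not enough usable data for the requested computation."""


class ConfigError(TrajscreenError, ValueError):
    """Invalid configuration object."""


class NumericalError(TrajscreenError, RuntimeError):
    """A numerical routine failed (non-PSD covariance, overflow)."""
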