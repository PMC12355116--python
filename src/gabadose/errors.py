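"""Exception hierarchy for the gabadose pipeline.

Exit-code mapping in the CLI: SchemaError -> 2, any other GabadoseError -> 3.
"""


class GabadoseError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GabadoseError):
    """An invalid configuration value; the message names the offending field."""


class DataError(GabadoseError):
    """Invalid data content (non-positive quantity, unknown drug, ...)."""


class DataIntegrityError(DataError):
    """Cross-table inconsistency (orphan dispensing, overlapping enrolment,
    death before cohort entry)."""


class SchemaError(GabadoseError):
    """An input table does not match the expected schema."""


class ConvergenceError(GabadoseError):
    """A model fit failed to converge; message carries the last gradient norm."""
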