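"""Exception hierarchy shared across the package.

All domain-level failures derive from :class:`ICZError` so callers can
catch everything the library raises with one clause.  Validation of
user-supplied values raises :class:`ValidationError`; malformed files
raise :class:`SchemaError`; missing measurement coverage (a ray with too
few points, a required ray absent from the model) raises
:class:`CoverageError`.
"""


class ICZError(Exception):
    """Base class for all errors raised by iczone."""


class ValidationError(ICZError, ValueError):
    """An input value violates a documented invariant or precondition."""


class SchemaError(ICZError, ValueError):
    """A file does not conform to the documented on-disk schema."""


class CoverageError(ValidationError):
    """The measurement point cloud does not cover a required region."""
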