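"""Exception hierarchy.

Every error raised by this package derives from :class:`LncnetError`, so
callers can catch one type at a pipeline boundary. The subclasses mirror the
kinds of failure a stage can hit: bad configuration, malformed input files,
invalid data values, an experimental design the statistics cannot support,
out-of-range parameters, and a corrupted packaged fixture.
"""


class LncnetError(Exception):
    """Base class for all lncnet errors."""


class ConfigurationError(LncnetError):
    """A simulation or pipeline configuration field is invalid."""


class FormatError(LncnetError):
    """An input file does not conform to its expected format."""


class DataError(LncnetError):
    """Input values violate a data invariant (e.g. non-positive intensity)."""


class DesignError(LncnetError):
    """The study design cannot support the requested computation."""


class ParameterError(LncnetError):
    """An operation parameter is out of its valid domain."""


class IntegrityError(LncnetError):
    """A packaged fixture failed its checksum verification."""
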