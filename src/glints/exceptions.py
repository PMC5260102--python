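"""Exception hierarchy for glints.

All errors raised by the package derive from :class:`GlintsError`, so callers
can catch a single type at pipeline boundaries. Per-gene / per-measure failures
inside the pipeline are downgraded to missing entries rather than aborting a
whole run; the exceptions below are raised by the individual operations.
"""


class GlintsError(Exception):
    """Base class for all glints errors."""


class FormatError(GlintsError):
    """An input file could not be parsed in its declared dialect."""


class ValidationError(GlintsError):
    """A record violates a structural invariant (e.g. strand not in {+,-})."""


class ConfigurationError(GlintsError):
    """A score or option referenced in the configuration is unknown."""


class DataIntegrityError(GlintsError):
    """Inputs contradict each other (e.g. VCF REF does not match the genome)."""


class InsufficientNullError(GlintsError):
    """An empirical null panel is empty or smaller than the required minimum."""


class InsufficientDataError(GlintsError):
    """Too few regression rows remain after filtering (n < 3)."""


class DegenerateDesignError(GlintsError):
    """The regression design is degenerate (constant genotype similarity)."""


class DegenerateFitError(GlintsError):
    """The fitted noise variance is zero in the tested direction."""


class MissingResultError(GlintsError):
    """No p-value source is present for a variant; nothing to combine."""
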