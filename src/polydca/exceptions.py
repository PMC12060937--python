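"""Exception hierarchy.

``ValidationError`` flags inputs that violate a data contract (bad row sums,
non-contiguous outcome categories, ...); ``ConfigurationError`` flags a
malformed or incoherent analysis configuration; ``DegenerateSplitError``
flags a binary split on which a utility statistic is undefined (for example
zero prevalence, where standardized net benefit has no meaning).
"""


class PolyDCAError(Exception):
    """Base class for all package errors."""


class ValidationError(PolyDCAError, ValueError):
    """Input data violates a documented invariant."""


class ConfigurationError(PolyDCAError, ValueError):
    """Analysis configuration is missing, malformed, or self-contradictory."""


class DegenerateSplitError(PolyDCAError, ValueError):
    """A statistic is undefined on this binary split (e.g. prevalence 0)."""
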