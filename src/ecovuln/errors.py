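"""Exception hierarchy for the vulnerability pipeline.

Every stage raises a subclass of :class:`EcovulnError` so the pipeline
driver can fail fast while naming the offending stage.
"""


class EcovulnError(Exception):
    """Base class for all pipeline errors."""


class RangeError(EcovulnError):
    """A value fell outside its documented domain (e.g. an EVI outside [0, 1])."""


class StructuralError(EcovulnError):
    """Mismatched grids, schemes, or vector lengths between stages."""


class FormatError(EcovulnError):
    """A file on disk does not conform to its declared format."""


class ValidationError(EcovulnError):
    """A run configuration failed validation; the message lists every problem."""


class DegenerateLayerError(EcovulnError):
    """An operation that divides by a value range met a constant layer."""


class RankError(EcovulnError):
    """A regression or PCA design is rank deficient or under-determined."""
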