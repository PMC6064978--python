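"""Exception hierarchy for pfcompare.

All library errors derive from :class:`PFCompareError` so callers can catch
one base class; the subclasses distinguish bad configuration (unknown shape
or contrast kind), bad model specifications (mismatched dimensions, invalid
custom maps), bad numeric domains (probabilities outside asymptotes,
non-positive Weibull stimuli), and unparseable data files.
"""


class PFCompareError(Exception):
    """Base class for all pfcompare errors."""


class ConfigurationError(PFCompareError, ValueError):
    """An identifier (shape, contrast kind, constraint mode) is unknown."""


class SpecificationError(PFCompareError, ValueError):
    """A model specification is internally inconsistent or mismatched."""


class DomainError(PFCompareError, ValueError):
    """A numeric argument lies outside the mathematically valid domain."""


class DataError(PFCompareError, ValueError):
    """A data file or Dataset violates its invariants."""
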