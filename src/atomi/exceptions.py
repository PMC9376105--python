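"""Exception hierarchy for the AToMI pipeline.

Every stage raises a subclass of :class:`AtomiError`, so callers (and the
pipeline orchestrator) can distinguish pipeline failures from programming
errors. Messages always name the offending plate/well/gene so a failed run
points at the records that caused it.
"""


class AtomiError(Exception):
    """Base class for all pipeline errors."""


class FormatError(AtomiError):
    """An input table does not conform to the documented schema."""


class DegenerateInputError(AtomiError):
    """A single measurement is unusable (e.g. non-positive bait abundance)."""


class MissingReferenceError(AtomiError):
    """A bait has no vehicle (DMSO) measurements to normalize against."""


class ConfigurationError(AtomiError):
    """Invalid analysis configuration (e.g. empty compound role sets)."""


class MissingControlError(AtomiError):
    """A plate lacks a required control class (negative or positive)."""


class PlateQCError(AtomiError):
    """A plate failed quality control (death control did not kill)."""


class IncompleteGeneError(AtomiError):
    """A gene lacks the full complement of siRNA measurements."""
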