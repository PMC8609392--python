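"""Exception hierarchy for the pipeline.

Every error raised on bad data or bad configuration derives from
:class:`SeroburdenError`, so callers (and the CLI) can separate data
problems from programming errors.
"""


class SeroburdenError(Exception):
    """Base class for all pipeline errors."""


class ParseError(SeroburdenError):
    """A file could not be parsed (malformed header, duplicate labels,
    non-numeric cell); the message names the offending row/column."""


class PairingError(SeroburdenError):
    """A patient lacks a pre- or post-surgical sample."""


class ConfigurationError(SeroburdenError):
    """Invalid analysis or simulation parameters, or metadata missing
    for an operation (e.g. no LLD for a protein that needs clipping)."""


class ScaleError(SeroburdenError):
    """An operation received a matrix on the wrong measurement scale."""


class AlignmentError(SeroburdenError):
    """Two matrices that must share a protein set do not."""


class DomainError(SeroburdenError):
    """A numeric input is outside the operation's domain
    (non-positive concentration, too few replicates, ...)."""


class SampleSizeError(SeroburdenError):
    """Too few paired observations for the requested statistic."""


class DegenerateInputError(SeroburdenError):
    """Statistic undefined on this input (e.g. zero variance)."""


class AmbiguityError(SeroburdenError):
    """Analyte matching found a key resolving to several labels."""


class TargetError(SeroburdenError):
    """A requested protein/target is absent from a matrix."""
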