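"""Exception hierarchy for detrunc."""


class DetruncError(Exception):
    """Base class for all detrunc errors."""


class SMVFormatError(DetruncError):
    """The SMV header is malformed or missing a required key."""


class TruncatedFileError(SMVFormatError):
    """The pixel payload is shorter than the header declares."""


class PixelRangeError(DetruncError, ValueError):
    """A pixel value plus offset falls outside the unsigned 16-bit range."""


class DegeneratePartitionError(DetruncError, ValueError):
    """Too few distinct pixel radii to form the requested annuli."""


class EmptyAnnulusError(DetruncError, ValueError):
    """An annulus contains no valid pixels after masking."""


class InsufficientDataError(DetruncError, ValueError):
    """A histogram has too few distinct positive bins to start a fit."""


class ModelInconsistencyError(DetruncError):
    """The fitted model assigns no mass to censored values although zeros exist."""


class FitError(DetruncError):
    """Per-annulus maximum-likelihood fit failed under the 'fail' policy."""
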