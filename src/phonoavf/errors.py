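"""Exception hierarchy for the phonoavf pipeline."""


class PhonoAVFError(Exception):
    """Base class for all phonoavf errors."""


class AudioFormatError(PhonoAVFError):
    """Input audio is not mono 16-bit PCM WAV, or is otherwise unreadable."""


class EmptyInputError(PhonoAVFError):
    """A recording or segment list is empty where data is required."""


class ResamplingError(PhonoAVFError):
    """Requested rate conversion is unsupported (e.g. upsampling to 8 kS/s)."""


class DegenerateSignalError(PhonoAVFError):
    """All-zero spectrum: the segment carries no energy and cannot be normalized."""


class SchemeError(PhonoAVFError):
    """A cross-validation scheme is infeasible for the given data."""


class FeatureMismatchError(PhonoAVFError):
    """A stored model's feature list does not match the offered features."""
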