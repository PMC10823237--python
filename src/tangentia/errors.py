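"""Exception types shared across the package."""


class TangentiaError(Exception):
    """Base class for all package-specific errors."""


class FormatError(TangentiaError):
    """A file on disk does not match the declared on-disk format."""


class EmptyInputError(TangentiaError):
    """An operation received no usable spikes/frames."""


class DegenerateWaveformError(TangentiaError):
    """A waveform is all-zero or otherwise carries no measurable signal."""


class DecompositionError(TangentiaError):
    """AF/DF temporal decomposition failed (no zero crossing found)."""
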