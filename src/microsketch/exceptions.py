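"""Exception hierarchy for the microsketch package."""


class MicrosketchError(Exception):
    """Base class for all package-specific errors."""


class FastqParseError(MicrosketchError):
    """A FASTQ stream violated the 4-line record contract."""

    def __init__(self, record_index: int, message: str):
        self.record_index = record_index
        super().__init__(f"malformed FASTQ record {record_index}: {message}")


class EmptySpectrumError(MicrosketchError):
    """A sketch was requested for a spectrum with no nonzero bins."""


class NothingToSketchError(EmptySpectrumError):
    """A read stream produced zero valid k-mers."""


class IncompatibleSketchError(MicrosketchError):
    """Two sketches (or a sketch and a model/index) disagree on a
    comparability parameter (k, sketch size, bin count or master seed)."""


class SketchFormatError(MicrosketchError):
    """A serialized sketch/index/model file is truncated or has a bad header."""


class LSHTuningError(MicrosketchError):
    """No (K, L) pair satisfies the requested error bounds."""
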