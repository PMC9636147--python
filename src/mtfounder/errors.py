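"""Named exceptions raised across the package."""


class MtFounderError(Exception):
    """Base class for all package errors."""


class VariantParseError(MtFounderError):
    """A variant string does not follow mtDNA nomenclature.

    Carries ``offset``, the character position where parsing failed.
    """

    def __init__(self, text: str, offset: int, message: str = "") -> None:
        self.text = text
        self.offset = offset
        super().__init__(
            f"cannot parse variant string {text!r} at offset {offset}"
            + (f": {message}" if message else "")
        )


class MetadataMismatchError(MtFounderError):
    """FASTA record IDs and the metadata table do not line up."""


class DuplicateSampleError(MtFounderError):
    """Two FASTA records (or metadata rows) share a sample ID."""


class AlignmentError(MtFounderError):
    """A sequence cannot be anchored to the reference coordinate system."""


class HaplotreeError(MtFounderError):
    """Structural problem in a haplogroup tree file (cycle, orphan, duplicate)."""


class MissingCallsError(MtFounderError):
    """Profiles submitted to the founder scan lack haplogroup calls."""


class EmptyGroupError(MtFounderError):
    """A statistical comparison received an empty group."""


class ConfigError(MtFounderError):
    """Invalid simulation or pipeline configuration."""
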