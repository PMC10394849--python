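"""Exception hierarchy shared across the package."""


class VariantScreenError(Exception):
    """Base class for all errors raised by this package."""


class VcfParseError(VariantScreenError):
    """A VCF file violates the format contract (bad header, ragged data line)."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class VoiFormatError(VariantScreenError):
    """The variants-of-interest table cannot be mapped onto the canonical schema."""


class AnnotationParseError(VariantScreenError):
    """A BED12 line is internally inconsistent."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class DataError(VariantScreenError):
    """Inputs are well-formed but mutually inconsistent (e.g. allele index out
    of range, chromosome nomenclature mismatch, zero shared loci)."""
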