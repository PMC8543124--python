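"""Exception types shared across the package."""


class AanetError(Exception):
    """Base class for all package-specific errors."""


class StructureFormatError(AanetError):
    """The input could not be parsed as a structure file."""


class EmptyStructureError(AanetError):
    """No residues survived parsing and filtering."""


class GenerationError(AanetError):
    """A synthetic-structure recipe could not be satisfied."""


class DatasetUnavailableError(AanetError):
    """A named reference structure could not be located or fetched."""
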