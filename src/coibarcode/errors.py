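"""Exception hierarchy shared across the pipeline stages."""


class CoiBarcodeError(Exception):
    """Base class for all pipeline errors."""


class FastaFormatError(CoiBarcodeError):
    """Malformed FASTA input (bad header, empty record, ...)."""


class DuplicateIdError(CoiBarcodeError):
    """Two records in one dataset share an identifier."""


class AlignmentError(CoiBarcodeError):
    """Records violate the alignment contract (unequal lengths, < 2 records)."""


class InvalidSequenceError(CoiBarcodeError):
    """A sequence contains characters outside the IUPAC nucleotide alphabet."""


class IncomparablePairError(CoiBarcodeError):
    """A sequence pair shares no unambiguous A/C/G/T site, so no distance exists."""


class SaturationError(CoiBarcodeError):
    """A distance computation hit the K2P saturation bound."""


class AmbiguousBaseError(CoiBarcodeError):
    """Restriction digestion requires an unambiguous A/C/G/T sequence."""


class ConfigError(CoiBarcodeError):
    """A simulation or pipeline configuration violates its invariants."""
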