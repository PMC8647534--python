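"""Exception hierarchy for the neoforge pipeline."""


class NeoforgeError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(NeoforgeError):
    """Invalid or inconsistent configuration."""


class PlacementError(NeoforgeError):
    """Synthetic genes cannot be placed within the requested chromosomes."""


class RealizationError(NeoforgeError):
    """A requested variant consequence class cannot be realized."""


class ReferenceMismatchError(NeoforgeError):
    """A record's REF allele disagrees with the reference sequence."""


class NormalizationError(NeoforgeError):
    """A record cannot be brought to canonical form."""


class OrderingError(NeoforgeError):
    """Records violate the sorted-by-position precondition."""


class MissingAnnotationError(NeoforgeError):
    """A required INFO annotation is absent from a record."""


class CoordinateError(NeoforgeError):
    """A coordinate falls outside the valid range."""


class LabelError(NeoforgeError):
    """A protein-change label was requested for an inapplicable class."""


class AlphabetError(NeoforgeError):
    """A peptide contains a non-standard residue."""


class CalibrationError(NeoforgeError):
    """An allele profile is used before background calibration."""


class FormatError(NeoforgeError):
    """External table text does not match the expected dialect."""


class CoverageError(NeoforgeError):
    """Binding results do not cover a consistent allele set."""
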