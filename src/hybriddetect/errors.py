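"""Exception hierarchy used across the package."""


class HybridDetectError(Exception):
    """Base class for all package-specific errors."""


class FormatError(HybridDetectError):
    """Malformed input file (non-binary cell, duplicate ids, bad header)."""


class MetadataError(HybridDetectError):
    """Specimen metadata missing or inconsistent with the marker matrix."""


class MergeError(HybridDetectError):
    """Marker matrices cannot be merged (specimen sets differ)."""


class ClassificationError(HybridDetectError):
    """Band classification preconditions violated (e.g. empty parental group)."""


class UndefinedSimilarityError(HybridDetectError):
    """Dice similarity undefined: both profiles are all-absent."""


class ConfigError(HybridDetectError):
    """Invalid configuration value or combination."""


class AlignmentError(HybridDetectError):
    """Sequences do not form a valid alignment (length mismatch, empty group)."""


class DigestError(HybridDetectError):
    """Unknown enzyme or invalid sequence for in-silico digestion."""
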