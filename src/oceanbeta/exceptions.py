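"""Exception hierarchy for oceanbeta."""


class OceanBetaError(Exception):
    """Base class for all package errors."""


class FormatError(OceanBetaError):
    """Malformed input file (bad header, duplicate ids, wrong dialect)."""


class ValidationError(OceanBetaError):
    """Structurally parseable input that violates a data invariant."""


class ClassificationError(OceanBetaError):
    """Sample metadata insufficient to assign an ecosystem class."""
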