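"""Exception types shared across the package."""


class ChipABMError(Exception):
    """Base class for all package errors."""


class GeometryError(ChipABMError):
    """Invalid chip geometry (non-positive dimensions, inconsistent counts)."""


class ConfigurationError(ChipABMError):
    """Invalid kinetic/fixed parameters (e.g. violated stability bound)."""


class StateError(ChipABMError):
    """Corrupted simulation state (e.g. an agent on an obstacle square)."""


class AlignmentError(ChipABMError):
    """Summaries computed on different evaluation-frame sets."""


class CoverageError(ChipABMError):
    """A requested evaluation frame is not covered by the frame series."""


class SchemaError(ChipABMError):
    """An input table is missing required columns."""
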