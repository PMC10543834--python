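"""Exception hierarchy for dtagnn."""

from __future__ import annotations

__all__ = [
    "DtagnnError",
    "InputError",
    "ConfigError",
    "SchemaError",
    "SmilesParseError",
    "BatchFeaturizationError",
    "UndefinedMetricError",
    "TrainingDivergedError",
]


class DtagnnError(Exception):
    """Base class for all package errors."""


class InputError(DtagnnError, ValueError):
    """Invalid user-supplied value (empty sequence, negative count, ...)."""


class ConfigError(DtagnnError, ValueError):
    """Invalid model or training configuration."""


class SchemaError(DtagnnError, ValueError):
    """Tabular or benchmark-directory input does not match the expected schema."""


class SmilesParseError(InputError):
    """A SMILES string could not be parsed; carries the offending string."""

    def __init__(self, smiles: str, message: str | None = None):
        self.smiles = smiles
        super().__init__(message or f"unparseable SMILES: {smiles!r}")


class BatchFeaturizationError(DtagnnError):
    """Every item of a featurization batch failed."""


class UndefinedMetricError(DtagnnError, ValueError):
    """A metric is undefined for the given inputs (e.g. CI with no comparable pairs)."""


class TrainingDivergedError(DtagnnError, RuntimeError):
    """Loss became non-finite; carries the epoch and batch index."""

    def __init__(self, epoch: int, batch: int):
        self.epoch = epoch
        self.batch = batch
        super().__init__(f"non-finite loss at epoch {epoch}, batch {batch}")
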