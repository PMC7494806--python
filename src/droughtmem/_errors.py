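"""Shared error types and the flagged-missing-value sentinel.

Missing data never propagate as silent zeros: trait extractors return a
:class:`Missing` carrying a machine-readable reason code, and aggregation
excludes those records while decrementing the replicate count.
"""

from __future__ import annotations

from dataclasses import dataclass


class DroughtmemError(Exception):
    """Base class for package errors."""


class ConfigError(DroughtmemError):
    """Invalid simulation or analysis configuration; names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid config field {field!r}: {message}")


class SchemaError(DroughtmemError):
    """An input table is missing or malformed."""


class ComputationError(DroughtmemError):
    """A well-formed input is outside the domain of a computation."""


@dataclass(frozen=True)
class Missing:
    """Flagged missing value with a reason code (e.g. 'insufficient_post_peak_points')."""

    reason: str

    def __bool__(self) -> bool:  # treat like NA in conditionals
        return False


def is_missing(x) -> bool:
    return isinstance(x, Missing)
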