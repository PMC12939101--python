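"""Exception hierarchy; the CLI maps these onto exit codes."""

from __future__ import annotations


class MeatRbaError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class SchemaError(MeatRbaError):
    """A dataset file does not conform to the documented schema."""

    exit_code = 2


class DatasetValidationError(SchemaError):
    """Parsed values violate an invariant (negative amount, duplicate row)."""


class ConfigurationError(MeatRbaError):
    """The assessment configuration is incomplete or inconsistent."""

    exit_code = 3


class UnresolvableExposureError(MeatRbaError):
    """A concentration cannot be turned into an exposure (no serving size)."""

    exit_code = 3


class IOFailure(MeatRbaError):
    """An output path could not be written or an input could not be read."""

    exit_code = 4
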