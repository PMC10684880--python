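"""Error hierarchy for the pipeline.

Every exception carries a stable machine-readable ``code`` so that CLI and
pipeline layers can tag failures by stage without string-matching messages.
"""

from __future__ import annotations


class SustdietError(Exception):
    """Base class for all package errors."""

    code: str = "ERROR"

    def __init__(self, message: str, *, code: str | None = None) -> None:
        super().__init__(message)
        if code is not None:
            self.code = code


class UnknownGroupError(SustdietError):
    code = "UNKNOWN_GROUP"


class NegativeShareError(SustdietError):
    code = "NEGATIVE_SHARE"


class SumNotOneError(SustdietError):
    code = "SUM_NOT_ONE"


class ScheduleIncompleteError(SustdietError):
    code = "SCHEDULE_INCOMPLETE"


class MassImbalanceError(SustdietError):
    code = "MASS_IMBALANCE"


class MissingFoodError(SustdietError):
    code = "MISSING_FOOD"


class ZeroEnergyError(SustdietError):
    # raised both for a zero-energy diet and a zero-kcal normalisation basis
    code = "ZERO_ENERGY"


class KeyMismatchError(SustdietError):
    code = "KEY_MISMATCH"


class UnitMismatchError(SustdietError):
    code = "UNIT_MISMATCH"


class NonMonotoneCutpointsError(SustdietError):
    code = "NON_MONOTONE_CUTPOINTS"


class EmptyDomainError(SustdietError):
    code = "EMPTY_DOMAIN"


class AllZeroError(SustdietError):
    code = "ALL_ZERO"


class ZeroRaccError(SustdietError):
    code = "ZERO_RACC"


class MissingFactorError(SustdietError):
    code = "MISSING_FACTOR"


class ZeroBaselineError(SustdietError):
    code = "ZERO_BASELINE"


class ZeroVarianceError(SustdietError):
    code = "ZERO_VARIANCE"


class LengthMismatchError(SustdietError):
    code = "LENGTH_MISMATCH"


class EmptySubsetError(SustdietError):
    code = "EMPTY_SUBSET"


class EmptyTableError(SustdietError):
    code = "EMPTY_TABLE"


class MissingImpactsError(SustdietError):
    code = "MISSING_IMPACTS"


class BadConfigError(SustdietError):
    code = "BAD_CONFIG"


class ChecksumMismatchError(SustdietError):
    code = "CHECKSUM_MISMATCH"
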