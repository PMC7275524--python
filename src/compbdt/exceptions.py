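"""Exception hierarchy for paired diagnostic-test comparison.

Input-validation errors name the offending cell or group so that a caller
(or the CLI) can report exactly what is wrong with the table.
"""

from __future__ import annotations


class CompbdtError(Exception):
    """Base class for all errors raised by this package."""


class CountsError(CompbdtError, ValueError):
    """Invalid paired-design cell counts."""


class NonIntegerCellError(CountsError):
    def __init__(self, cell: str, value: object) -> None:
        super().__init__(f"cell {cell!r} must be an integer, got {value!r}")
        self.cell = cell


class NegativeCellError(CountsError):
    def __init__(self, cell: str, value: int) -> None:
        super().__init__(f"cell {cell!r} must be non-negative, got {value}")
        self.cell = cell


class EmptyDiseaseGroupError(CountsError):
    def __init__(self) -> None:
        super().__init__("the diseased group is empty (s11+s10+s01+s00 = 0)")


class EmptyNonDiseaseGroupError(CountsError):
    def __init__(self) -> None:
        super().__init__("the non-diseased group is empty (r11+r10+r01+r00 = 0)")


class NonInformativeTestError(CompbdtError):
    """A test's estimated Youden index (Se + Sp - 1) is not positive."""

    def __init__(self, test: int, youden: float) -> None:
        super().__init__(
            f"Test {test} is non-informative: estimated Youden index "
            f"{youden:.4f} is not greater than 0"
        )
        self.test = test
        self.youden = youden


class InvalidTrialsError(CompbdtError, ValueError):
    """Binomial interval requested with m < 1 or successes outside [0, m]."""


class InfeasibleStatisticError(CompbdtError):
    """A test statistic cannot be computed from the observed frequencies."""


class InfeasibleLRTError(InfeasibleStatisticError):
    """Likelihood-ratio test needs every discordant cell to be positive."""


class InfeasibleMcNemarError(InfeasibleStatisticError):
    """McNemar test needs at least one discordant pair."""


class DegenerateStatisticError(InfeasibleStatisticError):
    """A statistic's denominator is zero on the observed table."""


class SingularSigmaError(InfeasibleStatisticError):
    """An estimated covariance matrix is singular; the global test is skipped."""


class ZeroLRError(InfeasibleStatisticError):
    """A likelihood ratio estimate is zero or undefined."""


class NonIdentifiablePowerError(CompbdtError):
    """Observed estimates of the family are exactly equal; the retrospective
    power target (a difference like the observed one) is undefined."""


class ResamplingCapError(CompbdtError):
    """Monte Carlo resampling exceeded the attempt cap without completing."""
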