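"""Paired-design contingency table for two binary diagnostic tests.

Both tests and the gold standard are applied to every subject of one random
sample, which yields eight cells: ``s_ij`` counts diseased subjects with
Test 1 result ``i`` and Test 2 result ``j`` (1 positive, 0 negative), and
``r_ij`` the analogous non-diseased counts.  All downstream statistics are
functions of these eight integers and their margins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator

from scipy.stats import norm

from .exceptions import (
    EmptyDiseaseGroupError,
    EmptyNonDiseaseGroupError,
    NegativeCellError,
    NonInformativeTestError,
    NonIntegerCellError,
)

CELL_NAMES = ("s11", "s10", "s01", "s00", "r11", "r10", "r01", "r00")


class StudyDesign(str, Enum):
    """How the sample was drawn.

    Under ``CASE_CONTROL`` the diseased and non-diseased group sizes are fixed
    by the researcher, so the prevalence and the predictive values are not
    estimable and their output is suppressed.
    """

    PAIRED_COHORT = "paired_cohort"
    CASE_CONTROL = "case_control"


@dataclass(frozen=True)
class PairedCounts:
    """The eight observed cells of the paired design with derived margins."""

    s11: int
    s10: int
    s01: int
    s00: int
    r11: int
    r10: int
    r01: int
    r00: int

    # --- group totals -----------------------------------------------------
    @property
    def s(self) -> int:
        """Number of diseased subjects."""
        return self.s11 + self.s10 + self.s01 + self.s00

    @property
    def r(self) -> int:
        """Number of non-diseased subjects."""
        return self.r11 + self.r10 + self.r01 + self.r00

    @property
    def n(self) -> int:
        return self.s + self.r

    # --- pooled cells n_ij ------------------------------------------------
    @property
    def n11(self) -> int:
        return self.s11 + self.r11

    @property
    def n10(self) -> int:
        return self.s10 + self.r10

    @property
    def n01(self) -> int:
        return self.s01 + self.r01

    @property
    def n00(self) -> int:
        return self.s00 + self.r00

    # --- diseased margins -------------------------------------------------
    @property
    def s1_dot(self) -> int:
        """Diseased subjects positive on Test 1."""
        return self.s11 + self.s10

    @property
    def s0_dot(self) -> int:
        return self.s01 + self.s00

    @property
    def s_dot1(self) -> int:
        """Diseased subjects positive on Test 2."""
        return self.s11 + self.s01

    @property
    def s_dot0(self) -> int:
        return self.s10 + self.s00

    # --- non-diseased margins ----------------------------------------------
    @property
    def r1_dot(self) -> int:
        return self.r11 + self.r10

    @property
    def r0_dot(self) -> int:
        return self.r01 + self.r00

    @property
    def r_dot1(self) -> int:
        return self.r11 + self.r01

    @property
    def r_dot0(self) -> int:
        return self.r10 + self.r00

    # --- pooled margins ----------------------------------------------------
    @property
    def n1_dot(self) -> int:
        """Subjects positive on Test 1."""
        return self.n11 + self.n10

    @property
    def n0_dot(self) -> int:
        return self.n01 + self.n00

    @property
    def n_dot1(self) -> int:
        return self.n11 + self.n01

    @property
    def n_dot0(self) -> int:
        return self.n10 + self.n00

    # --- naive estimates used throughout ------------------------------------
    @property
    def prevalence(self) -> float:
        return self.s / self.n

    def sensitivity(self, test: int) -> float:
        return (self.s1_dot if test == 1 else self.s_dot1) / self.s

    def specificity(self, test: int) -> float:
        return (self.r0_dot if test == 1 else self.r_dot0) / self.r

    def cells(self) -> tuple[int, ...]:
        """The eight cells in canonical (s11..s00, r11..r00) order."""
        return (self.s11, self.s10, self.s01, self.s00,
                self.r11, self.r10, self.r01, self.r00)

    def relabelled(self) -> "PairedCounts":
        """Swap the roles of Test 1 and Test 2 (transposes each 2x2 block)."""
        return PairedCounts(self.s11, self.s01, self.s10, self.s00,
                            self.r11, self.r01, self.r10, self.r00)

    def __iter__(self) -> Iterator[int]:
        return iter(self.cells())


@dataclass(frozen=True)
class AnalysisConfig:
    """Settings shared by every analysis stage.

    alpha : two-sided significance level of every test and interval.
    decip : decimal places in rendered reports.
    seed  : seed of the Monte Carlo generator (power estimation).
    reps  : Monte Carlo replicates for the power estimate.
    design: sampling design; case-control suppresses prevalence/PV output.
    """

    alpha: float = 0.05
    decip: int = 3
    seed: int = 20200605
    reps: int = 10_000
    design: StudyDesign = StudyDesign.PAIRED_COHORT
    max_attempt_factor: int = 100

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.reps < 1:
            raise ValueError(f"reps must be >= 1, got {self.reps}")
        if self.decip < 0:
            raise ValueError(f"decip must be >= 0, got {self.decip}")

    @property
    def z(self) -> float:
        """The 100(1 - alpha/2)th standard-normal percentile."""
        return float(norm.ppf(1.0 - self.alpha / 2.0))


def validate_counts(*raw: object) -> PairedCounts:
    """Validate eight cell counts given in the positional order
    (s11, s10, s01, s00, r11, r10, r01, r00) and return a :class:`PairedCounts`.

    Raises
    ------
    NonIntegerCellError, NegativeCellError
        A cell is not a non-negative integer.
    EmptyDiseaseGroupError, EmptyNonDiseaseGroupError
        An entire disease-status group is empty.
    """
    if len(raw) == 1 and isinstance(raw[0], (tuple, list)):
        raw = tuple(raw[0])
    if len(raw) != 8:
        raise ValueError(f"expected 8 cell counts, got {len(raw)}")
    cells: list[int] = []
    for name, value in zip(CELL_NAMES, raw):
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise NonIntegerCellError(name, value)
        if float(value) != int(value):
            raise NonIntegerCellError(name, value)
        value = int(value)
        if value < 0:
            raise NegativeCellError(name, value)
        cells.append(value)
    counts = PairedCounts(*cells)
    if counts.s == 0:
        raise EmptyDiseaseGroupError()
    if counts.r == 0:
        raise EmptyNonDiseaseGroupError()
    return counts


def check_youden(counts: PairedCounts) -> tuple[float, float]:
    """Return the estimated Youden indices (Se_i + Sp_i - 1) of both tests.

    A binary diagnostic test is only informative when its Youden index is
    positive; otherwise :class:`NonInformativeTestError` is raised naming the
    offending test.
    """
    youden = []
    for test in (1, 2):
        y = counts.sensitivity(test) + counts.specificity(test) - 1.0
        if y <= 0.0:
            raise NonInformativeTestError(test, y)
        youden.append(y)
    return (youden[0], youden[1])


@dataclass(frozen=True)
class StatisticFeasibility:
    feasible: bool
    reason: str | None = None


@dataclass(frozen=True)
class FeasibilityReport:
    """Which statistics are computable on the observed table.

    Infeasible statistics are reported (with the reason) rather than raised so
    that the rest of the analysis can still run.
    """

    wald_se: StatisticFeasibility
    wald_sp: StatisticFeasibility
    lrt_se: StatisticFeasibility
    lrt_sp: StatisticFeasibility
    mcnemar_se: StatisticFeasibility
    mcnemar_sp: StatisticFeasibility
    lr_family: StatisticFeasibility
    wgs_ppv: StatisticFeasibility
    wgs_npv: StatisticFeasibility
    pv_family: StatisticFeasibility

    @property
    def accuracy_global(self) -> bool:
        return self.wald_se.feasible and self.wald_sp.feasible

    @property
    def lrt_global(self) -> bool:
        return self.lrt_se.feasible and self.lrt_sp.feasible


def _ok() -> StatisticFeasibility:
    return StatisticFeasibility(True)


def _bad(reason: str) -> StatisticFeasibility:
    return StatisticFeasibility(False, reason)


def check_feasibility(counts: PairedCounts) -> FeasibilityReport:
    """Report, per statistic, whether the observed zero pattern allows it.

    The likelihood-ratio (deviance) tests require every discordant cell of
    their group to be positive; the McNemar tests require at least one
    discordant pair; the Wald tests require a non-zero denominator; the
    likelihood-ratio comparison requires all four LR estimates to exist and be
    positive; the predictive-value statistics require every pooled test margin
    to be positive.
    """
    c = counts

    wald_se = _ok() if 4 * c.s10 * c.s01 + (c.s11 + c.s00) * (c.s10 + c.s01) > 0 \
        else _bad("Wald Se denominator is 0 (no diseased discordant pairs)")
    wald_sp = _ok() if 4 * c.r10 * c.r01 + (c.r11 + c.r00) * (c.r10 + c.r01) > 0 \
        else _bad("Wald Sp denominator is 0 (no non-diseased discordant pairs)")
    lrt_se = _ok() if c.s10 > 0 and c.s01 > 0 \
        else _bad("LRT for Se needs s10 > 0 and s01 > 0")
    lrt_sp = _ok() if c.r10 > 0 and c.r01 > 0 \
        else _bad("LRT for Sp needs r10 > 0 and r01 > 0")
    mcnemar_se = _ok() if c.s10 + c.s01 > 0 \
        else _bad("McNemar for Se needs s10 + s01 > 0")
    mcnemar_sp = _ok() if c.r10 + c.r01 > 0 \
        else _bad("McNemar for Sp needs r10 + r01 > 0")

    # the log-ratio contrast needs all four LRs positive and finite, i.e.
    # every one-dimensional margin strictly inside its group total
    lr_ok = all(0 < m < c.s for m in (c.s1_dot, c.s_dot1)) and \
        all(0 < m < c.r for m in (c.r1_dot, c.r_dot1))
    lr_family = _ok() if lr_ok else _bad(
        "likelihood-ratio comparison needs every Se and Sp estimate strictly "
        "inside (0, 1)")

    wgs_ppv = _ok() if c.n1_dot > 0 and c.n_dot1 > 0 \
        else _bad("PPV comparison needs subjects positive on each test")
    wgs_npv = _ok() if c.n0_dot > 0 and c.n_dot0 > 0 \
        else _bad("NPV comparison needs subjects negative on each test")
    pv_ok = wgs_ppv.feasible and wgs_npv.feasible
    pv_family = _ok() if pv_ok else _bad(
        "predictive-value comparison needs every pooled test margin positive")

    return FeasibilityReport(
        wald_se=wald_se, wald_sp=wald_sp,
        lrt_se=lrt_se, lrt_sp=lrt_sp,
        mcnemar_se=mcnemar_se, mcnemar_sp=mcnemar_sp,
        lr_family=lr_family,
        wgs_ppv=wgs_ppv, wgs_npv=wgs_npv, pv_family=pv_family,
    )
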