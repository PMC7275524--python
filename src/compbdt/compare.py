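"""Global and individual hypothesis tests for the three parameter families.

Each family (accuracy = Se/Sp, likelihood ratios, predictive values) is
compared through a global 2-df test of simultaneous equality; when the global
test is significant the two individual hypotheses are resolved with the Holm
step-down method and an oriented confidence interval is attached to every
rejected null.

Accuracy tests operate on the discordant pairs (Wald, deviance/LRT,
McNemar with continuity correction).  The likelihood ratios are compared on
the log scale through a delta-method Wald statistic; the predictive values
through a contrast-matrix Wald statistic under the full 8-cell multinomial
and, individually, through Kosinski's weighted generalized score statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.stats import chi2, norm

from .counts import AnalysisConfig, PairedCounts, check_feasibility
from .estimate import ConfidenceInterval
from .exceptions import (
    DegenerateStatisticError,
    InfeasibleLRTError,
    InfeasibleMcNemarError,
    SingularSigmaError,
    ZeroLRError,
)

Distribution = Literal["chi2_1", "chi2_2", "std_normal"]


@dataclass(frozen=True)
class TestResult:
    """A test statistic, its reference distribution and two-sided p-value."""

    statistic: float
    distribution: Distribution
    p_value: float
    method: str

    @staticmethod
    def from_chi2(statistic: float, df: int, method: str) -> "TestResult":
        return TestResult(
            statistic=statistic,
            distribution="chi2_1" if df == 1 else "chi2_2",
            p_value=float(chi2.sf(statistic, df)),
            method=method,
        )

    @staticmethod
    def from_z(statistic: float, method: str) -> "TestResult":
        return TestResult(
            statistic=statistic,
            distribution="std_normal",
            p_value=float(2.0 * norm.sf(abs(statistic))),
            method=method,
        )


@dataclass(frozen=True)
class HolmDecision:
    reject: tuple[bool, bool]
    adjusted_p: tuple[float, float]


@dataclass(frozen=True)
class IndividualComparison:
    """One resolved individual hypothesis with its Holm decision."""

    hypothesis: str             # e.g. "Se1 = Se2"
    test: TestResult
    reject: bool
    adjusted_p: float
    larger_test: int | None = None       # which test has the larger estimate
    interval: ConfidenceInterval | None = None


@dataclass(frozen=True)
class LogRatioContrast:
    """omega = (ln PLR1/PLR2, ln NLR1/NLR2) with its delta-method covariance."""

    omega: np.ndarray
    sigma: np.ndarray


@dataclass(frozen=True)
class PVContrast:
    """eta = (PPV1, PPV2, NPV1, NPV2), its covariance and the contrast matrix."""

    eta: np.ndarray
    sigma: np.ndarray
    phi: np.ndarray


@dataclass(frozen=True)
class KosinskiComponents:
    """Pooled predictive values and C-terms of the WGS variance."""

    pooled: float
    c_term: float
    variance: float   # full denominator variance term of the statistic


@dataclass(frozen=True)
class ComparisonOutcome:
    family: Literal["accuracy", "likelihood_ratios", "predictive_values"]
    global_test: TestResult | None
    rule: str                       # which decision branch produced the outcome
    individual: tuple[IndividualComparison, ...] = ()
    notes: tuple[str, ...] = ()
    secondary_global: TestResult | None = None   # LRT alongside the Wald
    power: "object | None" = None                # PowerEstimate, filled later

    def is_global_significant(self, alpha: float) -> bool:
        if self.global_test is None:
            return any(i.reject for i in self.individual)
        return self.global_test.p_value <= alpha


# ---------------------------------------------------------------------------
# accuracy family
# ---------------------------------------------------------------------------

def wald_accuracy_tests(counts: PairedCounts) -> tuple[TestResult, TestResult, TestResult]:
    """Wald statistics for H0: Se1=Se2, H0: Sp1=Sp2 and their 2-df sum."""
    c = counts
    den_se = 4 * c.s10 * c.s01 + (c.s11 + c.s00) * (c.s10 + c.s01)
    den_sp = 4 * c.r10 * c.r01 + (c.r11 + c.r00) * (c.r10 + c.r01)
    if den_se == 0 or den_sp == 0:
        raise DegenerateStatisticError(
            "Wald accuracy statistic has a zero denominator")
    chi_se = c.s * (c.s10 - c.s01) ** 2 / den_se
    chi_sp = c.r * (c.r10 - c.r01) ** 2 / den_sp
    return (
        TestResult.from_chi2(chi_se, 1, "Wald"),
        TestResult.from_chi2(chi_sp, 1, "Wald"),
        TestResult.from_chi2(chi_se + chi_sp, 2, "Wald"),
    )


def _deviance_term(a: int, b: int) -> float:
    # a * ln(2a/(a+b)) with the 0*ln0 = 0 convention
    if a == 0:
        return 0.0
    return a * math.log(2.0 * a / (a + b))


def lrt_accuracy_tests(counts: PairedCounts) -> tuple[TestResult, TestResult, TestResult]:
    """Deviance (likelihood-ratio) statistics for the accuracy hypotheses.

    Only defined when all four discordant cells are positive.  Referred to
    chi-square (1 df individually, 2 df globally); the global statistic is the
    exact sum of the two individual deviances.
    """
    c = counts
    if min(c.s10, c.s01, c.r10, c.r01) == 0:
        raise InfeasibleLRTError(
            "likelihood-ratio test needs all discordant cells positive")
    d_se = 2.0 * (_deviance_term(c.s10, c.s01) + _deviance_term(c.s01, c.s10))
    d_sp = 2.0 * (_deviance_term(c.r10, c.r01) + _deviance_term(c.r01, c.r10))
    return (
        TestResult.from_chi2(d_se, 1, "LRT"),
        TestResult.from_chi2(d_sp, 1, "LRT"),
        TestResult.from_chi2(d_se + d_sp, 2, "LRT"),
    )


def mcnemar_cc(a: int, b: int) -> TestResult:
    """McNemar statistic with continuity correction on discordant counts."""
    if a + b == 0:
        raise InfeasibleMcNemarError("McNemar test needs a + b > 0")
    statistic = (abs(a - b) - 1) ** 2 / (a + b)
    return TestResult.from_chi2(statistic, 1, "McNemar_cc")


def bonett_laplace_diff_interval(
    a: int, b: int, group_total: int, alpha: float = 0.05,
    larger_test: int | None = None,
) -> ConfidenceInterval:
    """Bonett-Laplace-adjusted Wald interval for a paired difference of
    proportions, from the discordant counts ``a`` (positive part of the
    difference) and ``b``, over ``group_total`` subjects.  Clipped to [-1, 1].
    """
    t = group_total + 2
    centre = (a - b) / t
    half = _z(alpha) * math.sqrt((a + b + 2) / t**2 - (a - b) ** 2 / t**3)
    return ConfidenceInterval(
        lower=max(-1.0, centre - half),
        upper=min(1.0, centre + half),
        level=1.0 - alpha,
        scale="difference",
        larger_test=larger_test,
    )


def holm_adjust(p_values: tuple[float, float], alpha: float = 0.05) -> HolmDecision:
    """Holm step-down for two hypotheses.

    The smaller p-value is tested at alpha/2; only if rejected is the larger
    tested at alpha.  Adjusted p-values follow the step-down monotonicity:
    p_adj(min) = min(1, 2 p_min) and p_adj(max) = min(1, max(p_max, 2 p_min)).
    """
    p = list(p_values)
    order = sorted(range(2), key=lambda i: p[i])
    p_min, p_max = p[order[0]], p[order[1]]
    adj_min = min(1.0, 2.0 * p_min)
    adj_max = min(1.0, max(p_max, adj_min))
    reject_min = p_min <= alpha / 2.0
    reject_max = reject_min and p_max <= alpha
    reject = [False, False]
    adjusted = [0.0, 0.0]
    reject[order[0]], reject[order[1]] = reject_min, reject_max
    adjusted[order[0]], adjusted[order[1]] = adj_min, adj_max
    return HolmDecision(reject=(reject[0], reject[1]),
                        adjusted_p=(adjusted[0], adjusted[1]))


def _z(alpha: float) -> float:
    return float(norm.ppf(1.0 - alpha / 2.0))


def _resolve_accuracy_individuals(
    counts: PairedCounts,
    tests: tuple[TestResult, TestResult],
    alpha: float,
) -> tuple[IndividualComparison, IndividualComparison]:
    """Holm-resolve the Se and Sp individual tests and attach oriented
    Bonett-Laplace intervals to rejected nulls."""
    c = counts
    holm = holm_adjust((tests[0].p_value, tests[1].p_value), alpha)
    out = []
    for k, (name, test) in enumerate(zip(("Se1 = Se2", "Sp1 = Sp2"), tests)):
        reject = holm.reject[k]
        larger = None
        interval = None
        if reject:
            if name.startswith("Se"):
                # Se1 - Se2 is proportional to s10 - s01
                larger = 1 if c.s10 >= c.s01 else 2
                a, b = (c.s10, c.s01) if larger == 1 else (c.s01, c.s10)
                interval = bonett_laplace_diff_interval(a, b, c.s, alpha, larger)
            else:
                # Sp1 - Sp2 is proportional to r01 - r10
                larger = 1 if c.r01 >= c.r10 else 2
                a, b = (c.r01, c.r10) if larger == 1 else (c.r10, c.r01)
                interval = bonett_laplace_diff_interval(a, b, c.r, alpha, larger)
        out.append(IndividualComparison(
            hypothesis=name, test=test, reject=reject,
            adjusted_p=holm.adjusted_p[k], larger_test=larger,
            interval=interval))
    return (out[0], out[1])


def compare_accuracies(counts: PairedCounts, config: AnalysisConfig) -> ComparisonOutcome:
    """Compare the two sensitivities and specificities.

    Decision rules (prevalence p and sample size n):

    (a) p <= 0.10 and n <= 100 -> no global test; the two individual Wald
        tests are solved directly with Holm at alpha.
    (b) otherwise -> global 2-df Wald test (the deviance version is reported
        alongside when the discordant cells allow it); if significant, the
        individual hypotheses are resolved with Holm using the Wald tests when
        n <= 100 or n >= 1000 and the McNemar tests with continuity correction
        when 100 < n < 1000.
    """
    c = counts
    alpha = config.alpha
    feas = check_feasibility(c)
    notes: list[str] = []

    if c.prevalence <= 0.10 and c.n <= 100:
        # rule (a): individual tests only
        if not (feas.wald_se.feasible and feas.wald_sp.feasible):
            bad = feas.wald_se if not feas.wald_se.feasible else feas.wald_sp
            notes.append(f"not computable: {bad.reason}")
            return ComparisonOutcome("accuracy", None, rule="individual_only",
                                     notes=tuple(notes))
        chi_se, chi_sp, _ = wald_accuracy_tests(c)
        individual = _resolve_accuracy_individuals(c, (chi_se, chi_sp), alpha)
        return ComparisonOutcome("accuracy", None, rule="individual_only",
                                 individual=individual, notes=tuple(notes))

    # rule (b): global first
    if not (feas.wald_se.feasible and feas.wald_sp.feasible):
        bad = feas.wald_se if not feas.wald_se.feasible else feas.wald_sp
        notes.append(f"not computable: {bad.reason}")
        return ComparisonOutcome("accuracy", None, rule="global_first",
                                 notes=tuple(notes))
    chi_se, chi_sp, chi_global = wald_accuracy_tests(c)
    secondary = None
    if feas.lrt_global:
        secondary = lrt_accuracy_tests(c)[2]
    else:
        notes.append("deviance (LRT) global test not computable: "
                     "a discordant cell is 0")

    if chi_global.p_value > alpha:
        return ComparisonOutcome("accuracy", chi_global, rule="global_first",
                                 secondary_global=secondary, notes=tuple(notes))

    if 100 < c.n < 1000:
        if not (feas.mcnemar_se.feasible and feas.mcnemar_sp.feasible):
            bad = feas.mcnemar_se if not feas.mcnemar_se.feasible else feas.mcnemar_sp
            notes.append(f"individual tests not computable: {bad.reason}")
            return ComparisonOutcome("accuracy", chi_global, rule="global_first",
                                     secondary_global=secondary, notes=tuple(notes))
        ind_tests = (mcnemar_cc(c.s10, c.s01), mcnemar_cc(c.r10, c.r01))
        rule = "global_then_mcnemar_cc"
    else:
        ind_tests = (chi_se, chi_sp)
        rule = "global_then_wald"
    individual = _resolve_accuracy_individuals(c, ind_tests, alpha)
    return ComparisonOutcome("accuracy", chi_global, rule=rule,
                             individual=individual,
                             secondary_global=secondary, notes=tuple(notes))


# ---------------------------------------------------------------------------
# likelihood-ratio family
# ---------------------------------------------------------------------------

def _se_sp_moments(counts: PairedCounts) -> tuple[np.ndarray, np.ndarray]:
    """Estimates (Se1, Se2, Sp1, Sp2) and their 4x4 covariance.

    The diseased and non-diseased groups are independent; within a group the
    two tests' proportions are paired through the joint cell:
    Cov(Se1, Se2) = (s11/s - Se1 Se2)/s and Cov(Sp1, Sp2) = (r00/r - Sp1 Sp2)/r.
    """
    c = counts
    se1, se2 = c.sensitivity(1), c.sensitivity(2)
    sp1, sp2 = c.specificity(1), c.specificity(2)
    v = np.array([se1 * (1 - se1) / c.s, se2 * (1 - se2) / c.s,
                  sp1 * (1 - sp1) / c.r, sp2 * (1 - sp2) / c.r])
    cov_se = (c.s11 / c.s - se1 * se2) / c.s
    cov_sp = (c.r00 / c.r - sp1 * sp2) / c.r
    sigma = np.diag(v)
    sigma[0, 1] = sigma[1, 0] = cov_se
    sigma[2, 3] = sigma[3, 2] = cov_sp
    return np.array([se1, se2, sp1, sp2]), sigma


def lr_contrast(counts: PairedCounts) -> LogRatioContrast:
    """Log-ratio vector of the paired likelihood ratios and its delta-method
    covariance.

    omega = (ln(PLR1/PLR2), ln(NLR1/NLR2)); the gradient of each component
    with respect to (Se1, Se2, Sp1, Sp2) propagates the within-group binomial
    covariance structure.
    """
    theta, sigma4 = _se_sp_moments(counts)
    se1, se2, sp1, sp2 = theta
    if not (0 < se1 < 1 and 0 < se2 < 1 and 0 < sp1 < 1 and 0 < sp2 < 1):
        raise ZeroLRError(
            "likelihood-ratio contrast needs every Se and Sp strictly in (0,1)")
    omega = np.array([
        math.log(se1 / se2) - math.log((1 - sp1) / (1 - sp2)),
        math.log((1 - se1) / (1 - se2)) - math.log(sp1 / sp2),
    ])
    grad = np.array([
        [1 / se1, -1 / se2, 1 / (1 - sp1), -1 / (1 - sp2)],
        [-1 / (1 - se1), 1 / (1 - se2), -1 / sp1, 1 / sp2],
    ])
    sigma = grad @ sigma4 @ grad.T
    return LogRatioContrast(omega=omega, sigma=sigma)


def compare_lrs(counts: PairedCounts, config: AnalysisConfig) -> ComparisonOutcome:
    """Compare the positive and negative likelihood ratios simultaneously.

    Global 2-df Wald statistic omega' Sigma^-1 omega; when significant the two
    individual z statistics are Holm-resolved and a ratio interval (log-scale
    for the PLRs, Wald-type for the NLRs) oriented above 1 is attached to each
    rejected null.
    """
    alpha = config.alpha
    feas = check_feasibility(counts)
    if not feas.lr_family.feasible:
        return ComparisonOutcome(
            "likelihood_ratios", None, rule="global_first",
            notes=(f"not computable: {feas.lr_family.reason}",))
    contrast = lr_contrast(counts)
    det = float(np.linalg.det(contrast.sigma))
    if det <= 0 or not np.isfinite(det):
        return ComparisonOutcome(
            "likelihood_ratios", None, rule="global_first",
            notes=("not computable: the estimated covariance of the log-ratios "
                   "is singular",))
    stat = float(contrast.omega @ np.linalg.solve(contrast.sigma, contrast.omega))
    global_test = TestResult.from_chi2(stat, 2, "Wald")
    if global_test.p_value > alpha:
        return ComparisonOutcome("likelihood_ratios", global_test,
                                 rule="global_first")

    z_plr = contrast.omega[0] / math.sqrt(contrast.sigma[0, 0])
    z_nlr = contrast.omega[1] / math.sqrt(contrast.sigma[1, 1])
    tests = (TestResult.from_z(z_plr, "log_ratio_z"),
             TestResult.from_z(z_nlr, "log_ratio_z"))
    holm = holm_adjust((tests[0].p_value, tests[1].p_value), alpha)

    individual = []
    for k, (name, test) in enumerate(zip(("PLR1 = PLR2", "NLR1 = NLR2"), tests)):
        larger = None
        interval = None
        if holm.reject[k]:
            omega_k = contrast.omega[k]
            var_k = contrast.sigma[k, k]
            larger = 1 if omega_k > 0 else 2
            ratio = math.exp(abs(omega_k))      # oriented larger/smaller > 1
            z = _z(alpha)
            if name.startswith("PLR"):
                lo = ratio * math.exp(-z * math.sqrt(var_k))
                hi = ratio * math.exp(z * math.sqrt(var_k))
            else:
                lo = ratio * (1.0 - z * math.sqrt(var_k))
                hi = ratio * (1.0 + z * math.sqrt(var_k))
            interval = ConfidenceInterval(max(0.0, lo), hi, 1.0 - alpha,
                                          scale="ratio", larger_test=larger)
        individual.append(IndividualComparison(
            hypothesis=name, test=test, reject=holm.reject[k],
            adjusted_p=holm.adjusted_p[k], larger_test=larger,
            interval=interval))
    return ComparisonOutcome("likelihood_ratios", global_test,
                             rule="global_then_z",
                             individual=tuple(individual))


# ---------------------------------------------------------------------------
# predictive-value family
# ---------------------------------------------------------------------------

# cell order (s11, s10, s01, s00, r11, r10, r01, r00); each PV is a ratio
# a/(a+b) with index sets (numerator cells, complementary cells)
_PV_INDEX = {
    "PPV1": ((0, 1), (4, 5)),
    "PPV2": ((0, 2), (4, 6)),
    "NPV1": ((7, 6), (3, 2)),
    "NPV2": ((7, 5), (3, 1)),
}

PHI = np.array([[1.0, -1.0, 0.0, 0.0],
                [0.0, 0.0, 1.0, -1.0]])


def pv_global_test(counts: PairedCounts) -> tuple[TestResult, PVContrast]:
    """Global 2-df Wald test of simultaneous equality of the predictive values.

    eta = (PPV1, PPV2, NPV1, NPV2) are smooth functions of the eight cell
    proportions of one multinomial of size n (prevalence random), so Sigma is
    obtained by the delta method through that multinomial covariance.
    """
    c = counts
    cells = np.asarray(c.cells(), dtype=float)
    n = cells.sum()
    p = cells / n
    eta = np.empty(4)
    jac = np.zeros((4, 8))
    for k, (ia, ib) in enumerate(_PV_INDEX.values()):
        a = p[list(ia)].sum()
        b = p[list(ib)].sum()
        if a + b == 0:
            raise DegenerateStatisticError(
                "a predictive value has an empty test margin")
        eta[k] = a / (a + b)
        for i in ia:
            jac[k, i] = b / (a + b) ** 2
        for i in ib:
            jac[k, i] = -a / (a + b) ** 2
    mult_cov = (np.diag(p) - np.outer(p, p)) / n
    sigma = jac @ mult_cov @ jac.T
    contrast = PVContrast(eta=eta, sigma=sigma, phi=PHI)
    mid = PHI @ sigma @ PHI.T
    det = float(np.linalg.det(mid))
    if det <= 0 or not np.isfinite(det):
        raise SingularSigmaError("contrast covariance of the PVs is singular")
    d = PHI @ eta
    stat = float(d @ np.linalg.solve(mid, d))
    return TestResult.from_chi2(stat, 2, "Wald"), contrast


def kosinski_wgs(
    counts: PairedCounts, which: Literal["PPV", "NPV"]
) -> tuple[TestResult, KosinskiComponents]:
    """Kosinski's weighted generalized score statistic for one PV pair.

    The pooled predictive value weights both tests' margins; the C term
    removes the paired covariance.  Referred to chi-square with 1 df.
    """
    c = counts
    if which == "PPV":
        den = 2 * c.n11 + c.n10 + c.n01
        if den == 0 or c.n1_dot == 0 or c.n_dot1 == 0:
            raise DegenerateStatisticError("PPV comparison has an empty margin")
        pooled = (2 * c.s11 + c.s10 + c.s01) / den
        c_term = (c.s11 * (1 - pooled) ** 2 + c.r11 * pooled**2) / den
        weight = 1.0 / c.n1_dot + 1.0 / c.n_dot1
        diff = c.s1_dot / c.n1_dot - c.s_dot1 / c.n_dot1
    else:
        den = 2 * c.n00 + c.n01 + c.n10
        if den == 0 or c.n0_dot == 0 or c.n_dot0 == 0:
            raise DegenerateStatisticError("NPV comparison has an empty margin")
        pooled = (2 * c.r00 + c.r01 + c.r10) / den
        c_term = (c.s00 * pooled**2 + c.r00 * (1 - pooled) ** 2) / den
        weight = 1.0 / c.n0_dot + 1.0 / c.n_dot0
        diff = c.r0_dot / c.n0_dot - c.r_dot0 / c.n_dot0
    variance = (pooled * (1 - pooled) - 2 * c_term) * weight
    if variance <= 0:
        if diff == 0.0:
            # exactly concordant tests: the null value, 0/0 resolved as 0
            statistic = 0.0
            variance = 0.0
            return (TestResult.from_chi2(statistic, 1, "WGS"),
                    KosinskiComponents(pooled=pooled, c_term=c_term,
                                       variance=variance))
        raise DegenerateStatisticError(
            f"WGS variance term for the {which}s is not positive")
    statistic = diff**2 / variance
    return (TestResult.from_chi2(statistic, 1, "WGS"),
            KosinskiComponents(pooled=pooled, c_term=c_term, variance=variance))


def pv_diff_interval(
    counts: PairedCounts, which: Literal["PPV", "NPV"], alpha: float = 0.05
) -> ConfidenceInterval:
    """Difference interval obtained by inverting the WGS statistic, oriented
    so the reported difference (larger minus smaller) is positive."""
    c = counts
    _, comps = kosinski_wgs(counts, which)
    if which == "PPV":
        v1, v2 = c.s1_dot / c.n1_dot, c.s_dot1 / c.n_dot1
    else:
        v1, v2 = c.r0_dot / c.n0_dot, c.r_dot0 / c.n_dot0
    larger = 1 if v1 >= v2 else 2
    centre = abs(v1 - v2)
    half = _z(alpha) * math.sqrt(comps.variance)
    return ConfidenceInterval(
        lower=max(-1.0, centre - half),
        upper=min(1.0, centre + half),
        level=1.0 - alpha,
        scale="difference",
        larger_test=larger,
    )


def compare_pvs(counts: PairedCounts, config: AnalysisConfig) -> ComparisonOutcome:
    """Compare the predictive values: global contrast Wald test, then the
    Kosinski WGS individual tests with Holm, with inverted-statistic
    difference intervals for rejected nulls."""
    alpha = config.alpha
    feas = check_feasibility(counts)
    if not feas.pv_family.feasible:
        return ComparisonOutcome(
            "predictive_values", None, rule="global_first",
            notes=(f"not computable: {feas.pv_family.reason}",))
    try:
        global_test, _ = pv_global_test(counts)
    except (DegenerateStatisticError, SingularSigmaError) as exc:
        return ComparisonOutcome("predictive_values", None, rule="global_first",
                                 notes=(f"not computable: {exc}",))
    if global_test.p_value > alpha:
        return ComparisonOutcome("predictive_values", global_test,
                                 rule="global_first")

    results = {}
    for which in ("PPV", "NPV"):
        try:
            results[which] = kosinski_wgs(counts, which)
        except DegenerateStatisticError as exc:
            return ComparisonOutcome(
                "predictive_values", global_test, rule="global_first",
                notes=(f"individual tests not computable: {exc}",))
    tests = (results["PPV"][0], results["NPV"][0])
    holm = holm_adjust((tests[0].p_value, tests[1].p_value), alpha)

    c = counts
    values = {
        "PPV": (c.s1_dot / c.n1_dot, c.s_dot1 / c.n_dot1),
        "NPV": (c.r0_dot / c.n0_dot, c.r_dot0 / c.n_dot0),
    }
    individual = []
    for k, which in enumerate(("PPV", "NPV")):
        larger = None
        interval = None
        if holm.reject[k]:
            v1, v2 = values[which]
            larger = 1 if v1 >= v2 else 2
            interval = pv_diff_interval(counts, which, alpha)
        individual.append(IndividualComparison(
            hypothesis=f"{which}1 = {which}2", test=tests[k],
            reject=holm.reject[k], adjusted_p=holm.adjusted_p[k],
            larger_test=larger, interval=interval))
    return ComparisonOutcome("predictive_values", global_test,
                             rule="global_then_wgs",
                             individual=tuple(individual))
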