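"""Point estimates, standard errors and confidence intervals.

Sensitivity, specificity and the predictive values are binomial proportions;
their intervals use the modified-Wilson interval of Yu, Guo and Xu, which has
the best coverage/width trade-off among the standard proportion intervals.
The likelihood ratios are ratios of two independent binomial proportions
(relative risks); their intervals use the Martín-Andrés & Álvarez-Hernández
approximate score method on counts adjusted by +0.5, with closed-form limit
replacements at the boundaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

from .counts import PairedCounts
from .exceptions import InvalidTrialsError

__all__ = [
    "PointEstimate",
    "ConfidenceInterval",
    "ParameterSummary",
    "AdjustedCounts",
    "yu_interval",
    "estimate_prevalence",
    "estimate_proportion_params",
    "estimate_likelihood_ratios",
    "score_ratio_interval",
]


@dataclass(frozen=True)
class PointEstimate:
    """A parameter estimate and its standard error."""

    value: float
    se: float | None
    label: str


@dataclass(frozen=True)
class ConfidenceInterval:
    lower: float
    upper: float
    level: float
    scale: Literal["proportion", "ratio", "difference"] = "proportion"
    larger_test: int | None = None  # orientation of contrast intervals


@dataclass(frozen=True)
class ParameterSummary:
    """Estimate + interval for one parameter; ``error`` explains a missing one."""

    label: str
    estimate: PointEstimate | None
    interval: ConfidenceInterval | None
    error: str | None = None


@dataclass(frozen=True)
class AdjustedCounts:
    """Margins and totals after adding 0.5 to each observed margin.

    Used by the score-type interval for the likelihood ratios; the adjustment
    keeps every quantity strictly positive whatever the observed zeros.
    """

    s1_dot: float
    s0_dot: float
    s_dot1: float
    s_dot0: float
    r1_dot: float
    r0_dot: float
    r_dot1: float
    r_dot0: float
    s: float
    r: float
    n: float

    @classmethod
    def from_counts(cls, c: PairedCounts) -> "AdjustedCounts":
        return cls(
            s1_dot=c.s1_dot + 0.5, s0_dot=c.s0_dot + 0.5,
            s_dot1=c.s_dot1 + 0.5, s_dot0=c.s_dot0 + 0.5,
            r1_dot=c.r1_dot + 0.5, r0_dot=c.r0_dot + 0.5,
            r_dot1=c.r_dot1 + 0.5, r_dot0=c.r_dot0 + 0.5,
            s=c.s + 1.0, r=c.r + 1.0, n=c.n + 2.0,
        )


def _z(alpha: float) -> float:
    from scipy.stats import norm

    return float(norm.ppf(1.0 - alpha / 2.0))


def yu_interval(successes: int, trials: int, alpha: float = 0.05) -> ConfidenceInterval:
    """Modified-Wilson (Yu et al.) interval for a binomial proportion.

    The centre shrinks the sample proportion towards 1/2 by the factor
    ``(m + z^4/53) / (m + z^2)`` and the half-width is the Wilson one,
    ``z/(m + z^2) * sqrt(m p(1-p) + z^2/4)``.  The result is clipped to
    [0, 1].
    """
    if trials < 1 or not 0 <= successes <= trials:
        raise InvalidTrialsError(
            f"need 0 <= successes <= trials with trials >= 1, "
            f"got successes={successes}, trials={trials}")
    z = _z(alpha)
    m = float(trials)
    p_hat = successes / m
    centre = 0.5 + (m + z**4 / 53.0) / (m + z**2) * (p_hat - 0.5)
    half = z / (m + z**2) * math.sqrt(m * p_hat * (1.0 - p_hat) + z**2 / 4.0)
    return ConfidenceInterval(
        lower=max(0.0, centre - half),
        upper=min(1.0, centre + half),
        level=1.0 - alpha,
        scale="proportion",
    )


def estimate_prevalence(counts: PairedCounts, alpha: float = 0.05) -> ParameterSummary:
    """Disease prevalence p = s/n with binomial SE and Yu interval."""
    p = counts.prevalence
    se = math.sqrt(p * (1.0 - p) / counts.n)
    return ParameterSummary(
        label="prevalence",
        estimate=PointEstimate(p, se, "prevalence"),
        interval=yu_interval(counts.s, counts.n, alpha),
    )


def _proportion_summary(label: str, successes: int, trials: int,
                        se: float | None, alpha: float) -> ParameterSummary:
    if trials == 0:
        return ParameterSummary(label, None, None,
                                error=f"{label} undefined: zero denominator")
    value = successes / trials
    return ParameterSummary(
        label,
        PointEstimate(value, se, label),
        yu_interval(successes, trials, alpha),
    )


def estimate_proportion_params(
    counts: PairedCounts, alpha: float = 0.05
) -> dict[str, ParameterSummary]:
    """Estimates, SEs and Yu intervals for Se, Sp, PPV and NPV of both tests.

    The sensitivities/specificities are conditional proportions over the
    diseased/non-diseased groups; the predictive values are proportions over
    the pooled test margins, with SE = sqrt(a*b/(a+b)^3) for a margin split
    into a diseased part ``a`` and non-diseased part ``b``.
    """
    c = counts

    def prop_se(k: int, m: int) -> float | None:
        if m == 0:
            return None
        p = k / m
        return math.sqrt(p * (1.0 - p) / m)

    def margin_se(a: int, b: int) -> float | None:
        t = a + b
        if t == 0:
            return None
        return math.sqrt(a * b / t**3)

    return {
        "Se1": _proportion_summary("Se1", c.s1_dot, c.s, prop_se(c.s1_dot, c.s), alpha),
        "Se2": _proportion_summary("Se2", c.s_dot1, c.s, prop_se(c.s_dot1, c.s), alpha),
        "Sp1": _proportion_summary("Sp1", c.r0_dot, c.r, prop_se(c.r0_dot, c.r), alpha),
        "Sp2": _proportion_summary("Sp2", c.r_dot0, c.r, prop_se(c.r_dot0, c.r), alpha),
        "PPV1": _proportion_summary("PPV1", c.s1_dot, c.n1_dot,
                                    margin_se(c.s1_dot, c.r1_dot), alpha),
        "PPV2": _proportion_summary("PPV2", c.s_dot1, c.n_dot1,
                                    margin_se(c.s_dot1, c.r_dot1), alpha),
        "NPV1": _proportion_summary("NPV1", c.r0_dot, c.n0_dot,
                                    margin_se(c.s0_dot, c.r0_dot), alpha),
        "NPV2": _proportion_summary("NPV2", c.r_dot0, c.n_dot0,
                                    margin_se(c.s_dot0, c.r_dot0), alpha),
    }


def estimate_likelihood_ratios(
    counts: PairedCounts, alpha: float = 0.05
) -> dict[str, ParameterSummary]:
    """Estimates, delta-method SEs and score intervals for PLR and NLR.

    PLR_i = Se_i/(1-Sp_i) and NLR_i = (1-Se_i)/Sp_i; an LR whose denominator
    proportion is 0 is reported as undefined, and an LR estimated as exactly 0
    is reported with an undefined SE (boundary of the parameter space).
    """
    c = counts
    out: dict[str, ParameterSummary] = {}
    specs = {
        "PLR1": (c.s1_dot, c.r1_dot, c.sensitivity(1), 1.0 - c.specificity(1)),
        "PLR2": (c.s_dot1, c.r_dot1, c.sensitivity(2), 1.0 - c.specificity(2)),
        "NLR1": (c.s0_dot, c.r0_dot, 1.0 - c.sensitivity(1), c.specificity(1)),
        "NLR2": (c.s_dot0, c.r_dot0, 1.0 - c.sensitivity(2), c.specificity(2)),
    }
    for label, (num_margin, den_margin, p_num, p_den) in specs.items():
        if den_margin == 0:
            out[label] = ParameterSummary(
                label, None, None,
                error=f"{label} undefined: denominator proportion is 0")
            continue
        value = (c.r * num_margin) / (c.s * den_margin)
        test = 1 if label.endswith("1") else 2
        se = _lr_se(label, counts, test)
        if num_margin == 0:
            out[label] = ParameterSummary(
                label, PointEstimate(0.0, None, label),
                score_ratio_interval(counts, label, alpha),  # adjustment handles 0
                error=f"{label} estimated at the boundary 0; SE undefined")
            continue
        out[label] = ParameterSummary(
            label,
            PointEstimate(value, se, label),
            score_ratio_interval(counts, label, alpha),
        )
    return out


def _lr_se(label: str, c: PairedCounts, test: int) -> float | None:
    se_hat = c.sensitivity(test)
    sp_hat = c.specificity(test)
    var_se = se_hat * (1.0 - se_hat) / c.s
    var_sp = sp_hat * (1.0 - sp_hat) / c.r
    if label.startswith("PLR"):
        if sp_hat == 1.0:
            return None
        return math.sqrt(
            (se_hat**2 * var_sp + (1.0 - sp_hat) ** 2 * var_se)
            / (1.0 - sp_hat) ** 4)
    if sp_hat == 0.0:
        return None
    return math.sqrt(
        ((1.0 - se_hat) ** 2 * var_sp + sp_hat**2 * var_se) / sp_hat**4)


def _score_ratio_limits(a: float, s_t: float, b: float, r_t: float,
                        point: float, z: float) -> tuple[float, float]:
    """Approximate score interval for the ratio (a/s_t)/(b/r_t) of two
    independent binomial proportions, on already-adjusted counts.

    ``a``/``b`` are the adjusted numerator/denominator margins, ``s_t``/``r_t``
    the adjusted group totals, ``point`` the unadjusted point estimate used by
    the boundary-replacement rules.
    """
    n_t = s_t + r_t
    p1 = a / s_t
    q = b / r_t
    disc = (n_t**2 * a * b * (a + b - n_t * p1 * q)
            + z**2 / 4.0 * (s_t * a - r_t * b) ** 2)
    base = n_t * a * b + z**2 / 2.0 * (s_t * a + r_t * b - 2.0 * a * b)
    den = b * (n_t * s_t * q - z**2 * (s_t - b))
    lower = (base - z * math.sqrt(max(0.0, disc))) / den
    upper = (base + z * math.sqrt(max(0.0, disc))) / den

    if lower < a / (n_t - b) or lower > point:
        lower = (a * q + z**2 / 2.0
                 - z * math.sqrt(max(0.0, z**2 / 4.0 + a * (q - p1)))) \
            / (s_t * q**2 + z**2)
    if upper > (n_t - a) / b or upper < point:
        upper = (b * p1 + z**2 / 2.0
                 + z * math.sqrt(max(0.0, z**2 / 4.0 + b * (p1 - q)))) \
            / (r_t * q**2)
    return max(0.0, lower), upper


def score_ratio_interval(
    counts: PairedCounts,
    which: Literal["PLR1", "PLR2", "NLR1", "NLR2"],
    alpha: float = 0.05,
) -> ConfidenceInterval:
    """Martín-Andrés score-type interval for one likelihood ratio.

    Computed on +0.5-adjusted margins, so it exists whatever the observed
    zero pattern; always a positive interval.
    """
    adj = AdjustedCounts.from_counts(counts)
    c = counts
    margins = {
        "PLR1": (adj.s1_dot, adj.r1_dot, c.s1_dot, c.r1_dot),
        "PLR2": (adj.s_dot1, adj.r_dot1, c.s_dot1, c.r_dot1),
        "NLR1": (adj.s0_dot, adj.r0_dot, c.s0_dot, c.r0_dot),
        "NLR2": (adj.s_dot0, adj.r_dot0, c.s_dot0, c.r_dot0),
    }
    a, b, raw_num, raw_den = margins[which]
    # unadjusted point estimate when defined, else the adjusted one
    if raw_den > 0:
        point = (c.r * raw_num) / (c.s * raw_den)
    else:
        point = (adj.r * a) / (adj.s * b)
    lower, upper = _score_ratio_limits(a, adj.s, b, adj.r, point, _z(alpha))
    return ConfidenceInterval(lower, upper, 1.0 - alpha, scale="ratio")
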