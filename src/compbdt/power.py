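"""Monte Carlo retrospective power / type-II-error estimation.

For each family the operating characteristic of the global test actually
applied to the observed table is estimated by resampling: replicates are
drawn from a multinomial with the observed sample size and the observed cell
relative frequencies, the family's global test is applied at the same alpha
to each, and the rejection fraction is the power (when the observed global
test was significant) or one minus the type-II-error probability (when it
was not).  Replicates on which the test cannot be computed are regenerated,
so exactly ``reps`` valid replicates contribute.

The per-replicate statistics are vectorized over all replicates; the same
machinery drives the calibration checks of the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np
from scipy.stats import chi2

from .counts import AnalysisConfig, PairedCounts, validate_counts
from .exceptions import NonIdentifiablePowerError, ResamplingCapError

Family = Literal["accuracy", "likelihood_ratios", "predictive_values"]

__all__ = [
    "PowerEstimate",
    "sample_paired_table",
    "rejection_rate",
    "estimate_power",
]


@dataclass(frozen=True)
class PowerEstimate:
    mode: Literal["power", "type_II_error"]
    value: float
    mc_se: float
    reps_used: int
    resampled: int
    test_used: str

    @property
    def power(self) -> float:
        return self.value if self.mode == "power" else 1.0 - self.value


def sample_paired_table(
    probs: np.ndarray, n: int, rng: np.random.Generator
) -> PairedCounts:
    """One multinomial draw of ``n`` subjects arranged as a PairedCounts."""
    probs = np.asarray(probs, dtype=float)
    if probs.shape != (8,) or not math.isclose(probs.sum(), 1.0, rel_tol=1e-9):
        raise ValueError("probs must be 8 cell proportions summing to 1")
    draw = rng.multinomial(n, probs)
    return validate_counts(*[int(x) for x in draw])


# ---------------------------------------------------------------------------
# vectorized per-replicate global statistics: each takes an integer array of
# shape (reps, 8) in canonical cell order and returns (statistic, feasible)
# ---------------------------------------------------------------------------

def _accuracy_global(cells: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    s11, s10, s01, s00, r11, r10, r01, r00 = cells.T.astype(float)
    s = s11 + s10 + s01 + s00
    r = r11 + r10 + r01 + r00
    den_se = 4 * s10 * s01 + (s11 + s00) * (s10 + s01)
    den_sp = 4 * r10 * r01 + (r11 + r00) * (r10 + r01)
    feasible = (den_se > 0) & (den_sp > 0) & (s > 0) & (r > 0)
    den_se = np.where(den_se > 0, den_se, 1.0)
    den_sp = np.where(den_sp > 0, den_sp, 1.0)
    stat = s * (s10 - s01) ** 2 / den_se + r * (r10 - r01) ** 2 / den_sp
    return stat, feasible


def _accuracy_individual_holm(cells: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    """Rejection indicator for the rule-(a) procedure: Holm over the two
    individual Wald statistics rejects at least one (i.e. min p <= alpha/2)."""
    s11, s10, s01, s00, r11, r10, r01, r00 = cells.T.astype(float)
    s = s11 + s10 + s01 + s00
    r = r11 + r10 + r01 + r00
    den_se = 4 * s10 * s01 + (s11 + s00) * (s10 + s01)
    den_sp = 4 * r10 * r01 + (r11 + r00) * (r10 + r01)
    feasible = (den_se > 0) & (den_sp > 0)
    den_se = np.where(den_se > 0, den_se, 1.0)
    den_sp = np.where(den_sp > 0, den_sp, 1.0)
    chi_se = s * (s10 - s01) ** 2 / den_se
    chi_sp = r * (r10 - r01) ** 2 / den_sp
    crit = chi2.isf(alpha / 2.0, 1)
    reject = np.maximum(chi_se, chi_sp) >= crit
    return reject.astype(float), feasible


def _lr_global(cells: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    s11, s10, s01, s00, r11, r10, r01, r00 = cells.T.astype(float)
    s = s11 + s10 + s01 + s00
    r = r11 + r10 + r01 + r00
    with np.errstate(divide="ignore", invalid="ignore"):
        se1, se2 = (s11 + s10) / s, (s11 + s01) / s
        sp1, sp2 = (r01 + r00) / r, (r10 + r00) / r
    feasible = ((se1 > 0) & (se1 < 1) & (se2 > 0) & (se2 < 1)
                & (sp1 > 0) & (sp1 < 1) & (sp2 > 0) & (sp2 < 1))
    eps = 1e-12
    se1, se2, sp1, sp2 = (np.clip(x, eps, 1 - eps) for x in (se1, se2, sp1, sp2))
    v_se1, v_se2 = se1 * (1 - se1) / s, se2 * (1 - se2) / s
    v_sp1, v_sp2 = sp1 * (1 - sp1) / r, sp2 * (1 - sp2) / r
    c_se = (s11 / s - se1 * se2) / s
    c_sp = (r00 / r - sp1 * sp2) / r
    w1 = np.log(se1 / se2) - np.log((1 - sp1) / (1 - sp2))
    w2 = np.log((1 - se1) / (1 - se2)) - np.log(sp1 / sp2)
    s_11 = (v_se1 / se1**2 + v_se2 / se2**2 - 2 * c_se / (se1 * se2)
            + v_sp1 / (1 - sp1) ** 2 + v_sp2 / (1 - sp2) ** 2
            - 2 * c_sp / ((1 - sp1) * (1 - sp2)))
    s_22 = (v_se1 / (1 - se1) ** 2 + v_se2 / (1 - se2) ** 2
            - 2 * c_se / ((1 - se1) * (1 - se2))
            + v_sp1 / sp1**2 + v_sp2 / sp2**2 - 2 * c_sp / (sp1 * sp2))
    s_12 = (-v_se1 / (se1 * (1 - se1)) - v_se2 / (se2 * (1 - se2))
            + c_se / (se1 * (1 - se2)) + c_se / (se2 * (1 - se1))
            - v_sp1 / (sp1 * (1 - sp1)) - v_sp2 / (sp2 * (1 - sp2))
            + c_sp / ((1 - sp1) * sp2) + c_sp / ((1 - sp2) * sp1))
    det = s_11 * s_22 - s_12**2
    feasible &= det > 0
    det = np.where(det > 0, det, 1.0)
    stat = (s_22 * w1**2 - 2 * s_12 * w1 * w2 + s_11 * w2**2) / det
    return stat, feasible


# cell index sets of each predictive value (numerator, complement), canonical
# order (s11, s10, s01, s00, r11, r10, r01, r00)
_PV_PAIRS = (((0, 1), (4, 5)), ((0, 2), (4, 6)), ((7, 6), (3, 2)), ((7, 5), (3, 1)))


def _pv_global(cells: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    counts = cells.astype(float)
    n = counts.sum(axis=1)
    p = counts / n[:, None]
    reps = len(counts)
    eta = np.empty((reps, 4))
    jac = np.zeros((reps, 4, 8))
    feasible = np.ones(reps, dtype=bool)
    for k, (ia, ib) in enumerate(_PV_PAIRS):
        a = p[:, ia].sum(axis=1)
        b = p[:, ib].sum(axis=1)
        tot = a + b
        feasible &= tot > 0
        tot = np.where(tot > 0, tot, 1.0)
        eta[:, k] = a / tot
        for i in ia:
            jac[:, k, i] = b / tot**2
        for i in ib:
            jac[:, k, i] = -a / tot**2
    phi = np.array([[1.0, -1.0, 0.0, 0.0], [0.0, 0.0, 1.0, -1.0]])
    grad = np.einsum("ij,njk->nik", phi, jac)
    grad_p = np.einsum("nik,nk->ni", grad, p)
    cov = (np.einsum("nik,njk,nk->nij", grad, grad, p)
           - np.einsum("ni,nj->nij", grad_p, grad_p)) / n[:, None, None]
    d = np.einsum("ij,nj->ni", phi, eta)
    det = cov[:, 0, 0] * cov[:, 1, 1] - cov[:, 0, 1] ** 2
    feasible &= det > 0
    det = np.where(det > 0, det, 1.0)
    stat = (cov[:, 1, 1] * d[:, 0] ** 2 - 2 * cov[:, 0, 1] * d[:, 0] * d[:, 1]
            + cov[:, 0, 0] * d[:, 1] ** 2) / det
    return stat, feasible


_GLOBAL_STATS: dict[Family, Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]]] = {
    "accuracy": _accuracy_global,
    "likelihood_ratios": _lr_global,
    "predictive_values": _pv_global,
}


def rejection_rate(
    probs: np.ndarray,
    n: int,
    family: Family,
    alpha: float,
    reps: int,
    rng: np.random.Generator,
    max_attempts: int | None = None,
    individual_only: bool = False,
) -> tuple[float, int]:
    """Fraction of ``reps`` valid multinomial replicates on which the family's
    global test rejects at level ``alpha``.

    Infeasible replicates (a statistic that cannot be computed) are replaced
    by new draws and counted; drawing stops with :class:`ResamplingCapError`
    after ``max_attempts`` total draws (default 100 * reps).

    With ``individual_only`` the accuracy family uses the rule-(a) procedure
    (Holm over the two individual Wald tests, rejection = at least one).
    """
    probs = np.asarray(probs, dtype=float)
    if max_attempts is None:
        max_attempts = 100 * reps
    crit = chi2.isf(alpha, 2)
    collected = 0
    rejected = 0
    resampled = 0
    attempts = 0
    while collected < reps:
        batch = min(max(reps - collected, 1000), max_attempts - attempts)
        if batch <= 0:
            raise ResamplingCapError(
                f"exceeded {max_attempts} draws with only {collected}/{reps} "
                f"feasible replicates (family={family})")
        draws = rng.multinomial(n, probs, size=batch)
        attempts += batch
        if individual_only and family == "accuracy":
            stat, feasible = _accuracy_individual_holm(draws, alpha)
            take = stat[feasible][: reps - collected]
            rejected += int(take.sum())
        else:
            stat, feasible = _GLOBAL_STATS[family](draws)
            take = stat[feasible][: reps - collected]
            rejected += int((take >= crit).sum())
        resampled += int((~feasible).sum())
        collected += len(take)
    return rejected / reps, resampled


def _estimates_differ(counts: PairedCounts, family: Family) -> bool:
    if family == "accuracy":
        return counts.s10 != counts.s01 or counts.r10 != counts.r01
    if family == "likelihood_ratios":
        # PLR1 = PLR2 iff s1. * r.1 == s.1 * r1. ; analogous for the NLRs
        return (counts.s1_dot * counts.r_dot1 != counts.s_dot1 * counts.r1_dot
                or counts.s0_dot * counts.r_dot0 != counts.s_dot0 * counts.r0_dot)
    return (counts.s1_dot * counts.n_dot1 != counts.s_dot1 * counts.n1_dot
            or counts.r0_dot * counts.n_dot0 != counts.r_dot0 * counts.n0_dot)


def estimate_power(
    counts: PairedCounts,
    family: Family,
    config: AnalysisConfig,
    observed_significant: bool | None = None,
    rng: np.random.Generator | None = None,
) -> PowerEstimate:
    """Retrospective power (or type-II-error probability) of a family's
    global test, under the alternative equal to the observed table.

    ``observed_significant`` selects the reporting mode (power when the
    observed global test rejected, type-II error otherwise); when ``None``
    it is determined by running the global test on ``counts``.
    """
    if not _estimates_differ(counts, family):
        raise NonIdentifiablePowerError(
            f"the observed {family} estimates of the two tests are identical; "
            "there is no observed difference to target")
    cells = np.asarray(counts.cells(), dtype=float)
    probs = cells / cells.sum()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    individual_only = (family == "accuracy"
                       and counts.prevalence <= 0.10 and counts.n <= 100)
    if observed_significant is None:
        obs = np.asarray([counts.cells()])
        if individual_only:
            stat, feasible = _accuracy_individual_holm(obs, config.alpha)
            observed_significant = bool(feasible[0] and stat[0] > 0)
        else:
            stat, feasible = _GLOBAL_STATS[family](obs)
            observed_significant = bool(
                feasible[0] and stat[0] >= chi2.isf(config.alpha, 2))

    rate, resampled = rejection_rate(
        probs, counts.n, family, config.alpha, config.reps, rng,
        max_attempts=config.max_attempt_factor * config.reps,
        individual_only=individual_only,
    )
    mode = "power" if observed_significant else "type_II_error"
    value = rate if observed_significant else 1.0 - rate
    mc_se = math.sqrt(value * (1.0 - value) / config.reps)
    test_used = ("Holm over individual Wald tests" if individual_only
                 else "global 2-df Wald test")
    return PowerEstimate(mode=mode, value=value, mc_se=mc_se,
                         reps_used=config.reps, resampled=resampled,
                         test_used=test_used)
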