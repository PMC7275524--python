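import math

import numpy as np
import pytest

from compbdt import (
    AnalysisConfig,
    PairedCounts,
    bonett_laplace_diff_interval,
    compare_accuracies,
    compare_lrs,
    compare_pvs,
    holm_adjust,
    kosinski_wgs,
    lr_contrast,
    lrt_accuracy_tests,
    mcnemar_cc,
    pv_diff_interval,
    pv_global_test,
    wald_accuracy_tests,
)
from compbdt.exceptions import (
    DegenerateStatisticError,
    InfeasibleLRTError,
    InfeasibleMcNemarError,
)
from conftest import random_tables


def test_wald_accuracy_weiner(weiner):
    chi_se, chi_sp, chi_global = wald_accuracy_tests(weiner)
    # frozen from direct arithmetic: 608 * 52^2 / (4*29*81 + 498*110)
    assert chi_se.statistic == pytest.approx(1644032 / 64176, rel=1e-12)
    assert chi_sp.statistic == pytest.approx(0.044, abs=5e-4)
    assert chi_global.statistic == pytest.approx(25.662, abs=5e-4)
    assert chi_global.statistic == pytest.approx(
        chi_se.statistic + chi_sp.statistic, rel=1e-12)


def test_wald_accuracy_symmetric_table_is_null():
    c = PairedCounts(40, 7, 7, 30, 10, 5, 5, 40)
    chi_se, chi_sp, chi_global = wald_accuracy_tests(c)
    assert chi_se.statistic == chi_sp.statistic == chi_global.statistic == 0.0
    assert chi_global.p_value == 1.0


def test_wald_accuracy_degenerate():
    with pytest.raises(DegenerateStatisticError):
        wald_accuracy_tests(PairedCounts(10, 0, 0, 10, 5, 3, 4, 8))


def test_lrt_accuracy_weiner(weiner):
    # direct evaluation of the deviance: 2[29 ln(58/110) + 81 ln(162/110)]
    expected_se = 2 * (29 * math.log(58 / 110) + 81 * math.log(162 / 110))
    d_se, d_sp, d_global = lrt_accuracy_tests(weiner)
    assert d_se.statistic == pytest.approx(expected_se, rel=1e-12)
    assert d_se.statistic == pytest.approx(25.591, abs=5e-4)
    assert d_global.statistic == pytest.approx(
        d_se.statistic + d_sp.statistic, rel=1e-12)


def test_lrt_balanced_discordance_is_null():
    d_se, _, _ = lrt_accuracy_tests(PairedCounts(10, 6, 6, 10, 5, 3, 4, 8))
    assert d_se.statistic == pytest.approx(0.0, abs=1e-12)


def test_lrt_requires_positive_discordant_cells():
    with pytest.raises(InfeasibleLRTError):
        lrt_accuracy_tests(PairedCounts(10, 0, 6, 10, 5, 3, 4, 8))


@pytest.mark.parametrize("a, b, expected", [
    (29, 81, 23.645),
    (46, 44, 0.011),
])
def test_mcnemar_cc_weiner_values(a, b, expected):
    assert mcnemar_cc(a, b).statistic == pytest.approx(expected, abs=5e-4)


@pytest.mark.parametrize("k", [0, 1, 5, 40])
def test_mcnemar_cc_difference_one_is_zero(k):
    assert mcnemar_cc(k, k + 1).statistic == 0.0


def test_mcnemar_cc_infeasible():
    with pytest.raises(InfeasibleMcNemarError):
        mcnemar_cc(0, 0)


def test_bonett_laplace_weiner():
    ci = bonett_laplace_diff_interval(81, 29, 608, alpha=0.05)
    assert ci.lower == pytest.approx(0.05192, abs=5e-6)
    assert ci.upper == pytest.approx(0.11857, abs=5e-6)


def test_bonett_laplace_symmetric_centre():
    ci = bonett_laplace_diff_interval(7, 7, 100)
    assert ci.lower == pytest.approx(-ci.upper, abs=1e-12)


def test_bonett_laplace_zero_discordance_closed_form():
    z = AnalysisConfig().z
    ci = bonett_laplace_diff_interval(0, 0, 10)
    assert ci.upper == pytest.approx(z * math.sqrt(2) / 12, rel=1e-12)


@pytest.mark.parametrize("p_values, expected", [
    ((1e-6, 0.991), (True, False)),
    ((0.03, 0.04), (False, False)),   # step-down stops at 0.03 > 0.025
    ((0.01, 0.04), (True, True)),
    ((0.991, 1e-6), (False, True)),   # order-free
])
def test_holm_decisions(p_values, expected):
    assert holm_adjust(p_values, alpha=0.05).reject == expected


def test_holm_adjusted_p_values():
    holm = holm_adjust((0.01, 0.04))
    assert holm.adjusted_p == (0.02, 0.04)
    holm = holm_adjust((0.03, 0.035))
    assert holm.adjusted_p == (0.06, 0.06)  # monotone step-down cap


def test_lr_contrast_weiner(weiner):
    contrast = lr_contrast(weiner)
    z_plr = contrast.omega[0] / math.sqrt(contrast.sigma[0, 0])
    z_nlr = contrast.omega[1] / math.sqrt(contrast.sigma[1, 1])
    assert abs(z_plr) == pytest.approx(0.898, abs=5e-4)
    assert z_nlr == pytest.approx(4.663, abs=5e-4)
    # sigma is a symmetric PSD covariance
    assert contrast.sigma[0, 1] == contrast.sigma[1, 0]
    assert np.all(np.linalg.eigvalsh(contrast.sigma) > 0)


def test_lr_contrast_identical_tests_is_null():
    contrast = lr_contrast(PairedCounts(12, 0, 0, 12, 7, 0, 0, 9))
    assert np.allclose(contrast.omega, 0.0)


def test_compare_accuracies_weiner(weiner, config):
    outcome = compare_accuracies(weiner, config)
    assert outcome.rule == "global_then_mcnemar_cc"  # 100 < n=871 < 1000
    assert outcome.global_test.statistic == pytest.approx(25.662, abs=5e-4)
    se, sp = outcome.individual
    assert se.reject and not sp.reject
    assert se.larger_test == 2
    assert se.interval.lower == pytest.approx(0.05192, abs=5e-6)
    assert se.interval.upper == pytest.approx(0.11857, abs=5e-6)
    assert sp.interval is None


def test_compare_accuracies_rule_a_no_global():
    # prevalence 5/80 ~ 6% <= 10% and n = 80 <= 100: individual tests only
    c = PairedCounts(2, 1, 2, 0, 20, 10, 30, 15)
    outcome = compare_accuracies(c, AnalysisConfig())
    assert outcome.rule == "individual_only"
    assert outcome.global_test is None
    assert len(outcome.individual) == 2
    assert all(i.test.method == "Wald" for i in outcome.individual)


def test_compare_accuracies_wald_branch_large_n():
    c = PairedCounts(*[2 * x for x in (473, 29, 81, 25, 22, 46, 44, 151)])
    outcome = compare_accuracies(c, AnalysisConfig())  # n = 1742 >= 1000
    assert outcome.rule == "global_then_wald"
    assert all(i.test.method == "Wald" for i in outcome.individual)


def test_compare_accuracies_null_table_retains_homogeneity():
    c = PairedCounts(200, 30, 30, 150, 60, 20, 20, 200)
    outcome = compare_accuracies(c, AnalysisConfig())
    assert outcome.global_test.p_value == 1.0
    assert outcome.individual == ()


def test_compare_lrs_weiner(weiner, config):
    outcome = compare_lrs(weiner, config)
    assert outcome.global_test.statistic == pytest.approx(23.438, abs=5e-4)
    plr, nlr = outcome.individual
    assert not plr.reject and nlr.reject
    assert nlr.larger_test == 1
    assert nlr.interval.lower == pytest.approx(1.412, abs=5e-4)
    assert nlr.interval.upper == pytest.approx(2.554, abs=5e-4)
    assert plr.interval is None


def test_kosinski_wgs_weiner(weiner):
    ppv, _ = kosinski_wgs(weiner, "PPV")
    npv, comps = kosinski_wgs(weiner, "NPV")
    assert ppv.statistic == pytest.approx(0.807, abs=5e-4)
    assert npv.statistic == pytest.approx(22.502, abs=5e-4)
    assert 0.0 <= comps.pooled <= 1.0 and comps.c_term >= 0.0


def test_kosinski_wgs_identical_tests_is_null():
    test, _ = kosinski_wgs(PairedCounts(12, 0, 0, 12, 7, 0, 0, 9), "PPV")
    assert test.statistic == 0.0


def test_pv_global_weiner(weiner):
    test, contrast = pv_global_test(weiner)
    assert test.statistic == pytest.approx(25.944, abs=5e-4)
    # diagonal of the delta-method covariance matches the printed PV SEs
    assert np.sqrt(contrast.sigma[2, 2]) == pytest.approx(0.028, abs=5e-4)
    assert np.all(np.linalg.eigvalsh(contrast.sigma) > -1e-15)


def test_pv_diff_interval_weiner(weiner):
    ci = pv_diff_interval(weiner, "NPV", alpha=0.05)
    assert ci.larger_test == 2
    assert ci.lower == pytest.approx(0.08041, abs=5e-6)
    assert ci.upper == pytest.approx(0.19363, abs=5e-6)


def test_pv_diff_interval_width_is_wgs_inverse(weiner):
    """The interval width equals 2 z sqrt(variance term of the WGS statistic)."""
    z = AnalysisConfig().z
    _, comps = kosinski_wgs(weiner, "NPV")
    ci = pv_diff_interval(weiner, "NPV")
    assert ci.upper - ci.lower == pytest.approx(
        2 * z * math.sqrt(comps.variance), rel=1e-12)


def test_compare_pvs_weiner(weiner, config):
    outcome = compare_pvs(weiner, config)
    assert outcome.global_test.statistic == pytest.approx(25.944, abs=5e-4)
    ppv, npv = outcome.individual
    assert not ppv.reject and npv.reject
    assert npv.larger_test == 2
    assert npv.interval is not None and ppv.interval is None


def test_relabelling_symmetry_fuzzed():
    """Swapping the roles of Test 1 and Test 2 leaves every global statistic
    unchanged and flips the sign of the log-ratio contrasts."""
    rng = np.random.default_rng(42)
    checked = 0
    for c in random_tables(rng, 300, low=0, high=40):
        swapped = c.relabelled()
        try:
            g1 = wald_accuracy_tests(c)[2].statistic
            g2 = wald_accuracy_tests(swapped)[2].statistic
        except DegenerateStatisticError:
            continue
        assert g1 == pytest.approx(g2, rel=1e-9)
        try:
            c1, c2 = lr_contrast(c), lr_contrast(swapped)
        except Exception:
            continue
        assert np.allclose(c1.omega, -c2.omega)
        assert np.allclose(c1.sigma, c2.sigma)
        checked += 1
    assert checked > 100
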