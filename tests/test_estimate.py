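import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from compbdt import (
    PairedCounts,
    estimate_likelihood_ratios,
    estimate_prevalence,
    estimate_proportion_params,
    score_ratio_interval,
    yu_interval,
)
from compbdt.exceptions import InvalidTrialsError


# modified-Wilson interval endpoints frozen from the published worked example
@pytest.mark.parametrize("k, m, lower, upper", [
    (608, 871, 0.66681, 0.72768),   # prevalence
    (502, 608, 0.79363, 0.85389),   # Se1
    (554, 608, 0.88610, 0.93148),   # Se2
    (195, 263, 0.68557, 0.79087),   # Sp1
    (197, 263, 0.69358, 0.79787),   # Sp2
    (502, 570, 0.85170, 0.90498),   # PPV1
    (554, 620, 0.86698, 0.91562),   # PPV2
    (195, 301, 0.59246, 0.69976),   # NPV1
    (197, 251, 0.73024, 0.83151),   # NPV2
])
def test_yu_interval_reference_values(k, m, lower, upper):
    ci = yu_interval(k, m, alpha=0.05)
    assert ci.lower == pytest.approx(lower, abs=5e-6)
    assert ci.upper == pytest.approx(upper, abs=5e-6)


@pytest.mark.parametrize("m", [10, 50, 400])
def test_yu_interval_symmetric_at_half(m):
    ci = yu_interval(m // 2, m)
    assert ci.lower + ci.upper == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("k, m", [(5, 0), (-1, 10), (11, 10)])
def test_yu_interval_rejects_bad_trials(k, m):
    with pytest.raises(InvalidTrialsError):
        yu_interval(k, m)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.integers(1, 500), st.data())
def test_yu_interval_contains_point_estimate(m, data):
    k = data.draw(st.integers(0, m))
    ci = yu_interval(k, m)
    assert ci.lower <= k / m <= ci.upper
    assert 0.0 <= ci.lower <= ci.upper <= 1.0


def test_yu_interval_width_shrinks_with_m():
    widths = [np.ptp([yu_interval(int(0.3 * m), m).lower,
                      yu_interval(int(0.3 * m), m).upper])
              for m in (10, 100, 1000, 10000)]
    assert widths == sorted(widths, reverse=True)


def test_proportion_estimates_weiner(weiner):
    params = estimate_proportion_params(weiner)
    expected = {"Se1": 0.82566, "Se2": 0.91118, "Sp1": 0.74144, "Sp2": 0.74905,
                "PPV1": 0.88070, "PPV2": 0.89355, "NPV1": 0.64784,
                "NPV2": 0.78486}
    for name, value in expected.items():
        assert params[name].estimate.value == pytest.approx(value, abs=5e-6)
    ses = {"Se1": 0.015, "Se2": 0.012, "Sp1": 0.027, "Sp2": 0.027,
           "PPV1": 0.014, "PPV2": 0.012, "NPV1": 0.028, "NPV2": 0.026}
    for name, se in ses.items():
        assert params[name].estimate.se == pytest.approx(se, abs=5e-4)


def test_prevalence_weiner(weiner):
    prev = estimate_prevalence(weiner)
    assert prev.estimate.value == pytest.approx(0.69805, abs=5e-6)
    assert prev.estimate.se == pytest.approx(0.016, abs=5e-4)


def test_likelihood_ratio_estimates_weiner(weiner):
    lrs = estimate_likelihood_ratios(weiner)
    expected = {"PLR1": (3.193, 0.339), "PLR2": (3.631, 0.390),
                "NLR1": (0.235, 0.022), "NLR2": (0.119, 0.016)}
    for name, (value, se) in expected.items():
        assert lrs[name].estimate.value == pytest.approx(value, abs=5e-4)
        assert lrs[name].estimate.se == pytest.approx(se, abs=5e-4)


def test_identical_tests_have_identical_estimates():
    c = PairedCounts(12, 0, 0, 12, 7, 0, 0, 9)
    params = estimate_proportion_params(c)
    assert params["Se1"].estimate.value == params["Se2"].estimate.value
    assert params["Sp1"].estimate.value == params["Sp2"].estimate.value


def test_lr_boundary_zero_estimate():
    # Test 1 never negative among diseased: NLR1 estimated at the boundary 0
    c = PairedCounts(10, 5, 0, 0, 2, 3, 4, 6)
    lrs = estimate_likelihood_ratios(c)
    assert lrs["NLR1"].estimate.value == 0.0
    assert lrs["NLR1"].estimate.se is None
    assert lrs["NLR1"].error is not None
    assert lrs["NLR1"].interval is not None  # +0.5 adjustment still yields one


@settings(max_examples=150, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 100), min_size=8, max_size=8).filter(
    lambda c: 0 < c[0] + c[1] < sum(c[:4]) and 0 < c[4] + c[5] < sum(c[4:])
    and 0 < c[0] + c[2] < sum(c[:4]) and 0 < c[4] + c[6] < sum(c[4:])))
def test_lr_estimator_identities(cells):
    """Count-ratio and Se/Sp forms of the LR estimators agree exactly."""
    c = PairedCounts(*cells)
    lrs = estimate_likelihood_ratios(c)
    for test in (1, 2):
        se, sp = c.sensitivity(test), c.specificity(test)
        assert lrs[f"PLR{test}"].estimate.value == pytest.approx(
            se / (1 - sp), rel=1e-12)
        assert lrs[f"NLR{test}"].estimate.value == pytest.approx(
            (1 - se) / sp, rel=1e-12)


# score-method ratio intervals frozen from the published worked example
@pytest.mark.parametrize("which, lower, upper", [
    ("PLR1", 2.610, 3.952),
    ("PLR2", 2.962, 4.505),
    ("NLR1", 0.195, 0.283),
    ("NLR2", 0.090, 0.153),
])
def test_score_ratio_interval_reference_values(weiner, which, lower, upper):
    ci = score_ratio_interval(weiner, which, alpha=0.05)
    assert ci.lower == pytest.approx(lower, abs=5e-4)
    assert ci.upper == pytest.approx(upper, abs=5e-4)


def test_score_ratio_interval_contains_estimate(weiner):
    lrs = estimate_likelihood_ratios(weiner)
    for which in ("PLR1", "PLR2", "NLR1", "NLR2"):
        ci = score_ratio_interval(weiner, which)
        assert ci.lower <= lrs[which].estimate.value <= ci.upper
        assert ci.lower >= 0.0


def test_score_ratio_interval_narrows_with_sample_size(weiner):
    scaled = PairedCounts(*[10 * x for x in weiner.cells()])
    for which in ("PLR1", "PLR2", "NLR1", "NLR2"):
        small = score_ratio_interval(weiner, which)
        big = score_ratio_interval(scaled, which)
        assert big.upper - big.lower < small.upper - small.lower
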