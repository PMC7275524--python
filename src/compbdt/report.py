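"""Full-analysis driver and plain-text report rendering.

:func:`run_compbdt` validates the table, estimates every parameter, runs the
three comparison families, estimates the retrospective power (or type-II
error probability) of each, and assembles a :class:`FullReport` whose three
family blocks are written by :func:`write_reports` to the files

* ``Results_Comparison_Accuracies.txt``
* ``Results_Comparison_LRs.txt``
* ``Results_Comparison_PVs.txt``
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .compare import (
    ComparisonOutcome,
    IndividualComparison,
    compare_accuracies,
    compare_lrs,
    compare_pvs,
)
from .counts import AnalysisConfig, PairedCounts, StudyDesign, check_youden, validate_counts
from .estimate import (
    ConfidenceInterval,
    ParameterSummary,
    estimate_likelihood_ratios,
    estimate_prevalence,
    estimate_proportion_params,
)
from .exceptions import NonIdentifiablePowerError, ResamplingCapError
from .power import PowerEstimate, estimate_power

logger = logging.getLogger("compbdt")

_PARAM_NAMES = {
    "Se": "sensitivity",
    "Sp": "specificity",
    "PLR": "positive LR",
    "NLR": "negative LR",
    "PPV": "positive PV",
    "NPV": "negative PV",
}

REPORT_FILES = {
    "accuracy": "Results_Comparison_Accuracies.txt",
    "likelihood_ratios": "Results_Comparison_LRs.txt",
    "predictive_values": "Results_Comparison_PVs.txt",
}


@dataclass(frozen=True)
class FullReport:
    counts: PairedCounts
    config: AnalysisConfig
    youden: tuple[float, float]
    prevalence: ParameterSummary | None
    proportions: dict[str, ParameterSummary] | None
    likelihood_ratios: dict[str, ParameterSummary]
    accuracy: ComparisonOutcome
    lr: ComparisonOutcome
    pv: ComparisonOutcome | None

    # ------------------------------------------------------------------ fmt
    def _fmt(self, x: float) -> str:
        return f"{x:.{self.config.decip}f}"

    def _pct(self, x: float) -> str:
        return f"{100.0 * x:.{self.config.decip}f}%"

    def _pval(self, p: float) -> str:
        floor = 10.0 ** (-self.config.decip)
        if p < floor / 2.0:
            return f"<{self._fmt(floor)}"
        return self._fmt(p)

    def _interval(self, ci: ConfidenceInterval, percent: bool) -> str:
        f = self._pct if percent else self._fmt
        return f"({f(ci.lower)}; {f(ci.upper)})"

    def _level(self) -> str:
        return f"{100.0 * (1.0 - self.config.alpha):g}%"

    def _alpha_pct(self) -> str:
        return f"{100.0 * self.config.alpha:g}%"

    # ------------------------------------------------------------ renderers
    def _param_lines(self, summary: ParameterSummary, percent: bool) -> list[str]:
        key = summary.label[:-1]
        test = summary.label[-1]
        name = _PARAM_NAMES[key]
        if summary.estimate is None:
            return [f"The {name} of Test {test} is not estimable: {summary.error}."]
        f = self._pct if percent else self._fmt
        lines = []
        se_txt = (self._fmt(summary.estimate.se)
                  if summary.estimate.se is not None else "undefined")
        lines.append(f"Estimated {name} of Test {test} is "
                     f"{f(summary.estimate.value)} and its standard error is "
                     f"{se_txt}.")
        if summary.interval is not None:
            lines.append(f"{self._level()} confidence interval for the {name} "
                         f"of Test {test} is "
                         f"{self._interval(summary.interval, percent)}.")
        return lines

    def _individual_lines(self, ind: IndividualComparison, percent: bool,
                          statistic_label: str) -> list[str]:
        stat = abs(ind.test.statistic)
        return [f"{statistic_label} for H0: {ind.hypothesis} is "
                f"{self._fmt(stat)} and the two-sided p-value is "
                f"{self._pval(ind.test.p_value)}."]

    def _holm_sentence(self, outcome: ComparisonOutcome) -> str:
        parts = []
        for ind in outcome.individual:
            verb = "we reject" if ind.reject else "we do not reject"
            parts.append(f"{verb} the hypothesis H0: {ind.hypothesis}")
        return (f"Applying the Holm method (to an alpha error of "
                f"{self._alpha_pct()}), " + " and ".join(parts) + ".")

    def _contrast_lines(self, ind: IndividualComparison, percent: bool) -> list[str]:
        if not ind.reject or ind.interval is None:
            return []
        key = ind.hypothesis.split("1")[0]
        name = _PARAM_NAMES[key]
        larger = ind.larger_test
        smaller = 2 if larger == 1 else 1
        lines = [f"{name[0].upper()}{name[1:]} of Test {larger} is "
                 f"significantly greater than {name} of Test {smaller}."]
        if ind.interval.scale == "ratio":
            lines.append(
                f"{self._level()} confidence interval for the ratio "
                f"{key}{larger} / {key}{smaller} is "
                f"{self._interval(ind.interval, False)}.")
        else:
            lines.append(
                f"{self._level()} confidence interval for the difference "
                f"{key}{larger} - {key}{smaller} is "
                f"{self._interval(ind.interval, percent)}.")
        return lines

    def _power_lines(self, power: PowerEstimate | None,
                     notes: tuple[str, ...]) -> list[str]:
        lines = []
        if power is not None:
            if power.mode == "power":
                lines.append(f"Estimated power (to an alpha error of "
                             f"{self._alpha_pct()}) is {self._pct(power.value)}.")
            else:
                lines.append(
                    f"Estimated probability of a type II error (to an alpha "
                    f"error of {self._alpha_pct()}) is {self._pct(power.value)}.")
        lines.extend(f"Note: {note}" for note in notes)
        return lines

    def _family_block(self, title: str, outcome: ComparisonOutcome,
                      summaries: list[ParameterSummary], percent: bool,
                      global_name: str, statistic_label: str,
                      hypothesis: str) -> str:
        lines: list[str] = [title, ""]
        for summary in summaries:
            lines.extend(self._param_lines(summary, percent))
        lines.append("")
        if outcome.global_test is None and outcome.rule == "individual_only":
            lines.append("Prevalence and sample size are small; the individual "
                         "hypothesis tests are solved directly with the Holm "
                         "method (no global test).")
        elif outcome.global_test is None:
            lines.extend(f"Note: {note}" for note in outcome.notes)
            return "\n".join(lines) + "\n"
        else:
            g = outcome.global_test
            lines.append(f"{global_name} test statistic for the global "
                         f"hypothesis test H0: ({hypothesis}) is "
                         f"{self._fmt(g.statistic)}. Global p-value is "
                         f"{self._pval(g.p_value)}.")
            if outcome.secondary_global is not None:
                s = outcome.secondary_global
                lines.append(f"Likelihood-ratio (deviance) global test "
                             f"statistic is {self._fmt(s.statistic)} "
                             f"(p-value {self._pval(s.p_value)}).")
            verb = ("we reject" if g.p_value <= self.config.alpha
                    else "we do not reject")
            lines.append(f"Applying the global hypothesis test (to an alpha "
                         f"error of {self._alpha_pct()}), {verb} the "
                         f"hypothesis H0: ({hypothesis}).")
        lines.extend(self._power_lines(outcome.power, outcome.notes))
        if outcome.individual and (outcome.global_test is None
                                   or outcome.global_test.p_value <= self.config.alpha):
            lines.append("")
            lines.append("Investigation of the causes of significance:")
            for ind in outcome.individual:
                lines.extend(self._individual_lines(ind, percent, statistic_label))
            lines.append(self._holm_sentence(outcome))
            for ind in outcome.individual:
                lines.extend(self._contrast_lines(ind, percent))
        return "\n".join(lines) + "\n"

    # ------------------------------------------------------------- sections
    def prevalence_block(self) -> str:
        if self.prevalence is None:
            return ("Prevalence of the disease\n\n"
                    "Sampling is case-control: the group sizes were fixed by "
                    "design, so the disease prevalence is not estimable from "
                    "this table.\n")
        est = self.prevalence.estimate
        ci = self.prevalence.interval
        return ("Prevalence of the disease\n\n"
                f"Estimated prevalence of the disease is {self._pct(est.value)} "
                f"and its standard error is {self._fmt(est.se)}.\n"
                f"{self._level()} confidence interval for the prevalence of "
                f"the disease is {self._interval(ci, True)}.\n")

    def accuracy_block(self) -> str:
        props = self.proportions or estimate_proportion_params(
            self.counts, self.config.alpha)
        summaries = [props[k] for k in ("Se1", "Se2", "Sp1", "Sp2")]
        label = {"global_then_mcnemar_cc": "McNemar test statistic (with cc)",
                 "global_then_wald": "Wald test statistic",
                 "individual_only": "Wald test statistic"}.get(
                     self.accuracy.rule, "Test statistic")
        return self._family_block(
            "Comparison of the accuracies (sensitivities and specificities)",
            self.accuracy, summaries, percent=True, global_name="Wald",
            statistic_label=label, hypothesis="Se1 = Se2 and Sp1 = Sp2")

    def lr_block(self) -> str:
        summaries = [self.likelihood_ratios[k]
                     for k in ("PLR1", "PLR2", "NLR1", "NLR2")]
        return self._family_block(
            "Comparison of the likelihood ratios",
            self.lr, summaries, percent=False, global_name="Wald",
            statistic_label="Test statistic",
            hypothesis="PLR1 = PLR2 and NLR1 = NLR2")

    def pv_block(self) -> str:
        if self.pv is None:
            return ("Comparison of the predictive values\n\n"
                    "Sampling is case-control: the predictive values are not "
                    "estimable from this table (they depend on the disease "
                    "prevalence), so their estimation and comparison are "
                    "suppressed.\n")
        props = self.proportions
        summaries = [props[k] for k in ("PPV1", "PPV2", "NPV1", "NPV2")]
        return self._family_block(
            "Comparison of the predictive values",
            self.pv, summaries, percent=True, global_name="Wald",
            statistic_label="Weighted generalized score statistic",
            hypothesis="PPV1 = PPV2 and NPV1 = NPV2")

    def render(self) -> str:
        return "\n".join([self.prevalence_block(), self.accuracy_block(),
                          self.lr_block(), self.pv_block()])


def _attach_power(outcome: ComparisonOutcome, counts: PairedCounts,
                  config: AnalysisConfig,
                  rng: np.random.Generator) -> ComparisonOutcome:
    if outcome.global_test is None and not outcome.individual:
        return outcome
    observed_significant = outcome.is_global_significant(config.alpha)
    try:
        power = estimate_power(counts, outcome.family, config,
                               observed_significant=observed_significant,
                               rng=rng)
    except NonIdentifiablePowerError:
        return dataclasses.replace(outcome, notes=outcome.notes + (
            "power not estimated: the observed estimates of the two tests "
            "are identical",))
    except ResamplingCapError as exc:
        return dataclasses.replace(outcome, notes=outcome.notes + (
            f"power not estimated: {exc}",))
    return dataclasses.replace(outcome, power=power)


def run_compbdt(*cells: int, alpha: float = 0.05,
                config: AnalysisConfig | None = None) -> FullReport:
    """Validate, estimate, compare and power-analyse a paired-design table.

    Accepts the eight cells in the positional order
    (s11, s10, s01, s00, r11, r10, r01, r00); deterministic given
    ``config.seed``.
    """
    if config is None:
        config = AnalysisConfig(alpha=alpha)
    counts = validate_counts(*cells)
    youden = check_youden(counts)
    logger.info("validated table: s=%d r=%d n=%d youden=(%.3f, %.3f)",
                counts.s, counts.r, counts.n, youden[0], youden[1])

    case_control = config.design is StudyDesign.CASE_CONTROL
    prevalence = None if case_control else estimate_prevalence(counts, config.alpha)
    proportions = estimate_proportion_params(counts, config.alpha)
    lrs = estimate_likelihood_ratios(counts, config.alpha)

    rng = np.random.default_rng(config.seed)
    accuracy = compare_accuracies(counts, config)
    accuracy = _attach_power(accuracy, counts, config, rng)
    logger.info("accuracy family: rule=%s", accuracy.rule)
    lr = compare_lrs(counts, config)
    lr = _attach_power(lr, counts, config, rng)
    logger.info("likelihood-ratio family: rule=%s", lr.rule)
    pv = None
    if not case_control:
        pv = compare_pvs(counts, config)
        pv = _attach_power(pv, counts, config, rng)
        logger.info("predictive-value family: rule=%s", pv.rule)
    else:
        logger.info("predictive-value family suppressed (case-control design)")

    return FullReport(counts=counts, config=config, youden=youden,
                      prevalence=prevalence, proportions=proportions,
                      likelihood_ratios=lrs, accuracy=accuracy, lr=lr, pv=pv)


def write_reports(report: FullReport, out_dir: str | Path) -> list[Path]:
    """Write the three family report files; creates ``out_dir`` on demand."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        paths = []
        blocks = {
            "accuracy": report.prevalence_block() + "\n" + report.accuracy_block(),
            "likelihood_ratios": report.lr_block(),
            "predictive_values": report.pv_block(),
        }
        for family, name in REPORT_FILES.items():
            path = out / name
            path.write_text(blocks[family], encoding="utf-8")
            paths.append(path)
    except OSError as exc:
        raise OSError(f"could not write reports under {out}: {exc}") from exc
    return paths
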