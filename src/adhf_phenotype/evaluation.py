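"""Diagnostic-accuracy evaluation against a reference standard.

The accuracy framework is the classical 2x2 table with the reference
standard as column truth:

====================  ==================  ==================
\\                     reference positive  reference negative
classifier positive   true positive       false positive
classifier negative   false negative      true negative
====================  ==================  ==================

Sensitivity = TP/(TP+FN) and specificity = TN/(TN+FP) are the only accuracy
metrics reported by default; 95% confidence intervals are exact
(Clopper-Pearson, from beta-distribution quantiles). Predictive values are
deliberately behind an explicit flag because they depend on the prevalence
in the evaluated cohort and do not transport.

The discordance report lists every admission where classifier and reference
disagree, with the classifier's evidence attached — this is what drives the
iterative derivation loop: review mismatches, edit the term lists, re-run.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping
from dataclasses import dataclass
from typing import Any

from scipy.stats import beta as _beta

__all__ = [
    "TwoByTwo",
    "AccuracyEstimate",
    "ComparisonRow",
    "Discordance",
    "confusion_matrix",
    "sensitivity",
    "specificity",
    "exact_binomial_ci",
    "proportion_estimate",
    "compare_strategies",
    "discordance_report",
    "render_comparison_markdown",
    "comparison_to_frame",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TwoByTwo:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("2x2 cells must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class AccuracyEstimate:
    """A proportion with its exact confidence interval."""

    metric: str
    point: float
    ci_low: float
    ci_high: float
    n_numerator: int
    n_denominator: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.point <= self.ci_high <= 1.0):
            raise ValueError(
                f"{self.metric}: interval ({self.ci_low}, {self.ci_high}) must "
                f"bracket the point estimate {self.point} within [0, 1]"
            )

    @property
    def percent(self) -> float:
        """Point estimate on the percentage scale, one decimal."""
        return round(100 * self.point, 1)

    def format(self) -> str:
        return (
            f"{100 * self.point:.1f}% "
            f"(95% CI {100 * self.ci_low:.1f}-{100 * self.ci_high:.1f})"
        )


@dataclass(frozen=True)
class ComparisonRow:
    cohort_label: str
    strategy: str
    reference: str
    sensitivity: AccuracyEstimate
    specificity: AccuracyEstimate
    table: TwoByTwo

    def __post_init__(self) -> None:
        if self.strategy == self.reference:
            raise ValueError("a strategy cannot be compared against itself")


@dataclass(frozen=True)
class Discordance:
    admission_id: str
    predicted: bool
    reference_label: bool
    evidence: Any = None

    def __post_init__(self) -> None:
        if self.predicted == self.reference_label:
            raise ValueError("a discordance requires predicted != reference_label")


def confusion_matrix(
    predictions: Mapping[str, bool], reference: Mapping[str, bool]
) -> TwoByTwo:
    """Count the 2x2 cells over the reference-labelled admissions.

    Every reference admission must carry a prediction; predictions without a
    reference label are ignored with a logged count (they are simply outside
    the evaluated cohort).
    """
    missing = sorted(set(reference) - set(predictions))
    if missing:
        raise ValueError(
            f"{len(missing)} reference admissions lack predictions: {missing[:10]}"
        )
    extra = len(set(predictions) - set(reference))
    if extra:
        logger.info("%d predictions outside the reference cohort ignored", extra)
    tp = fp = fn = tn = 0
    for adm_id, truth in reference.items():
        pred = predictions[adm_id]
        if truth and pred:
            tp += 1
        elif truth and not pred:
            fn += 1
        elif not truth and pred:
            fp += 1
        else:
            tn += 1
    return TwoByTwo(tp=tp, fp=fp, fn=fn, tn=tn)


def exact_binomial_ci(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Clopper-Pearson exact interval for a binomial proportion.

    Lower bound is 0 when ``k == 0`` and upper bound 1 when ``k == n``;
    otherwise the bounds are the usual beta quantiles
    ``Beta(alpha/2; k, n-k+1)`` and ``Beta(1-alpha/2; k+1, n-k)``.
    """
    if not 0 <= k <= n or n < 1:
        raise ValueError(f"need 0 <= k <= n and n >= 1, got k={k}, n={n}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    low = 0.0 if k == 0 else float(_beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(_beta.isf(alpha / 2, k + 1, n - k))
    return low, high


def proportion_estimate(
    metric: str, k: int, n: int, alpha: float = 0.05
) -> AccuracyEstimate:
    if n <= 0:
        raise ValueError(f"{metric} is undefined: denominator is zero")
    low, high = exact_binomial_ci(k, n, alpha)
    return AccuracyEstimate(
        metric=metric,
        point=k / n,
        ci_low=low,
        ci_high=high,
        n_numerator=k,
        n_denominator=n,
        alpha=alpha,
    )


def sensitivity(tt: TwoByTwo, alpha: float = 0.05) -> AccuracyEstimate:
    """TP/(TP+FN) with exact CI; undefined when the reference has no positives."""
    if tt.tp + tt.fn == 0:
        raise ValueError("sensitivity undefined: no positives in the reference")
    return proportion_estimate("sensitivity", tt.tp, tt.tp + tt.fn, alpha)


def specificity(tt: TwoByTwo, alpha: float = 0.05) -> AccuracyEstimate:
    """TN/(TN+FP) with exact CI; undefined when the reference has no negatives."""
    if tt.tn + tt.fp == 0:
        raise ValueError("specificity undefined: no negatives in the reference")
    return proportion_estimate("specificity", tt.tn, tt.tn + tt.fp, alpha)


def predictive_values(
    tt: TwoByTwo, alpha: float = 0.05
) -> tuple[AccuracyEstimate, AccuracyEstimate]:
    """PPV and NPV. Not part of default reports: they depend on the cohort's
    prevalence, so request them explicitly and interpret them locally."""
    ppv = proportion_estimate("ppv", tt.tp, tt.tp + tt.fp, alpha)
    npv = proportion_estimate("npv", tt.tn, tt.tn + tt.fn, alpha)
    return ppv, npv


def compare_strategies(
    reference: Mapping[str, bool],
    strategies: Mapping[str, Mapping[str, bool]],
    cohort_label: str = "",
    reference_name: str = "reference standard",
    alpha: float = 0.05,
) -> list[ComparisonRow]:
    """One comparison row per strategy against the reference.

    The reference may itself be another strategy's predictions (pass its name
    as ``reference_name``) — that is how code-set strategies are compared to
    the text phenotype directly. A strategy sharing the reference's name is
    rejected.
    """
    if not strategies:
        raise ValueError("at least one strategy is required")
    rows = []
    for name, preds in strategies.items():
        if name == reference_name:
            raise ValueError(f"strategy {name!r} cannot be compared against itself")
        tt = confusion_matrix(preds, reference)
        rows.append(
            ComparisonRow(
                cohort_label=cohort_label,
                strategy=name,
                reference=reference_name,
                sensitivity=sensitivity(tt, alpha),
                specificity=specificity(tt, alpha),
                table=tt,
            )
        )
    return rows


def discordance_report(
    predictions: Mapping[str, bool],
    reference: Mapping[str, bool],
    evidence_store: Mapping[str, Any] | None = None,
) -> list[Discordance]:
    """Every mismatching admission, sorted by id, with evidence attached."""
    confusion_matrix(predictions, reference)  # validate coverage
    out = []
    for adm_id in sorted(reference):
        pred = predictions[adm_id]
        if pred != reference[adm_id]:
            out.append(
                Discordance(
                    admission_id=adm_id,
                    predicted=pred,
                    reference_label=reference[adm_id],
                    evidence=(evidence_store or {}).get(adm_id),
                )
            )
    return out


def comparison_to_frame(rows: list[ComparisonRow]):
    """Comparison rows as a tidy DataFrame (percent scale, one decimal)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "cohort": r.cohort_label,
                "strategy": r.strategy,
                "reference": r.reference,
                "n": r.table.n,
                "tp": r.table.tp,
                "fp": r.table.fp,
                "fn": r.table.fn,
                "tn": r.table.tn,
                "sensitivity_pct": r.sensitivity.percent,
                "sens_ci_low_pct": round(100 * r.sensitivity.ci_low, 1),
                "sens_ci_high_pct": round(100 * r.sensitivity.ci_high, 1),
                "specificity_pct": r.specificity.percent,
                "spec_ci_low_pct": round(100 * r.specificity.ci_low, 1),
                "spec_ci_high_pct": round(100 * r.specificity.ci_high, 1),
            }
            for r in rows
        ]
    )


def render_comparison_markdown(rows: list[ComparisonRow], title: str = "") -> str:
    """Human-readable Markdown rendering of a comparison table."""
    lines = []
    if title:
        lines += [f"## {title}", ""]
    lines += [
        "| Cohort | Strategy | Reference | n | Sensitivity | Specificity |",
        "|---|---|---|---|---|---|",
    ]
    for r in rows:
        lines.append(
            f"| {r.cohort_label} | {r.strategy} | {r.reference} | {r.table.n} "
            f"| {r.sensitivity.format()} | {r.specificity.format()} |"
        )
    return "\n".join(lines) + "\n"
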