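"""Diagnostic-accuracy statistics for the validation step.

Each disease is scored one-vs-rest: TP/FP/TN/FN counts over the cohort,
then prevalence, sensitivity (TP/(TP+FN)), specificity (TN/(TN+FP)),
positive and negative predictive values, accuracy and balanced accuracy
(mean of sensitivity and specificity).  Sensitivity and specificity
carry exact two-sided Clopper-Pearson 95% confidence intervals, the
interval obtained by inverting the exact binomial test; at the
boundaries it has the closed forms lower = (alpha/2)^(1/n) for n/n
successes and upper = 1 - (alpha/2)^(1/n) for 0/n.

Any ratio with a zero denominator is undefined and reported as ``None``
(printed "NA"), e.g. sensitivity of a disease absent from the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy.stats import beta

from .patient_model import DIAGNOSABLE_LABELS, DiseaseLabel, MalignancyFlag


@dataclass
class ConfusionCounts:
    label: str
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class DiagnosticMetrics:
    """Proportions in [0, 1]; None marks an undefined (0/0) quantity."""

    prevalence: float | None
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float | None
    balanced_accuracy: float | None
    sensitivity_ci: tuple[float, float] | None
    specificity_ci: tuple[float, float] | None


def _as_value(label) -> str:
    return label.value if hasattr(label, "value") else str(label)


def confusion_counts(
    truths: Sequence, predictions: Sequence, label
) -> ConfusionCounts:
    """One-vs-rest confusion counts for ``label``."""
    if len(truths) != len(predictions):
        raise ValueError(
            f"length mismatch: {len(truths)} truths vs {len(predictions)} predictions"
        )
    if not truths:
        raise ValueError("empty inputs")
    target = _as_value(label)
    tp = fp = tn = fn = 0
    for truth, pred in zip(truths, predictions):
        truth, pred = _as_value(truth), _as_value(pred)
        if truth == target and pred == target:
            tp += 1
        elif pred == target:
            fp += 1
        elif truth == target:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(target, tp, fp, tn, fn)


def clopper_pearson_ci(
    successes: int, trials: int, confidence: float = 0.95
) -> tuple[float, float] | None:
    """Exact two-sided binomial confidence interval (beta quantile form)."""
    if trials == 0:
        return None
    if not 0 <= successes <= trials:
        raise ValueError(f"successes {successes} outside [0, {trials}]")
    alpha = 1.0 - confidence
    lower = 0.0 if successes == 0 else float(
        beta.ppf(alpha / 2.0, successes, trials - successes + 1)
    )
    upper = 1.0 if successes == trials else float(
        beta.ppf(1.0 - alpha / 2.0, successes + 1, trials - successes)
    )
    return lower, upper


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def diagnostic_metrics(
    counts: ConfusionCounts, confidence: float = 0.95
) -> DiagnosticMetrics:
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    n = counts.total
    sensitivity = _ratio(tp, tp + fn)
    specificity = _ratio(tn, tn + fp)
    balanced = (
        (sensitivity + specificity) / 2.0
        if sensitivity is not None and specificity is not None
        else None
    )
    return DiagnosticMetrics(
        prevalence=_ratio(tp + fn, n),
        sensitivity=sensitivity,
        specificity=specificity,
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
        accuracy=_ratio(tp + tn, n),
        balanced_accuracy=balanced,
        sensitivity_ci=(
            clopper_pearson_ci(tp, tp + fn, confidence) if tp + fn else None
        ),
        specificity_ci=(
            clopper_pearson_ci(tn, tn + fp, confidence) if tn + fp else None
        ),
    )


@dataclass
class ValidationReport:
    rows: list[tuple[str, ConfusionCounts, DiagnosticMetrics]]
    n_patients: int
    n_correct: int  # labels only, malignancy row excluded

    def row(self, label) -> tuple[ConfusionCounts, DiagnosticMetrics]:
        target = _as_value(label)
        for name, counts, metrics in self.rows:
            if name == target:
                return counts, metrics
        raise KeyError(target)

    def to_dataframe(self) -> pd.DataFrame:
        def pct(x):
            return None if x is None else round(100.0 * x, 1)

        out = []
        for name, counts, m in self.rows:
            out.append(
                {
                    "group": name,
                    "tp": counts.tp,
                    "fp": counts.fp,
                    "tn": counts.tn,
                    "fn": counts.fn,
                    "prevalence_pct": pct(m.prevalence),
                    "sensitivity_pct": pct(m.sensitivity),
                    "sens_ci_low_pct": pct(m.sensitivity_ci and m.sensitivity_ci[0]),
                    "sens_ci_high_pct": pct(m.sensitivity_ci and m.sensitivity_ci[1]),
                    "specificity_pct": pct(m.specificity),
                    "spec_ci_low_pct": pct(m.specificity_ci and m.specificity_ci[0]),
                    "spec_ci_high_pct": pct(m.specificity_ci and m.specificity_ci[1]),
                    "ppv_pct": pct(m.ppv),
                    "npv_pct": pct(m.npv),
                    "accuracy_pct": pct(m.accuracy),
                    "balanced_accuracy": (
                        None
                        if m.balanced_accuracy is None
                        else round(m.balanced_accuracy, 3)
                    ),
                }
            )
        return pd.DataFrame(out)

    def render(self) -> str:
        df = self.to_dataframe().fillna("NA")
        header = (
            f"Validation analysis: {self.n_correct}/{self.n_patients} "
            "correctly diagnosed\n"
        )
        return header + df.to_string(index=False)


def validation_report(
    truths: Sequence,
    predictions: Sequence,
    labels: Sequence | None = None,
    true_malignancy: Sequence | None = None,
    predicted_malignancy: Sequence | None = None,
    confidence: float = 0.95,
) -> ValidationReport:
    """Per-disease metrics table plus an optional pooled malignancy row.

    The malignancy row scores any malignant complication (scar
    carcinoma or metastasis) as positive, regardless of subtype.
    """
    if labels is None:
        labels = DIAGNOSABLE_LABELS
    rows = []
    for label in labels:
        counts = confusion_counts(truths, predictions, label)
        rows.append((counts.label, counts, diagnostic_metrics(counts, confidence)))
    n_correct = sum(
        _as_value(t) == _as_value(p) for t, p in zip(truths, predictions)
    )
    if true_malignancy is not None and predicted_malignancy is not None:
        none = MalignancyFlag.NONE.value

        def flags(values):
            return [
                "Malignancy" if _as_value(v) != none else none for v in values
            ]

        counts = confusion_counts(
            flags(true_malignancy), flags(predicted_malignancy), "Malignancy"
        )
        rows.append((counts.label, counts, diagnostic_metrics(counts, confidence)))
    return ValidationReport(rows, n_patients=len(truths), n_correct=n_correct)
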