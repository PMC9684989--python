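"""Per-disease feature prevalence and chi-square significance analysis.

Reproduces the study's first analytic step: for every (disease, feature)
pair, the prevalence of the feature among that disease's patients, and a
Pearson chi-square test of association on the one-vs-rest 2x2 table
(patients of the disease vs all other patients, feature present vs
absent).  p < 0.05 is flagged significant; cells where the feature was
not performed for any patient of the disease, or where a 2x2 margin is
zero, are reported as not applicable (p is None).

Tri-state laboratory fields count only an explicit positive result; a
``not_done`` entry is never evidence for or against, but the denominator
is always the disease's full patient count, matching the published
table's convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd
from scipy.stats import chi2

from .patient_model import (
    FEATURE_FIELDS,
    TRISTATE_FIELDS,
    DiseaseLabel,
    PatientRecord,
    TriState,
)

SIGNIFICANCE_LEVEL = 0.05


@dataclass
class PrevalenceCell:
    disease: DiseaseLabel
    feature: str
    count: int
    percent: float  # round(100 * count / n_disease, 1)
    p_value: float | None = None  # None = not applicable
    significant: bool | None = None

    def __post_init__(self):
        if self.p_value is not None and self.significant is None:
            self.significant = self.p_value < SIGNIFICANCE_LEVEL


@dataclass
class PrevalenceTable:
    cells: list[PrevalenceCell]
    n_per_disease: dict[DiseaseLabel, int]
    n_total: int
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._index = {(c.disease, c.feature): c for c in self.cells}

    def cell(self, disease: DiseaseLabel, feature: str) -> PrevalenceCell:
        return self._index[(disease, feature)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "disease": c.disease.value,
                    "feature": c.feature,
                    "count": c.count,
                    "percent": c.percent,
                    "p_value": c.p_value,
                    "significant": c.significant,
                }
                for c in self.cells
            ]
        )


def format_p(p: float | None) -> str:
    """Render a p-value the way the study prints them."""
    if p is None:
        return "N/A"
    if p < 0.001:
        return "< 0.001"
    return f"{p:.3f}"


def render_table(table: PrevalenceTable) -> str:
    df = table.to_dataframe()
    df["p"] = [format_p(p) for p in df.pop("p_value")]
    return df.to_string(index=False)


def _feature_positive(record: PatientRecord, feature: str) -> bool:
    value = getattr(record, feature)
    return value is True or value is TriState.TRUE


def _check_labeled(cohort: Sequence[PatientRecord]) -> None:
    if not cohort:
        raise ValueError("empty cohort")
    for rec in cohort:
        if rec.true_label is None:
            raise ValueError(f"record {rec.patient_id!r} has no ground-truth label")


def prevalence_table(
    cohort: Sequence[PatientRecord],
    features: Sequence[str] = FEATURE_FIELDS,
) -> PrevalenceTable:
    """Per-disease feature counts and percentages (no tests)."""
    _check_labeled(cohort)
    diseases = sorted({r.true_label for r in cohort}, key=lambda d: d.value)
    n_per = {d: sum(r.true_label is d for r in cohort) for d in diseases}
    cells = []
    for disease in diseases:
        members = [r for r in cohort if r.true_label is disease]
        for feature in features:
            count = sum(_feature_positive(r, feature) for r in members)
            percent = round(100.0 * count / n_per[disease], 1)
            cells.append(PrevalenceCell(disease, feature, count, percent))
    return PrevalenceTable(cells, n_per, len(cohort))


def chi_square_2x2(
    a: int, b: int, c: int, d: int, correction: str = "none"
) -> tuple[float | None, float | None]:
    """Pearson chi-square on a 2x2 table, 1 degree of freedom.

    Cell layout is (feature & disease, feature & rest, no-feature &
    disease, no-feature & rest); the statistic is invariant under
    transposition.  ``correction="yates"`` applies the continuity
    adjustment |ad-bc| -> max(0, |ad-bc| - N/2).  A zero margin makes
    the test undefined: (None, None) is returned, not raised.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be nonnegative")
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    if correction not in ("none", "yates"):
        raise ValueError(f"unknown correction {correction!r}")
    if 0 in (a + b, c + d, a + c, b + d):
        return None, None
    diff = abs(a * d - b * c)
    if correction == "yates":
        diff = max(0.0, diff - n / 2.0)
    statistic = n * diff**2 / ((a + b) * (c + d) * (a + c) * (b + d))
    return float(statistic), float(chi2.sf(statistic, df=1))


def significance_table(
    cohort: Sequence[PatientRecord],
    features: Sequence[str] = FEATURE_FIELDS,
    correction: str = "none",
    adjust: str = "none",
) -> PrevalenceTable:
    """Prevalence table with one-vs-rest chi-square p-values attached.

    For each (disease, feature): a = feature-positive patients of the
    disease, b = feature-positive patients of every other disease,
    c/d their feature-negative complements.  ``adjust`` optionally
    applies a multiplicity correction ("bonferroni" or "fdr_bh") across
    all testable cells; the study applies none, so the default is none.
    """
    table = prevalence_table(cohort, features)
    by_disease: dict[DiseaseLabel, list[PatientRecord]] = {}
    for rec in cohort:
        by_disease.setdefault(rec.true_label, []).append(rec)
    total_positive = {
        f: sum(_feature_positive(r, f) for r in cohort) for f in features
    }
    for cell in table.cells:
        members = by_disease[cell.disease]
        if cell.feature in TRISTATE_FIELDS and all(
            getattr(r, cell.feature) is TriState.NOT_DONE for r in members
        ):
            continue  # test not performed for this disease: not applicable
        a = cell.count
        b = total_positive[cell.feature] - a
        c = len(members) - a
        d = table.n_total - len(members) - b
        statistic, p = chi_square_2x2(a, b, c, d, correction=correction)
        if p is not None:
            cell.p_value = p
            cell.significant = p < SIGNIFICANCE_LEVEL
    if adjust != "none":
        from statsmodels.stats.multitest import multipletests

        testable = [cell for cell in table.cells if cell.p_value is not None]
        if testable:
            _, adjusted, _, _ = multipletests(
                [cell.p_value for cell in testable],
                alpha=SIGNIFICANCE_LEVEL,
                method=adjust,
            )
            for cell, p_adj in zip(testable, adjusted):
                cell.p_value = float(p_adj)
                cell.significant = cell.p_value < SIGNIFICANCE_LEVEL
    return table
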