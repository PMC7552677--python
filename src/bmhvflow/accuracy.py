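"""Diagnostic accuracy of ASE guideline criteria over a case collection.

Each Doppler report is flagged against the guideline thresholds (inclusive
comparisons, matching the printed ">= 3 m/s" / "<= 0.35" conventions), the
ground-truth dysfunction label comes from the case's prescribed leaflet
restriction under one of two groupings, and sensitivity/specificity follow
from standard confusion-matrix arithmetic.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .doppler import DopplerReport
from .errors import ClassificationError, DegenerateInputError, DomainError
from .study_grid import CaseSpec


@dataclass(frozen=True)
class Criterion:
    """One guideline threshold, e.g. v_peak >= 3 m/s."""

    metric: str      # DopplerReport field name
    op: str          # ">=" or "<="
    threshold: float
    label: str

    def applies(self, value: float) -> bool:
        if self.op == ">=":
            return value >= self.threshold
        if self.op == "<=":
            return value <= self.threshold
        raise DomainError(f"unknown comparison {self.op!r}")


def default_criteria() -> list[Criterion]:
    """The ASE dysfunction criteria for Vpeak, TPGmean, DVI and EOA."""
    return [
        Criterion("v_peak", ">=", 4.0, "Vpeak >= 4 m/s"),
        Criterion("v_peak", ">=", 3.0, "Vpeak >= 3 m/s"),
        Criterion("tpg_mean", ">=", 35.0, "TPGmean >= 35 mmHg"),
        Criterion("tpg_mean", ">=", 20.0, "TPGmean >= 20 mmHg"),
        Criterion("dvi", "<=", 0.35, "DVI <= 0.35"),
        Criterion("dvi", "<=", 0.30, "DVI <= 0.30"),
        Criterion("dvi", "<=", 0.25, "DVI <= 0.25"),
        Criterion("eoa", "<=", 1.2, "EOA <= 1.2 cm2"),
        Criterion("eoa", "<=", 0.8, "EOA <= 0.8 cm2"),
    ]


#: Backwards-compatible alias: the full guideline threshold set.
AseCriteria = list[Criterion]


class Grouping(str, enum.Enum):
    """Ground-truth severity groupings for the accuracy analysis."""

    MILD_TO_SEVERE = "mild_to_severe"          # 50% and 100% dysfunction positive
    MODERATE_TO_SEVERE = "moderate_to_severe"  # only 100% dysfunction positive


def classify(report: DopplerReport,
             criteria: Sequence[Criterion] | None = None) -> dict[str, bool]:
    """Flag a report against each criterion (boundary equality is positive)."""
    criteria = criteria if criteria is not None else default_criteria()
    flags: dict[str, bool] = {}
    for c in criteria:
        value = getattr(report, c.metric, None)
        if value is None or not np.isfinite(value):
            raise ClassificationError(f"report missing metric {c.metric!r}")
        flags[c.label] = c.applies(float(value))
    return flags


def ground_truth(case: CaseSpec, grouping: Grouping | str) -> bool:
    """True iff the case counts as dysfunctional under the grouping."""
    grouping = Grouping(grouping)
    if grouping is Grouping.MILD_TO_SEVERE:
        return case.dysfunction_pct in (50.0, 100.0)
    return case.dysfunction_pct == 100.0


@dataclass(frozen=True)
class SensSpec:
    sensitivity_pct: float  # exact fraction * 100
    specificity_pct: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity_rounded(self) -> int:
        return int(round(self.sensitivity_pct))

    @property
    def specificity_rounded(self) -> int:
        return int(round(self.specificity_pct))


def sensitivity_specificity(flags: Sequence[bool],
                            labels: Sequence[bool]) -> SensSpec:
    """Confusion-matrix sensitivity and specificity (exact percentages)."""
    flags = [bool(f) for f in flags]
    labels = [bool(l) for l in labels]
    if len(flags) != len(labels):
        raise DomainError("flags and labels must have equal length")
    if all(labels):
        raise DegenerateInputError("all labels positive: specificity undefined")
    if not any(labels):
        raise DegenerateInputError("all labels negative: sensitivity undefined")
    tp = sum(f and l for f, l in zip(flags, labels))
    fn = sum((not f) and l for f, l in zip(flags, labels))
    fp = sum(f and (not l) for f, l in zip(flags, labels))
    tn = sum((not f) and (not l) for f, l in zip(flags, labels))
    return SensSpec(sensitivity_pct=100.0 * tp / (tp + fn),
                    specificity_pct=100.0 * tn / (tn + fp),
                    tp=tp, fp=fp, tn=tn, fn=fn)


def accuracy_table(reports: Sequence[DopplerReport],
                   criteria: Sequence[Criterion] | None = None,
                   groupings: Iterable[Grouping | str] = Grouping
                   ) -> pd.DataFrame:
    """Sensitivity/specificity per criterion and grouping.

    Rounded integer percentages are reported alongside the exact fractions
    and the raw confusion counts; reports must carry their CaseSpec.
    """
    criteria = criteria if criteria is not None else default_criteria()
    if any(r.case is None for r in reports):
        raise ClassificationError("every report needs an attached CaseSpec")
    rows = []
    for grouping in groupings:
        grouping = Grouping(grouping)
        labels = [ground_truth(r.case, grouping) for r in reports]
        for c in criteria:
            flags = [classify(r, [c])[c.label] for r in reports]
            ss = sensitivity_specificity(flags, labels)
            rows.append({
                "criterion": c.label, "grouping": grouping.value,
                "sensitivity_pct": ss.sensitivity_rounded,
                "specificity_pct": ss.specificity_rounded,
                "sensitivity_exact": ss.sensitivity_pct,
                "specificity_exact": ss.specificity_pct,
                "tp": ss.tp, "fp": ss.fp, "tn": ss.tn, "fn": ss.fn,
            })
    return pd.DataFrame(rows)


_METRICS = ("v_peak", "tpg_mean", "dvi", "eoa")


def summarize_by_lvot(reports: Sequence[DopplerReport]) -> pd.DataFrame:
    """Per-LVOT-diameter mean +/- SD and (min-max) of each Doppler metric.

    Sample standard deviation (n-1); rows ordered by diameter descending.
    """
    if any(r.case is None for r in reports):
        raise ClassificationError("every report needs an attached CaseSpec")
    by_d: dict[float, list[DopplerReport]] = {}
    for r in reports:
        by_d.setdefault(r.case.lvot_diameter_mm, []).append(r)
    rows = []
    for d in sorted(by_d, reverse=True):
        group = by_d[d]
        if len(group) < 2:
            raise DegenerateInputError(
                f"need >= 2 reports for LVOT diameter {d} mm, got {len(group)}")
        row: dict[str, float] = {"lvot_diameter_mm": d, "n": len(group)}
        for m in _METRICS:
            vals = np.array([getattr(r, m) for r in group], dtype=float)
            row[f"{m}_mean"] = float(vals.mean())
            row[f"{m}_sd"] = float(vals.std(ddof=1))
            row[f"{m}_min"] = float(vals.min())
            row[f"{m}_max"] = float(vals.max())
        rows.append(row)
    return pd.DataFrame(rows)
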