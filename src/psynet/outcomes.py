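"""Lab-anchored derivation of the BMI/A improvement threshold and
IMPV/MC outcome classification.

Nutritional improvement is measured as delta-z = z_entry - z_exit
(positive when the BMI-for-age z-score decreased, i.e. the child
improved). Children with a complete biomarker panel are split by
whether all three labs (insulin, triglycerides, HOMA-IR) moved strictly
toward their healthy range; the two delta-z distributions are compared
with a two-sided Mann-Whitney U test, and the improvement threshold is
the mean delta-z of the all-three-improved group. A child is labeled
IMPV when delta-z >= threshold (inclusive boundary), MC otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import json

from scipy.stats import mannwhitneyu

from .cohort import Cohort, CohortRecord, CohortValidationError, LabPanelPair, Outcome


class ThresholdDerivationError(CohortValidationError):
    """Empty partition or no lab-complete children."""


@dataclass(frozen=True)
class AnalyteRange:
    """Improvement direction and healthy bound for one analyte.

    ``direction`` is "decrease" when lower values are healthier (the
    case for all three defaults in an obesity cohort). The bound is
    carried for reporting; improvement is judged by strict movement in
    the healthy direction.
    """

    direction: str  # "decrease" or "increase"
    healthy_bound: float

    def __post_init__(self) -> None:
        if self.direction not in ("decrease", "increase"):
            raise ValueError(f"direction must be 'decrease' or 'increase', got {self.direction!r}")


@dataclass(frozen=True)
class HealthyRanges:
    insulin: AnalyteRange = field(default_factory=lambda: AnalyteRange("decrease", 15.0))
    triglycerides: AnalyteRange = field(default_factory=lambda: AnalyteRange("decrease", 100.0))
    homa_ir: AnalyteRange = field(default_factory=lambda: AnalyteRange("decrease", 2.5))


@dataclass(frozen=True)
class ThresholdResult:
    threshold: float  # mean delta-z of the improved-lab group
    n_improved: int
    n_not_improved: int
    n_lab_complete: int
    mwu_statistic: float
    mwu_p: float
    improved_mean: float
    not_improved_mean: float

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, sort_keys=True) + "\n")


def delta_z(record: CohortRecord) -> float:
    """BMI/A z-score change, entry minus exit (positive = improvement)."""
    return record.z_bmi_entry - record.z_bmi_exit


def labs_improved_all(labs: LabPanelPair, ranges: HealthyRanges) -> bool:
    """True iff all three analytes moved strictly toward healthy.

    No change counts as not improved ("no change or a worsening").
    """
    for name in ("insulin", "triglycerides", "homa_ir"):
        first = getattr(labs.first, name)
        last = getattr(labs.last, name)
        direction = getattr(ranges, name).direction
        improved = last < first if direction == "decrease" else last > first
        if not improved:
            return False
    return True


def derive_threshold(cohort: Cohort, ranges: Optional[HealthyRanges] = None) -> ThresholdResult:
    """Derive the improvement threshold from the lab-complete subset.

    Partitions lab-complete children by :func:`labs_improved_all`,
    compares the two delta-z distributions with a two-sided
    Mann-Whitney U test, and sets the threshold to the arithmetic mean
    delta-z of the all-three-improved group.
    """
    ranges = ranges or HealthyRanges()
    lab_complete = [r for r in cohort.records if r.labs is not None]
    if not lab_complete:
        raise ThresholdDerivationError("no children with a complete lab panel")
    improved = [delta_z(r) for r in lab_complete if labs_improved_all(r.labs, ranges)]
    not_improved = [delta_z(r) for r in lab_complete if not labs_improved_all(r.labs, ranges)]
    if len(improved) < 2 or len(not_improved) < 2:
        raise ThresholdDerivationError(
            f"need >=2 children in each lab partition, got {len(improved)} improved / "
            f"{len(not_improved)} not improved"
        )
    res = mannwhitneyu(improved, not_improved, alternative="two-sided")
    improved_mean = sum(improved) / len(improved)
    not_improved_mean = sum(not_improved) / len(not_improved)
    return ThresholdResult(
        threshold=improved_mean,
        n_improved=len(improved),
        n_not_improved=len(not_improved),
        n_lab_complete=len(lab_complete),
        mwu_statistic=float(res.statistic),
        mwu_p=float(res.pvalue),
        improved_mean=improved_mean,
        not_improved_mean=not_improved_mean,
    )


def classify_outcomes(cohort: Cohort, threshold: float) -> dict[str, Outcome]:
    """Label each child IMPV iff delta-z >= threshold, else MC."""
    labels: dict[str, Outcome] = {}
    for r in cohort.records:
        labels[r.child_id] = Outcome.IMPV if delta_z(r) >= threshold else Outcome.MC
    return labels
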