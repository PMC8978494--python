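"""WHO-5 screening-cutoff validation against depression/anxiety/stress screens.

A low normalized WHO-5 score is the *positive* screen: a user screens
positive for a condition when ``who5_norm < cutoff``.  Candidate cutoffs are
swept over a grid and scored by their sensitivity and specificity against
binarized PHQ-9 (depression, >= 10), GAD (anxiety, >= 10) and PSS (stress,
>= 21) questionnaires.  The binary cutoff is selected by maximal mean
Youden's J across conditions; the trinary cutoffs by specificity/sensitivity
floors (defaults 0.8 / 0.9).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scales import CutoffSet

__all__ = [
    "ConditionSpec",
    "CONDITIONS",
    "CutoffEvaluation",
    "SelectionPolicy",
    "ThresholdSelection",
    "binarize_condition",
    "cutoff_confusion",
    "sweep_cutoffs",
    "select_cutoffs",
]


@dataclass(frozen=True)
class ConditionSpec:
    """A mental-health condition and its screen-positive rule."""

    name: str
    scale: str  # source questionnaire: PHQ | GAD | PSS
    threshold: float  # score >= threshold is screen-positive
    scale_max: float


CONDITIONS = {
    "depression": ConditionSpec("depression", "PHQ", 10, 27),
    "anxiety": ConditionSpec("anxiety", "GAD", 10, 21),
    "stress": ConditionSpec("stress", "PSS", 21, 40),
}


def binarize_condition(spec: ConditionSpec, score):
    """True when the questionnaire score meets the screen-positive rule."""
    arr = np.asarray(score, dtype=float)
    if np.any(arr < 0) or np.any(arr > spec.scale_max):
        raise ValueError(f"{spec.scale} score outside [0, {spec.scale_max}]")
    out = arr >= spec.threshold
    return bool(out) if np.isscalar(score) else out


@dataclass
class CutoffEvaluation:
    """Confusion counts and rates of one WHO-5 cutoff for one condition."""

    condition: str
    cutoff: float
    n: int
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float  # NaN when no condition-positives exist
    specificity: float  # NaN when no condition-negatives exist

    @property
    def undefined(self) -> bool:
        return np.isnan(self.sensitivity) or np.isnan(self.specificity)


def cutoff_confusion(who5_norm, condition_labels, cutoff,
                     condition: str = "") -> CutoffEvaluation:
    """Exact confusion counts of the screen ``who5_norm < cutoff``.

    ``condition_labels`` are the ground-truth booleans from
    :func:`binarize_condition`.  Undefined rates (single-class labels) are
    reported as NaN rather than raised.
    """
    scores = np.asarray(who5_norm, dtype=float)
    labels = np.asarray(condition_labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    screen_pos = scores < cutoff
    tp = int(np.sum(screen_pos & labels))
    fp = int(np.sum(screen_pos & ~labels))
    tn = int(np.sum(~screen_pos & ~labels))
    fn = int(np.sum(~screen_pos & labels))
    sens = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    spec = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    return CutoffEvaluation(condition, float(cutoff), scores.size,
                            tp, fp, tn, fn, sens, spec)


def _default_grid(scores: np.ndarray) -> np.ndarray:
    uniq = np.unique(scores)
    if uniq.size < 2:
        return uniq.copy()
    return (uniq[1:] + uniq[:-1]) / 2.0


def sweep_cutoffs(who5_norm, labels_by_condition, grid=None) -> pd.DataFrame:
    """Evaluate every (condition, cutoff) pair.

    Parameters
    ----------
    who5_norm : array or mapping condition -> array
        Normalized WHO-5 scores.  A mapping allows per-condition cohorts
        (users missing a questionnaire are excluded per condition).
    labels_by_condition : mapping condition -> boolean array
    grid : array, optional
        Candidate cutoffs; defaults to midpoints of the pooled sorted
        unique scores.
    """
    per_condition_scores = isinstance(who5_norm, dict)
    if grid is None:
        if per_condition_scores:
            pooled = np.concatenate([np.asarray(v, float)
                                     for v in who5_norm.values()])
        else:
            pooled = np.asarray(who5_norm, float)
        grid = _default_grid(pooled)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty cutoff grid")
    rows = []
    for cond, labels in labels_by_condition.items():
        scores = who5_norm[cond] if per_condition_scores else who5_norm
        for c in grid:
            ev = cutoff_confusion(scores, labels, c, condition=cond)
            rows.append(vars(ev))
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SelectionPolicy:
    """Documented stand-in for the cutoff choice: Youden's J for the binary
    cutoff, specificity/sensitivity floors for the trinary pair."""

    trinary_specificity_floor: float = 0.8
    trinary_sensitivity_floor: float = 0.9


@dataclass
class ThresholdSelection:
    binary: CutoffSet | None
    trinary: CutoffSet | None
    report: dict = field(default_factory=dict)

    @property
    def failed(self) -> bool:
        return bool(self.report.get("failures"))


def select_cutoffs(sweep_table: pd.DataFrame,
                   policy: SelectionPolicy = SelectionPolicy()
                   ) -> ThresholdSelection:
    """Select binary and trinary cutoffs from a :func:`sweep_cutoffs` table.

    Binary: the cutoff maximizing the across-condition mean of Youden's
    J = sensitivity + specificity - 1 (ties broken toward the smaller
    cutoff).  Trinary: lower = largest cutoff whose mean specificity meets
    the floor; upper = smallest cutoff whose mean sensitivity meets the
    floor.  Unsatisfiable constraints are reported under
    ``report["failures"]`` instead of raising.
    """
    failures: list[str] = []
    tab = sweep_table
    by_cutoff = tab.groupby("cutoff")[["sensitivity", "specificity"]].mean()
    j = by_cutoff["sensitivity"] + by_cutoff["specificity"] - 1.0
    j = j.dropna()
    report: dict = {"policy": policy}
    binary = None
    if j.empty:
        failures.append("youden J undefined for every cutoff "
                        "(single-class labels for every condition)")
    else:
        best = float(j.index[np.argmax(j.to_numpy())])
        report["binary_youden_j"] = float(j.max())
        if 0.0 < best < 1.0:
            binary = CutoffSet("binary", (best,))
        else:
            failures.append(f"binary argmax {best} outside (0, 1)")

    trinary = None
    spec_ok = by_cutoff.index[
        by_cutoff["specificity"] >= policy.trinary_specificity_floor]
    sens_ok = by_cutoff.index[
        by_cutoff["sensitivity"] >= policy.trinary_sensitivity_floor]
    lower = float(spec_ok.max()) if len(spec_ok) else None
    upper = float(sens_ok.min()) if len(sens_ok) else None
    if lower is None:
        failures.append("no cutoff reaches the trinary specificity floor")
    if upper is None:
        failures.append("no cutoff reaches the trinary sensitivity floor")
    if lower is not None and upper is not None:
        if lower < upper and 0.0 < lower and upper < 1.0:
            trinary = CutoffSet("trinary", (lower, upper))
        else:
            failures.append(
                f"trinary cutoffs not ascending in (0,1): {lower}, {upper}")
    report["failures"] = failures
    return ThresholdSelection(binary, trinary, report)
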