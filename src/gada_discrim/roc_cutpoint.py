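"""Empirical ROC analysis and closest-to-corner cutoff selection.

Thresholds are placed at observed values only (no interpolation).  For a
CASE_HIGH variable a record tests positive when its value is >= the
threshold; for a CASE_LOW variable when its value is < the threshold.  The
optimal cutoff minimizes the distance from (sensitivity, specificity) to the
perfect corner (1, 1):

    distance = sqrt((1 - sensitivity)^2 + (1 - specificity)^2)

The squared form is reported alongside; both orderings share the argmin.
AUC is the rank-based (Mann-Whitney) estimate with ties counted one half,
with a Hanley-McNeil 95% confidence interval.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .cohort_model import Cohort, CutoffSet, Group
from .errors import DomainError


class Direction(str, enum.Enum):
    CASE_HIGH = "CASE_HIGH"  # cases tend to have higher values
    CASE_LOW = "CASE_LOW"  # cases tend to have lower values


@dataclass
class RocPoint:
    threshold: float
    sensitivity: float
    specificity: float


@dataclass
class RocCurve:
    variable: str
    direction: Direction
    points: list  # of RocPoint, ordered by threshold
    auc: float
    auc_ci: tuple  # (lo, hi) at 95%, Hanley-McNeil


@dataclass
class RocCutoffResult:
    variable: str
    cutoff: float
    sensitivity: float
    specificity: float
    distance: float
    distance_squared: float
    rule: str
    direction: Direction
    auc: float = float("nan")
    auc_ci: tuple = (float("nan"), float("nan"))


def corner_distance_squared(sensitivity: float, specificity: float) -> float:
    """(1 - sensitivity)^2 + (1 - specificity)^2."""
    return (1.0 - sensitivity) ** 2 + (1.0 - specificity) ** 2


def mann_whitney_auc(case_values: np.ndarray, control_values: np.ndarray) -> float:
    """P(case > control) + 0.5 P(case = control), via average ranks."""
    n1, n2 = case_values.size, control_values.size
    ranks = stats.rankdata(np.concatenate([case_values, control_values]))
    return float((ranks[:n1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n2))


def hanley_mcneil_ci(auc: float, n_case: int, n_control: int, level: float = 0.95) -> tuple:
    """Hanley-McNeil standard-error CI for an AUC, clipped to [0, 1]."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_case - 1) * (q1 - auc**2)
        + (n_control - 1) * (q2 - auc**2)
    ) / (n_case * n_control)
    se = float(np.sqrt(max(var, 0.0)))
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (max(0.0, auc - z * se), min(1.0, auc + z * se))


def empirical_roc(
    values: Sequence[float],
    is_case: Sequence[bool],
    direction: Optional[Direction] = None,
    variable: str = "",
) -> RocCurve:
    """Empirical ROC with one point per distinct observed value.

    When ``direction`` is None it is inferred from the sign of the
    case-minus-control mean difference (ties -> CASE_HIGH).
    """
    x = np.asarray(values, dtype=float)
    case = np.asarray(is_case, dtype=bool)
    if x.shape != case.shape or x.ndim != 1:
        raise DomainError("values and is_case must be equal-length 1-D sequences")
    n1 = int(case.sum())
    n2 = int((~case).sum())
    if n1 == 0 or n2 == 0:
        raise DomainError("need at least one case and one control")

    xc, xr = x[case], x[~case]
    if direction is None:
        direction = Direction.CASE_HIGH if xc.mean() >= xr.mean() else Direction.CASE_LOW

    thresholds = np.unique(x)
    xc_sorted, xr_sorted = np.sort(xc), np.sort(xr)
    # integer counts strictly below each threshold; dividing counts (not
    # subtracting fractions) keeps sens/spec bit-identical to direct counting
    below_case = np.searchsorted(xc_sorted, thresholds, side="left")
    below_ctrl = np.searchsorted(xr_sorted, thresholds, side="left")
    if direction is Direction.CASE_HIGH:
        sens_arr, spec_arr = (n1 - below_case) / n1, below_ctrl / n2
    else:
        sens_arr, spec_arr = below_case / n1, (n2 - below_ctrl) / n2
    points = [
        RocPoint(float(t), float(se), float(sp))
        for t, se, sp in zip(thresholds, sens_arr, spec_arr)
    ]

    auc = mann_whitney_auc(xc, xr)
    if direction is Direction.CASE_LOW:
        auc = 1.0 - auc
    ci = hanley_mcneil_ci(auc, n1, n2)
    return RocCurve(variable=variable, direction=direction, points=points, auc=auc, auc_ci=ci)


def min_distance_cutoff(curve: RocCurve) -> RocCutoffResult:
    """ROC point closest to the perfect corner.

    Ties are broken toward higher sensitivity, then lower threshold.
    """
    if not curve.points:
        raise DomainError("empty ROC curve")
    best = min(
        curve.points,
        key=lambda p: (corner_distance_squared(p.sensitivity, p.specificity), -p.sensitivity, p.threshold),
    )
    d2 = corner_distance_squared(best.sensitivity, best.specificity)
    op = ">=" if curve.direction is Direction.CASE_HIGH else "<"
    return RocCutoffResult(
        variable=curve.variable,
        cutoff=best.threshold,
        sensitivity=best.sensitivity,
        specificity=best.specificity,
        distance=float(np.sqrt(d2)),
        distance_squared=float(d2),
        rule=f"{curve.variable or 'value'} {op} {best.threshold:g}",
        direction=curve.direction,
        auc=curve.auc,
        auc_ci=curve.auc_ci,
    )


def cutoffs_for_variables(cohort: Cohort, variables: Sequence[str]) -> dict:
    """Closest-to-corner cutoff per variable (complete case per variable).

    Cases are the GADA-positive records; direction is inferred per variable.
    Returns ``{variable: RocCutoffResult}`` in the requested order.
    """
    cohort.require_two_groups()
    results: dict[str, RocCutoffResult] = {}
    for variable in variables:
        values, labels = [], []
        for rec in cohort.records:
            value = getattr(rec, variable, None)
            if value is None or rec.group is None:
                continue
            values.append(value)
            labels.append(rec.group is Group.GADA_POS)
        curve = empirical_roc(values, labels, variable=variable)
        results[variable] = min_distance_cutoff(curve)
    return results


def cutoff_set_from_results(results: dict, default: Optional[CutoffSet] = None) -> CutoffSet:
    """Build the encoding cutoffs from per-variable ROC results.

    Variables without a result keep the published defaults (or ``default``).
    """
    cuts = default or CutoffSet()
    mapping = cuts.as_dict()
    for variable, res in results.items():
        mapping[variable] = float(res.cutoff)
    return CutoffSet.from_dict(mapping)
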