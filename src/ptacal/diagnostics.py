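"""ROC analysis, cutoff derivation and nonparametric group comparisons.

The ROC convention throughout: higher marker means more likely positive, and a
positive call requires the marker *strictly above* the threshold (consistent
with the score rule "above the cut-off values").  Candidate thresholds are the
midpoints between consecutive sorted unique observed values plus sentinels
below the minimum and above the maximum, so every achievable
sensitivity/specificity pair appears exactly once.  The area under the curve
is computed by the trapezoidal rule and, by construction, equals the
tie-adjusted Mann-Whitney statistic U/(n1*n2).

Cutoffs maximise Youden's J = sensitivity + specificity - 1; ties are broken
toward higher specificity, then toward the larger threshold.  AUC quality
labels follow the bands excellent > 0.9, good > 0.8, acceptable >= 0.7,
poor < 0.7 (exactly 0.7 falls in "acceptable" by closed-lower-bound
convention).
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RocResult",
    "GroupSummary",
    "roc_curve",
    "classify_auc",
    "optimal_cutoff",
    "mann_whitney_u",
    "group_summary",
]


@dataclass
class RocResult:
    """ROC points, AUC with quality label, and (once derived) the chosen cutoff."""

    points: list[tuple[float, float, float]]  # (threshold, sensitivity, specificity)
    auc: float
    auc_class: str
    n_positive: int
    n_negative: int
    cutoff: Optional[float] = None
    cutoff_sens: Optional[float] = None
    cutoff_spec: Optional[float] = None
    criterion: Optional[str] = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["points"] = [list(p) for p in self.points]
        return d

    def points_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.points, columns=["threshold", "sensitivity", "specificity"])
        df["fpr"] = 1.0 - df["specificity"]
        return df


def classify_auc(auc: float) -> str:
    """Quality label for an area under the ROC curve."""
    if not 0.0 <= auc <= 1.0:
        raise ValueError(f"AUC must lie in [0, 1], got {auc}")
    if auc > 0.9:
        return "excellent"
    if auc > 0.8:
        return "good"
    if auc >= 0.7:
        return "acceptable"
    return "poor"


def roc_curve(values: Sequence, labels: Sequence) -> RocResult:
    """Empirical ROC curve of a marker against binary condition labels.

    ``labels`` are truthy for condition-positive subjects.  Requires at least
    one positive and one negative.
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels, dtype=bool)
    if v.shape != lab.shape:
        raise ValueError("values and labels must have the same length")
    keep = ~np.isnan(v)
    v, lab = v[keep], lab[keep]
    n_pos = int(lab.sum())
    n_neg = int((~lab).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative subject")

    uniq = np.unique(v)
    thresholds = np.concatenate(
        [[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]]
    )
    pos, neg = v[lab], v[~lab]
    points = []
    for t in thresholds:
        sens = float(np.mean(pos > t))
        spec = float(np.mean(neg <= t))
        points.append((float(t), sens, spec))

    # Thresholds ascend, so FPR and sensitivity both descend; reverse both to
    # integrate left to right over (FPR, sensitivity).
    fpr = np.array([1.0 - spec for _, _, spec in points])[::-1]
    sens_arr = np.array([s for _, s, _ in points])[::-1]
    auc = float(np.trapezoid(sens_arr, fpr))
    auc = min(max(auc, 0.0), 1.0)  # clamp -0.0 / float fuzz
    return RocResult(
        points=points,
        auc=auc,
        auc_class=classify_auc(auc),
        n_positive=n_pos,
        n_negative=n_neg,
    )


def optimal_cutoff(roc: RocResult) -> RocResult:
    """Fill the cutoff fields of a ROC result by maximising Youden's J.

    Only interior thresholds (midpoints between observed values) are eligible.
    Ties go to the point with higher specificity, then the larger threshold.
    """
    interior = roc.points[1:-1]
    if not interior:
        interior = roc.points  # degenerate: all observations identical
    best = max(interior, key=lambda p: (p[1] + p[2] - 1.0, p[2], p[0]))
    return replace(
        roc,
        cutoff=best[0],
        cutoff_sens=best[1],
        cutoff_spec=best[2],
        criterion="youden",
    )


def mann_whitney_u(a: Sequence, b: Sequence) -> tuple[float, float]:
    """Mann-Whitney U (for the first sample, from mid-rank sums) and the
    two-sided p-value.

    The p-value is by exact enumeration when n1*n2 <= 400 and there are no
    ties, and by the normal approximation with tie correction otherwise.
    """
    aa = np.asarray(a, dtype=float)
    bb = np.asarray(b, dtype=float)
    aa, bb = aa[~np.isnan(aa)], bb[~np.isnan(bb)]
    if aa.size == 0 or bb.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([aa, bb])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (aa.size * bb.size <= 400 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(aa, bb, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class GroupSummary:
    """Mean +/- SEM for one group, optionally with a Mann-Whitney comparison
    against a reference group."""

    n: int
    mean: float
    sem: Optional[float]
    u_stat: Optional[float] = None
    p_two_sided: Optional[float] = None


def group_summary(values: Sequence) -> GroupSummary:
    """n, mean and SEM (sample SD / sqrt(n)); SEM is undefined (None) at n = 1."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("cannot summarise an empty group")
    sem = float(np.std(v, ddof=1) / np.sqrt(v.size)) if v.size >= 2 else None
    return GroupSummary(n=int(v.size), mean=float(np.mean(v)), sem=sem)
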