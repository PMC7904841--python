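"""Agreement between the rapid test (QBT) and ELISA for one fluid.

Three complementary views, mirroring standard method-comparison practice:

* Spearman rank correlation with the labelled strength bands used in the
  source study (negligible / low / good / excellent);
* ordinary least-squares regression slope with a two-sided t confidence
  interval (direction: ELISA regressed on QBT);
* Bland-Altman analysis of the differences QBT - ELISA, with limits of
  agreement at bias +/- 2 x SD and an optional restriction to pairs whose
  per-pair mean lies in a clinically relevant range (<= 12,000 ng/ml by
  default downstream).

Missing values are removed pairwise.  The difference histogram and an
advisory Shapiro-Wilk p-value describe normality of the differences; neither
gates any result.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "AgreementReport",
    "BlandAltman",
    "spearman_r",
    "classify_correlation",
    "regression_slope_ci",
    "bland_altman",
    "agreement_report",
]


def _paired_clean(x: Sequence, y: Sequence) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise deletion of missing values."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("x and y must have the same length")
    keep = ~(np.isnan(xa) | np.isnan(ya))
    return xa[keep], ya[keep]


def spearman_r(x: Sequence, y: Sequence) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks
    (average ranks on ties), after pairwise deletion of missing values."""
    xc, yc = _paired_clean(x, y)
    if xc.size < 3:
        raise ValueError(f"need at least 3 complete pairs, got {xc.size}")
    if np.unique(xc).size < 2 or np.unique(yc).size < 2:
        raise ValueError("zero variance in the ranks of one argument")
    r = stats.spearmanr(xc, yc).statistic
    return float(r)


def classify_correlation(r: float) -> str:
    """Strength label for a Spearman coefficient: low (0.2 < r <= 0.5),
    good (0.5 < r <= 0.8), excellent (r > 0.8); below 0.2 is negligible."""
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"correlation must lie in [-1, 1], got {r}")
    if r > 0.8:
        return "excellent"
    if r > 0.5:
        return "good"
    if r > 0.2:
        return "low"
    return "negligible"


def regression_slope_ci(
    x: Sequence, y: Sequence, alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """OLS slope of y on x with a two-sided (1 - alpha) t-interval."""
    xc, yc = _paired_clean(x, y)
    if xc.size < 3:
        raise ValueError(f"need at least 3 complete pairs, got {xc.size}")
    if np.ptp(xc) == 0:
        raise ValueError("x has zero variance; slope undefined")
    model = sm.OLS(yc, sm.add_constant(xc)).fit()
    slope = float(model.params[1])
    lo, hi = model.conf_int(alpha=alpha)[1]
    return slope, (float(lo), float(hi))


@dataclass
class BlandAltman:
    """Bias, limits of agreement and difference histogram for paired methods."""

    n_pairs: int
    n_excluded: int
    bias: float
    sd: float
    limits: tuple[float, float]
    restriction: Optional[float]
    hist_edges: list[float] = field(default_factory=list)
    hist_counts: list[int] = field(default_factory=list)
    shapiro_p: Optional[float] = None


def bland_altman(
    qbt: Sequence,
    elisa: Sequence,
    restriction: Optional[float] = None,
    bins: int = 10,
) -> BlandAltman:
    """Bland-Altman analysis of QBT - ELISA differences.

    ``restriction`` keeps pairs whose per-pair mean (QBT + ELISA)/2 does not
    exceed the given bound (the plot's abscissa), mirroring the restriction to
    a clinically relevant concentration range.  Limits of agreement are
    bias +/- 2 x SD with the sample SD (n - 1 denominator).
    """
    q, e = _paired_clean(qbt, elisa)
    means = (q + e) / 2.0
    n_total = q.size
    if restriction is not None:
        keep = means <= restriction
        q, e = q[keep], e[keep]
    n = q.size
    if n < 2:
        raise ValueError(
            f"need at least 2 pairs after restriction, got {n} of {n_total}"
        )
    diffs = q - e
    bias = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    counts, edges = np.histogram(diffs, bins=bins)
    # Shapiro-Wilk needs >= 3 values and nonzero spread; advisory only.
    shapiro_p: Optional[float] = None
    if n >= 3 and np.ptp(diffs) > 0:
        shapiro_p = float(stats.shapiro(diffs).pvalue)
    return BlandAltman(
        n_pairs=n,
        n_excluded=n_total - n,
        bias=bias,
        sd=sd,
        limits=(bias - 2.0 * sd, bias + 2.0 * sd),
        restriction=restriction,
        hist_edges=[float(v) for v in edges],
        hist_counts=[int(c) for c in counts],
        shapiro_p=shapiro_p,
    )


@dataclass
class AgreementReport:
    """Combined QBT-vs-ELISA agreement summary for one fluid."""

    fluid: str
    n_pairs: int
    r_sp: float
    r_class: str
    slope: float
    slope_ci95: tuple[float, float]
    ba: BlandAltman

    def to_dict(self) -> dict:
        d = asdict(self)
        d["slope_ci95"] = list(self.slope_ci95)
        d["ba"]["limits"] = list(self.ba.limits)
        return d


def agreement_report(
    qbt: Sequence,
    elisa: Sequence,
    fluid: str = "saliva",
    ba_restriction: Optional[float] = 12000.0,
    bins: int = 10,
) -> AgreementReport:
    """Full per-fluid agreement analysis.

    The regression direction is ELISA on QBT: with the rapid test biased high,
    a slope below one expresses that ELISA reads lower on the QBT scale.
    """
    q, e = _paired_clean(qbt, elisa)
    r = spearman_r(q, e)
    slope, ci = regression_slope_ci(q, e)
    ba = bland_altman(q, e, restriction=ba_restriction, bins=bins)
    return AgreementReport(
        fluid=fluid,
        n_pairs=int(q.size),
        r_sp=r,
        r_class=classify_correlation(r),
        slope=slope,
        slope_ci95=ci,
        ba=ba,
    )
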