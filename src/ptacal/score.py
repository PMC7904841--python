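"""The adjusted PTA score: a 0-6 additive triage score for peritonsillar abscess.

One point for each of four clinical symptoms (trismus, halitosis, uvula edema,
unilateral swelling of the arched palate) and one point each for serum and
saliva calprotectin strictly above its rapid-test cutoff (defaults 2940 and
5310 ng/ml).  The ROC-derived statistical cutoff of 2.5 points becomes, for
integer-valued individual scores, a clinical cutoff of 3 points: a score of 3
or more calls the abscess.

Boundary convention: "above the cutoff" is a strict inequality everywhere —
a concentration exactly at its cutoff scores no point, and a score exactly at
an integer statistical cutoff is negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import pandas as pd

from .cohort import PatientRecord, SYMPTOMS
from .diagnostics import (
    GroupSummary,
    RocResult,
    group_summary,
    mann_whitney_u,
    optimal_cutoff,
    roc_curve,
)

__all__ = [
    "ScoreConfig",
    "ScoreResult",
    "ConfusionMatrix",
    "ScoreCohortResult",
    "clinical_cutoff",
    "compute_score",
    "score_cohort",
]

CRITERIA = SYMPTOMS + ("serum_elevated", "saliva_elevated")


@dataclass(frozen=True)
class ScoreConfig:
    serum_cutoff: float = 2940.0
    saliva_cutoff: float = 5310.0
    statistical_cutoff: float = 2.5
    missing_policy: str = "error"  # or "score_available_flagged"

    def __post_init__(self) -> None:
        if self.serum_cutoff <= 0 or self.saliva_cutoff <= 0:
            raise ValueError("biomarker cutoffs must be positive")
        if not 0.0 < self.statistical_cutoff < 6.0:
            raise ValueError("statistical_cutoff must lie in (0, 6)")
        if self.missing_policy not in ("error", "score_available_flagged"):
            raise ValueError(f"unknown missing_policy {self.missing_policy!r}")


@dataclass
class ScoreResult:
    """Per-patient score with its six-criterion breakdown."""

    patient_id: str
    score: int
    criteria: dict
    classification: str  # pta_positive | pta_negative
    incomplete: bool

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)


def clinical_cutoff(statistical_cutoff: float) -> int:
    """Smallest integer strictly greater than the ROC-derived cutoff.

    Individual scores are integers, so a statistical cutoff of 2.5 points
    becomes a clinical rule of "3 points or more".
    """
    if not 0.0 < statistical_cutoff < 6.0:
        raise ValueError("statistical_cutoff must lie in (0, 6)")
    return int(math.floor(statistical_cutoff)) + 1


def compute_score(record: PatientRecord, config: ScoreConfig = ScoreConfig()) -> ScoreResult:
    """Score one patient: one point per present symptom, one point per fluid
    with calprotectin strictly above its cutoff.

    Under ``missing_policy="error"`` every one of the six inputs must be
    present; under ``"score_available_flagged"`` missing criteria score no
    point and the result is flagged incomplete.  A record with all six inputs
    missing is an error under either policy.
    """
    raw = {s: getattr(record, s) for s in SYMPTOMS}
    raw["serum_elevated"] = (
        None if record.serum_qbt is None else record.serum_qbt > config.serum_cutoff
    )
    raw["saliva_elevated"] = (
        None if record.saliva_qbt is None else record.saliva_qbt > config.saliva_cutoff
    )

    missing = [k for k, v in raw.items() if v is None]
    if len(missing) == len(raw):
        raise ValueError(f"patient {record.patient_id}: all six score inputs missing")
    if missing and config.missing_policy == "error":
        raise ValueError(
            f"patient {record.patient_id}: missing score inputs {missing} "
            "(missing_policy='error')"
        )

    criteria = {k: bool(v) if v is not None else False for k, v in raw.items()}
    score = sum(criteria.values())
    positive = score >= clinical_cutoff(config.statistical_cutoff)
    return ScoreResult(
        patient_id=record.patient_id,
        score=score,
        criteria=criteria,
        classification="pta_positive" if positive else "pta_negative",
        incomplete=bool(missing),
    )


@dataclass
class ScoreCohortResult:
    """Cohort-level score analysis: per-group summaries, Mann-Whitney
    comparisons against the PTA group, the score ROC, and the confusion
    matrix of the integer clinical cutoff."""

    results: list[ScoreResult]
    group_summaries: dict  # group -> GroupSummary (u_stat/p vs PTA filled)
    roc: RocResult
    clinical_cutoff: int
    confusion: ConfusionMatrix
    negative_class: str

    def score_table(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            row = {"patient_id": r.patient_id}
            row.update({k: int(v) for k, v in r.criteria.items()})
            row["score"] = r.score
            row["classification"] = r.classification
            rows.append(row)
        return pd.DataFrame(rows)


def score_cohort(
    records: Sequence[PatientRecord],
    config: ScoreConfig = ScoreConfig(),
    negative_class: str = "controls",
) -> ScoreCohortResult:
    """Score every patient and reproduce the score-level group comparison and ROC.

    The score ROC treats PTA membership as the condition; the negative class
    is either the healthy controls (default) or all non-PTA subjects,
    mirroring the marker-level ROC configuration.
    """
    if negative_class not in ("controls", "all"):
        raise ValueError(f"negative_class must be 'controls' or 'all', got {negative_class!r}")
    groups = {r.group for r in records}
    if "pta" not in groups:
        raise ValueError("cohort contains no PTA subjects")
    if groups == {"pta"}:
        raise ValueError("cohort contains no comparison group")

    results = [compute_score(r, config) for r in records]
    by_group: dict[str, list[int]] = {}
    for rec, res in zip(records, results):
        by_group.setdefault(rec.group, []).append(res.score)

    summaries: dict[str, GroupSummary] = {}
    pta_scores = by_group["pta"]
    for g, scores in by_group.items():
        s = group_summary(scores)
        if g != "pta":
            s.u_stat, s.p_two_sided = mann_whitney_u(pta_scores, scores)
        summaries[g] = s

    if negative_class == "controls":
        if "control" not in by_group:
            raise ValueError("negative_class='controls' but cohort has no controls")
        neg_scores = by_group["control"]
    else:
        neg_scores = [s for g, sc in by_group.items() if g != "pta" for s in sc]

    values = pta_scores + list(neg_scores)
    labels = [True] * len(pta_scores) + [False] * len(neg_scores)
    roc = optimal_cutoff(roc_curve(values, labels))

    cut = clinical_cutoff(config.statistical_cutoff)
    tp = sum(s >= cut for s in pta_scores)
    fn = len(pta_scores) - tp
    fp = sum(s >= cut for s in neg_scores)
    tn = len(neg_scores) - fp
    return ScoreCohortResult(
        results=results,
        group_summaries=summaries,
        roc=roc,
        clinical_cutoff=cut,
        confusion=ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn),
        negative_class=negative_class,
    )
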