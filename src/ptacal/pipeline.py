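"""End-to-end analysis pipeline over a cohort table.

Sequences the full evaluation on a cohort CSV (or a freshly simulated
cohort): per-fluid QBT-vs-ELISA agreement, per-fluid marker ROC with Youden
cutoff, group mean +/- SEM summaries with Mann-Whitney comparisons, and the
adjusted PTA score analysis.  The result is a single machine-readable bundle
with provenance (seed, config hash) that is byte-identical for identical
configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .agreement import agreement_report
from .cohort import (
    GROUPS,
    CohortConfig,
    cohort_to_frame,
    default_config,
    generate_cohort,
    read_cohort_csv,
    records_from_frame,
    write_cohort_csv,
)
from .diagnostics import group_summary, mann_whitney_u, optimal_cutoff, roc_curve
from .score import ScoreConfig, score_cohort

log = logging.getLogger("ptacal")

__all__ = ["RunConfig", "run_full", "marker_group_summaries", "marker_roc", "write_outputs"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one input source: either ``input_path`` (a cohort CSV) or
    ``simulate=True`` (a seeded synthetic cohort from ``cohort_config``).
    """

    input_path: Optional[str] = None
    simulate: bool = False
    cohort_config: Optional[CohortConfig] = None
    score_config: ScoreConfig = field(default_factory=ScoreConfig)
    ba_restriction: Optional[float] = 12000.0
    negative_class: str = "controls"  # or "all"
    outdir: Optional[str] = None

    def __post_init__(self) -> None:
        if bool(self.input_path) == bool(self.simulate):
            raise ValueError("exactly one of input_path or simulate must be given")
        if self.negative_class not in ("controls", "all"):
            raise ValueError("negative_class must be 'controls' or 'all'")

    def to_dict(self) -> dict:
        d = {
            "input_path": self.input_path,
            "simulate": self.simulate,
            "cohort_config": self.cohort_config.to_dict() if self.cohort_config else None,
            "score_config": dataclasses.asdict(self.score_config),
            "ba_restriction": self.ba_restriction,
            "negative_class": self.negative_class,
        }
        return d


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def load_cohort(config: RunConfig) -> pd.DataFrame:
    if config.simulate:
        cc = config.cohort_config or default_config()
        log.info("simulating cohort (seed=%d)", cc.seed)
        return cohort_to_frame(generate_cohort(cc))
    log.info("reading cohort from %s", config.input_path)
    return read_cohort_csv(config.input_path)


def marker_group_summaries(df: pd.DataFrame, marker: str, reference: str = "control") -> dict:
    """Per-group mean +/- SEM of one marker column, with Mann-Whitney
    comparisons of every other group against the reference group."""
    out = {}
    ref_vals = df.loc[df["group"] == reference, marker].dropna()
    for g in GROUPS:
        vals = df.loc[df["group"] == g, marker].dropna()
        if vals.empty:
            continue
        s = group_summary(vals)
        if g != reference and not ref_vals.empty:
            s.u_stat, s.p_two_sided = mann_whitney_u(vals, ref_vals)
        out[g] = s
    return out


def marker_roc(df: pd.DataFrame, marker: str, negative_class: str = "controls"):
    """ROC of a marker for PTA membership with the Youden cutoff.

    Negatives are the healthy controls (default) or all non-PTA subjects.
    """
    if negative_class == "controls":
        sub = df[df["group"].isin(["pta", "control"])]
    else:
        sub = df
    sub = sub.dropna(subset=[marker])
    return optimal_cutoff(roc_curve(sub[marker], sub["group"] == "pta"))


def _summary_dict(s) -> dict:
    return {"n": s.n, "mean": s.mean, "sem": s.sem, "u_stat": s.u_stat, "p_two_sided": s.p_two_sided}


def run_full(config: RunConfig) -> dict:
    """Run every stage and assemble the machine-readable report bundle."""
    df = load_cohort(config)
    records = records_from_frame(df)

    bundle: dict = {
        "provenance": {
            "tool": "ptacal",
            "version": __version__,
            "config_hash": _config_hash(config),
            "seed": config.cohort_config.seed if config.cohort_config else None,
            "negative_class": config.negative_class,
            "cutoff_criterion": "youden",
        },
        "n_subjects": int(len(df)),
        "agreement": {},
        "marker_summaries": {},
        "marker_roc": {},
    }

    for fluid in ("serum", "saliva"):
        qbt, elisa = df[f"{fluid}_qbt"], df[f"{fluid}_elisa"]
        rep = agreement_report(qbt, elisa, fluid=fluid, ba_restriction=config.ba_restriction)
        bundle["agreement"][fluid] = rep.to_dict()
        bundle["marker_summaries"][fluid] = {
            g: _summary_dict(s) for g, s in marker_group_summaries(df, f"{fluid}_qbt").items()
        }
        roc = marker_roc(df, f"{fluid}_qbt", config.negative_class)
        bundle["marker_roc"][fluid] = roc.to_dict()
        log.info(
            "%s: r_sp=%.3f (%s), cutoff=%.0f ng/ml, AUC=%.3f (%s)",
            fluid, rep.r_sp, rep.r_class, roc.cutoff, roc.auc, roc.auc_class,
        )

    sc = score_cohort(records, config.score_config, negative_class=config.negative_class)
    bundle["score"] = {
        "config": dataclasses.asdict(config.score_config),
        "clinical_cutoff": sc.clinical_cutoff,
        "group_summaries": {g: _summary_dict(s) for g, s in sc.group_summaries.items()},
        "roc": sc.roc.to_dict(),
        "confusion_at_clinical_cutoff": {
            "tp": sc.confusion.tp, "fp": sc.confusion.fp,
            "tn": sc.confusion.tn, "fn": sc.confusion.fn,
            "sensitivity": sc.confusion.sensitivity,
            "specificity": sc.confusion.specificity,
        },
        "negative_class": sc.negative_class,
    }
    log.info(
        "score: statistical cutoff %.1f -> clinical cutoff %d; sens=%.3f spec=%.3f",
        sc.roc.cutoff if sc.roc.cutoff is not None else float("nan"),
        sc.clinical_cutoff, sc.confusion.sensitivity, sc.confusion.specificity,
    )
    bundle["_score_table"] = sc.score_table()
    bundle["_cohort"] = df
    return bundle


def bundle_to_json(bundle: dict) -> str:
    """Serialise the report bundle deterministically (private tables dropped)."""
    clean = {k: v for k, v in bundle.items() if not k.startswith("_")}
    return json.dumps(clean, indent=2, sort_keys=True)


def write_outputs(bundle: dict, outdir) -> None:
    """Write the report JSON plus plot-ready CSV tables."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(bundle_to_json(bundle) + "\n")

    df: pd.DataFrame = bundle["_cohort"]
    df.to_csv(out / "cohort.csv", index=False)
    bundle["_score_table"].to_csv(out / "score_table.csv", index=False)

    for fluid in ("serum", "saliva"):
        pairs = df[[f"{fluid}_qbt", f"{fluid}_elisa"]].dropna()
        pairs.columns = ["qbt", "elisa"]
        pairs = pairs.assign(mean=(pairs.qbt + pairs.elisa) / 2, diff=pairs.qbt - pairs.elisa)
        pairs.to_csv(out / f"{fluid}_agreement_pairs.csv", index=False)

        rocd = bundle["marker_roc"][fluid]
        roc_df = pd.DataFrame(rocd["points"], columns=["threshold", "sensitivity", "specificity"])
        roc_df["fpr"] = 1.0 - roc_df["specificity"]
        roc_df.to_csv(out / f"{fluid}_roc_points.csv", index=False)

        ba = bundle["agreement"][fluid]["ba"]
        hist = pd.DataFrame({
            "bin_left": ba["hist_edges"][:-1],
            "bin_right": ba["hist_edges"][1:],
            "count": ba["hist_counts"],
        })
        hist.to_csv(out / f"{fluid}_diff_histogram.csv", index=False)
    log.info("wrote outputs to %s", out)
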